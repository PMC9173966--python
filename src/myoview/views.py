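"""Window segmentation and the ten named feature-set "views".

A *view* is one 2-D feature representation of an sEMG analysis window: each
channel contributes one row and the view's ordered feature list the columns,
so every view image has shape (channels, features).  Ten literature-standard
feature sets are registered (Du, time-domain correlation, Atzori, two
Phinyomark sets, Doswald, DWT / DWPT / CWT wavelet coefficients, Hudgins);
their exact contents are configuration, defined in one place below, because
the named sets are citations whose compositions vary across the literature.
An ordered tuple of view images from one window, plus the class label, is
one multiview training sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt

from . import features as F
from .synth import EmgRecording

WAVELET = "db4"
DWT_LEVELS = 3
CWT_SCALES = np.geomspace(2.0, 32.0, 8)
AUTOCORR_LAGS = 8


@dataclass(frozen=True)
class ViewDefinition:
    """A named feature set mapped onto a (channels × features) image."""

    view_id: int
    name: str
    feature_names: tuple[str, ...]
    _extract: Callable[[np.ndarray, np.ndarray, float, int], list[float]] = field(
        repr=False, compare=False
    )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def layout(self, n_channels: int) -> tuple[int, int]:
        return (n_channels, self.n_features)


@dataclass(frozen=True)
class WindowSegment:
    """One analysis window: (samples × channels) values, label, provenance."""

    samples: np.ndarray
    class_id: int
    source_offset: int
    trial_id: int
    fs: float


@dataclass(frozen=True)
class ViewImage:
    values: np.ndarray
    view_id: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"view {self.view_id}: non-finite feature values")


@dataclass(frozen=True)
class MultiViewSample:
    """Ordered view images of one window plus its class label."""

    images: tuple[ViewImage, ...]
    class_id: int
    trial_id: int


def segment(rec: EmgRecording, window_len: int, step: int) -> list[WindowSegment]:
    """Tile each annotated interval with windows of ``window_len`` samples
    advanced by ``step``; windows never straddle interval boundaries.

    Per interval of length L ≥ window_len the window count is
    ``floor((L − window_len)/step) + 1``; shorter intervals yield none.
    """
    if not (0 < step <= window_len):
        raise ValueError("need 0 < step <= window_len")
    out: list[WindowSegment] = []
    for trial_id, (start, end, class_id) in enumerate(rec.annotations):
        length = end - start
        if length < window_len:
            continue
        n_windows = (length - window_len) // step + 1
        for k in range(n_windows):
            s = start + k * step
            out.append(
                WindowSegment(
                    samples=rec.samples[s : s + window_len],
                    class_id=class_id,
                    source_offset=s,
                    trial_id=trial_id,
                    fs=rec.fs,
                )
            )
    if not out:
        warnings.warn(
            "window length exceeds every annotated interval; no windows produced",
            stacklevel=2,
        )
    return out


# --- per-channel extractors --------------------------------------------------
# Each takes (x: this channel, window: all channels, fs, c: channel index)
# and returns the ordered feature values for one row of the view image.


def _hudgins(x, window, fs, c):
    thr = F.default_threshold(x)
    return [F.mav(x), F.zc(x, thr), F.ssc(x, thr), F.wl(x)]


def _du(x, window, fs, c):
    thr = F.default_threshold(x)
    return [F.iemg(x), F.var(x), F.wl(x), F.zc(x, thr), F.ssc(x, thr), F.wamp(x, thr)]


def _correlation(x, window, fs, c):
    # autocorrelation shape (scale invariant) + zero-lag coupling to the
    # next channel; single-channel windows couple to themselves (r = 1).
    ac = list(F.autocorrelation(x, AUTOCORR_LAGS))
    n_ch = window.shape[1]
    if n_ch == 1:
        cross = 1.0
    else:
        cross = F.cross_correlation(x, window[:, (c + 1) % n_ch])
    return ac + [cross]


def _atzori(x, window, fs, c):
    return [F.mav(x), F.var(x), F.wl(x), F.rms(x)] + list(F.amplitude_histogram(x))


def _phinyomark1(x, window, fs, c):
    thr = F.default_threshold(x)
    return (
        [F.mav(x), F.wl(x), F.zc(x, thr), F.ssc(x, thr)]
        + list(F.ar_coefficients(x, 4))
        + list(F.mavs(x, 3))
    )


def _phinyomark2(x, window, fs, c):
    sm = F.spectral_moments(x, fs)
    return [F.rms(x), F.wl(x), F.median_amplitude(x)] + list(sm)


def _doswald(x, window, fs, c):
    return [F.mav(x), F.wl(x), F.mean_frequency(x, fs), F.signal_power(x)]


def _check_wavelet_length(n: int, view_name: str) -> None:
    min_len = 2**DWT_LEVELS
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(WAVELET).dec_len)
    if n < min_len or max_level < DWT_LEVELS:
        raise ValueError(
            f"view '{view_name}': window of {n} samples too short for a "
            f"{DWT_LEVELS}-level {WAVELET} decomposition"
        )


def _dwt(x, window, fs, c):
    _check_wavelet_length(x.size, "DWT coefficients")
    coeffs = pywt.wavedec(x, WAVELET, level=DWT_LEVELS)
    energies = [float(np.sum(np.square(c))) for c in coeffs]
    subsampled = [float(v) for c in coeffs for v in c[:2]]
    return energies + subsampled


def _dwpt(x, window, fs, c):
    _check_wavelet_length(x.size, "DWPT coefficients")
    wp = pywt.WaveletPacket(x, WAVELET, maxlevel=DWT_LEVELS)
    leaves = wp.get_level(DWT_LEVELS, order="natural")
    energies = [float(np.sum(np.square(node.data))) for node in leaves]
    heads = [float(node.data[0]) for node in leaves]
    return energies + heads


def _cwt(x, window, fs, c):
    coefs, _freqs = pywt.cwt(x, CWT_SCALES, "morl", sampling_period=1.0 / fs)
    # temporal pooling: mean |coefficient| over the two window halves
    half = x.size // 2
    pooled = np.column_stack(
        [np.mean(np.abs(coefs[:, :half]), axis=1),
         np.mean(np.abs(coefs[:, half:]), axis=1)]
    )
    return [float(v) for v in pooled.ravel()]


def _names(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(n))


def standard_views() -> dict[int, ViewDefinition]:
    """The ten registered views, keyed by view id."""
    defs = [
        ViewDefinition(1, "Du",
                       ("IEMG", "VAR", "WL", "ZC", "SSC", "WAMP"), _du),
        ViewDefinition(2, "time-domain correlation",
                       _names("AC", AUTOCORR_LAGS) + ("XCORR",), _correlation),
        ViewDefinition(3, "Atzori",
                       ("MAV", "VAR", "WL", "RMS") + _names("HIST", 10), _atzori),
        ViewDefinition(4, "Phinyomark 1",
                       ("MAV", "WL", "ZC", "SSC") + _names("AR", 4)
                       + _names("MAVS", 2), _phinyomark1),
        ViewDefinition(5, "Phinyomark 2",
                       ("RMS", "WL", "MEDAMP", "SM0", "SM1", "SM2"), _phinyomark2),
        ViewDefinition(6, "Doswald",
                       ("MAV", "WL", "MNF", "POWER"), _doswald),
        ViewDefinition(7, "DWT coefficients",
                       _names("E", DWT_LEVELS + 1)
                       + _names("C", 2 * (DWT_LEVELS + 1)), _dwt),
        ViewDefinition(8, "DWPT coefficients",
                       _names("E", 2**DWT_LEVELS) + _names("C", 2**DWT_LEVELS),
                       _dwpt),
        ViewDefinition(9, "CWT coefficients",
                       _names("S", 2 * len(CWT_SCALES)), _cwt),
        ViewDefinition(10, "Hudgins",
                       ("MAV", "ZC", "SSC", "WL"), _hudgins),
    ]
    return {d.view_id: d for d in defs}


VIEWS = standard_views()


def compute_view(w: WindowSegment, vd: ViewDefinition) -> ViewImage:
    """Compute one view image (channels × features) from one window."""
    window = np.asarray(w.samples, dtype=float)
    rows = []
    for c in range(window.shape[1]):
        row = vd._extract(window[:, c], window, w.fs, c)
        if len(row) != vd.n_features:
            raise RuntimeError(
                f"view '{vd.name}' produced {len(row)} features, "
                f"expected {vd.n_features}"
            )
        rows.append(row)
    return ViewImage(values=np.asarray(rows, dtype=float), view_id=vd.view_id)


def build_multiview(
    windows: list[WindowSegment], selected: list[ViewDefinition]
) -> list[MultiViewSample]:
    """One multiview sample per window; image order follows ``selected``."""
    ids = [vd.view_id for vd in selected]
    if len(set(ids)) != len(ids):
        raise ValueError("selected views must be distinct")
    return [
        MultiViewSample(
            images=tuple(compute_view(w, vd) for vd in selected),
            class_id=w.class_id,
            trial_id=w.trial_id,
        )
        for w in windows
    ]
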