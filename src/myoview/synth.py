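"""Seeded generators for synthetic facial sEMG and two-arm clinical cohorts.

The signal model is deliberately simple: each gesture class is band-passed
Gaussian noise with a rectangular activation burst, with the burst RMS and
the passband controlled per class.  RMS, median frequency and mean power
frequency — the only statistics the downstream analysis consumes — are all
directly controllable under this model, while motor-unit physiology,
electrode geometry and line interference are explicitly out of scope.

The cohort generator draws a four-level House-Brackmann outcome from a
per-arm multinomial and Gaussian sEMG parameters (truncated at zero) per
muscle and timepoint, so that group-comparison statistics can be exercised
at the parameter level without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .clinical import HB_CATEGORIES, ClinicalRecord, SpectralParams

DEFAULT_FS = 1000.0
DEFAULT_CHANNELS = ("buccinator", "frontalis")


@dataclass(frozen=True)
class GestureClassParams:
    """Generative parameters for one gesture class.

    amplitude_uv : per-channel target RMS of the active burst, μV.  A scalar
        is broadcast over channels.
    passband_hz : band-pass corner frequencies (low, high), Hz.
    duty_cycle : fraction of each trial occupied by the centred burst.
    """

    class_id: int
    amplitude_uv: tuple[float, ...]
    passband_hz: tuple[float, float]
    duty_cycle: float = 1.0

    def validate(self, fs: float, n_channels: int) -> None:
        low, high = self.passband_hz
        if not (0 < low < high < fs / 2):
            raise ValueError(
                f"class {self.class_id}: passband {self.passband_hz} must "
                f"satisfy 0 < low < high < fs/2 = {fs / 2}"
            )
        amps = self.amplitudes(n_channels)
        if any(a <= 0 for a in amps):
            raise ValueError(f"class {self.class_id}: amplitude scale must be > 0")
        if not (0 < self.duty_cycle <= 1):
            raise ValueError(f"class {self.class_id}: duty cycle must be in (0, 1]")

    def amplitudes(self, n_channels: int) -> tuple[float, ...]:
        amps = self.amplitude_uv
        if np.isscalar(amps):
            amps = (float(amps),)
        if len(amps) == 1:
            return tuple(float(amps[0]) for _ in range(n_channels))
        if len(amps) != n_channels:
            raise ValueError(
                f"class {self.class_id}: {len(amps)} amplitudes for "
                f"{n_channels} channels"
            )
        return tuple(float(a) for a in amps)


@dataclass
class EmgRecording:
    """Multichannel sEMG: samples (time × channels, μV), sampling rate and
    half-open annotated intervals ``(start, end, class_id)``."""

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    annotations: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time × channels) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError("channel name count must match channel axis")
        n = self.samples.shape[0]
        prev_end = 0
        for start, end, _cid in sorted(self.annotations):
            if not (0 <= start < end <= n):
                raise ValueError(f"annotation [{start}, {end}) out of bounds")
            if start < prev_end:
                raise ValueError("annotations overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def _bandlimit(x: np.ndarray, passband: tuple[float, float], fs: float) -> np.ndarray:
    """Ideal zero-phase band-pass via the frequency domain.

    The passband is exactly flat, so the spectral targets hold in closed
    form: a flat band [f_lo, f_hi] has MF = MPF = (f_lo + f_hi)/2.  An IIR
    design (e.g. Butterworth) is geometrically symmetric about √(f_lo·f_hi)
    and would bias MF/MPF several Hz low.
    """
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fs)
    mask = (freqs >= passband[0]) & (freqs <= passband[1])
    return np.fft.irfft(spec * mask[:, None], n=x.shape[0], axis=0)


def simulate_semg(
    params: list[GestureClassParams],
    n_trials_per_class: int,
    trial_len: float,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
    noise_rms: float = 0.0,
) -> EmgRecording:
    """Generate gesture-labelled sEMG trials, concatenated with annotations.

    Each trial is white Gaussian noise band-limited (ideal zero-phase
    band-pass) to the class passband, windowed by a centred
    rectangular burst of the class duty cycle, and scaled so the burst RMS
    equals the class amplitude.  An optional broadband sensor-noise floor of
    RMS ``noise_rms`` μV is added on top.  Trials are interleaved across
    classes; annotations cover the active bursts.  Identical seeds give
    bit-identical output.
    """
    if trial_len <= 0:
        raise ValueError("trial length must be positive")
    if n_trials_per_class <= 0:
        raise ValueError("need at least one trial per class")
    n_ch = len(channel_names)
    for p in params:
        p.validate(fs, n_ch)
    n_samp = int(round(trial_len * fs))
    max_period = max(1.0 / p.passband_hz[0] for p in params)
    if n_samp < 2 * max_period * fs:
        raise ValueError("trial too short for the lowest passband frequency")

    rng = np.random.default_rng(seed)

    chunks: list[np.ndarray] = []
    annotations: list[tuple[int, int, int]] = []
    offset = 0
    for _trial in range(n_trials_per_class):
        for p in params:
            raw = rng.standard_normal((n_samp, n_ch))
            x = _bandlimit(raw, p.passband_hz, fs)
            act_len = max(1, int(round(p.duty_cycle * n_samp)))
            start = (n_samp - act_len) // 2
            mask = np.zeros((n_samp, 1))
            mask[start : start + act_len] = 1.0
            x = x * mask
            burst = x[start : start + act_len]
            scale = np.array(p.amplitudes(n_ch)) / np.sqrt(
                np.mean(np.square(burst), axis=0)
            )
            x = x * scale
            if noise_rms > 0:
                x = x + noise_rms * rng.standard_normal((n_samp, n_ch))
            chunks.append(x)
            annotations.append((offset + start, offset + start + act_len, p.class_id))
            offset += n_samp
    return EmgRecording(
        samples=np.concatenate(chunks, axis=0),
        fs=fs,
        channel_names=tuple(channel_names),
        annotations=annotations,
    )


# --- clinical cohorts -------------------------------------------------------

# (mean, SD) of (rms μV, mf Hz, mpf Hz) per muscle and timepoint.
SpectralMoments = dict[str, dict[str, tuple[float, float, float, float, float, float]]]


@dataclass(frozen=True)
class GroupParams:
    """One study arm: size, H-B outcome probabilities and Gaussian
    (mean, SD) parameters for RMS/MF/MPF per muscle and timepoint."""

    n: int
    hb_probs: tuple[float, float, float, float]
    spectral: SpectralMoments

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if abs(sum(self.hb_probs) - 1.0) > 1e-9:
            raise ValueError(
                f"H-B category probabilities sum to {sum(self.hb_probs)}, not 1"
            )
        if any(p < 0 for p in self.hb_probs):
            raise ValueError("H-B category probabilities must be non-negative")
        for muscle, by_tp in self.spectral.items():
            for tp, moments in by_tp.items():
                if any(sd < 0 for sd in moments[1::2]):
                    raise ValueError(f"negative SD for {muscle}/{tp}")


@dataclass(frozen=True)
class CohortParams:
    groups: dict[str, GroupParams]

    def validate(self) -> None:
        for gp in self.groups.values():
            gp.validate()


def _moments(rms_m, rms_sd, mf_m, mf_sd, mpf_m, mpf_sd):
    return (rms_m, rms_sd, mf_m, mf_sd, mpf_m, mpf_sd)


def default_cohort_params() -> CohortParams:
    """Two-arm cohort defaults for an electroacupuncture facial-paralysis
    study: 70 control / 80 treatment patients, post-treatment group means for
    RMS/MF/MPF of the buccinator and frontalis, and H-B outcome proportions.
    Pre-treatment means (not separately reported in the source study) are set
    below the post-treatment values of both arms, consistent with the
    reported within-group improvement.
    """
    pre = {
        "buccinator": {"pre": _moments(12.0, 2.4, 80.0, 10.8, 100.0, 8.6)},
        "frontalis": {"pre": _moments(7.0, 2.2, 85.0, 10.4, 95.0, 7.9)},
    }
    control = GroupParams(
        n=70,
        hb_probs=(39 / 70, 17 / 70, 3 / 70, 11 / 70),
        spectral={
            "buccinator": {
                **pre["buccinator"],
                "post": _moments(18.42, 2.4, 89.5, 10.8, 112.4, 8.6),
            },
            "frontalis": {
                **pre["frontalis"],
                "post": _moments(10.51, 2.2, 94.2, 10.4, 104.3, 7.9),
            },
        },
    )
    treatment = GroupParams(
        n=80,
        hb_probs=(51 / 80, 15 / 80, 9 / 80, 5 / 80),
        spectral={
            "buccinator": {
                **pre["buccinator"],
                "post": _moments(24.67, 2.4, 108.4, 10.6, 143.5, 8.2),
            },
            "frontalis": {
                **pre["frontalis"],
                "post": _moments(16.42, 2.2, 115.4, 10.4, 125.9, 7.8),
            },
        },
    )
    return CohortParams(groups={"control": control, "treatment": treatment})


def _truncated_normal(mean: float, sd: float, size: int, rng) -> np.ndarray:
    """Gaussian draws truncated at zero (physical non-negativity)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return _stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                                random_state=rng)


def simulate_cohort(params: CohortParams, seed: int = 0) -> list[ClinicalRecord]:
    """Draw a seeded two-arm cohort of :class:`ClinicalRecord` objects.

    H-B categories come from the arm multinomial; RMS/MF/MPF come from
    zero-truncated Gaussians per muscle and timepoint.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    records: list[ClinicalRecord] = []
    for group in sorted(params.groups):
        gp = params.groups[group]
        cats = rng.choice(len(HB_CATEGORIES), size=gp.n, p=np.asarray(gp.hb_probs))
        draws: dict[tuple[str, str], np.ndarray] = {}
        for muscle in sorted(gp.spectral):
            for tp in sorted(gp.spectral[muscle]):
                rms_m, rms_sd, mf_m, mf_sd, mpf_m, mpf_sd = gp.spectral[muscle][tp]
                draws[(muscle, tp)] = np.column_stack(
                    [
                        _truncated_normal(rms_m, rms_sd, gp.n, rng),
                        _truncated_normal(mf_m, mf_sd, gp.n, rng),
                        _truncated_normal(mpf_m, mpf_sd, gp.n, rng),
                    ]
                )
        for i in range(gp.n):
            per_patient = {
                key: SpectralParams(rms=float(v[i, 0]), mf=float(v[i, 1]),
                                    mpf=float(v[i, 2]))
                for key, v in draws.items()
            }
            records.append(
                ClinicalRecord(
                    patient_id=f"{group[0].upper()}{i + 1:03d}",
                    group=group,
                    hb_category=HB_CATEGORIES[int(cats[i])],
                    params=per_patient,
                )
            )
    return records
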