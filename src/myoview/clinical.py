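"""Clinical observation indexes and group-comparison statistics.

Surface-EMG treatment studies of peripheral facial paralysis summarise each
patient by three spectral parameters per muscle and timepoint — root mean
square (RMS, a muscle-strength surrogate in μV), median frequency (MF, the
frequency that splits spectral power into equal halves) and mean power
frequency (MPF, the power-weighted mean frequency) — plus a four-level
House-Brackmann (H-B) outcome category.  Group-level efficacy is reported as
the *total effective rate*: the percentage of patients in any category other
than "ineffective".  Between-group comparisons use a two-sample t-test for
measurement data and a Pearson chi-square test for count data, at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

HB_CATEGORIES = ("recovered", "markedly_effective", "effective", "ineffective")

MUSCLES = ("buccinator", "frontalis")
TIMEPOINTS = ("pre", "post")


@dataclass(frozen=True)
class SpectralParams:
    """RMS (μV), median frequency (Hz) and mean power frequency (Hz)."""

    rms: float
    mf: float
    mpf: float

    def __post_init__(self) -> None:
        if self.rms < 0 or self.mf < 0 or self.mpf < 0:
            raise ValueError("spectral parameters must be non-negative")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient: group arm, H-B outcome and per-muscle pre/post parameters.

    ``params`` maps ``(muscle, timepoint)`` — e.g. ``("buccinator", "post")``
    — to a :class:`SpectralParams`.
    """

    patient_id: str
    group: str
    hb_category: str
    params: dict[tuple[str, str], SpectralParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hb_category not in HB_CATEGORIES:
            raise ValueError(
                f"unknown H-B category {self.hb_category!r}; "
                f"expected one of {HB_CATEGORIES}"
            )


@dataclass(frozen=True)
class EfficacySummary:
    """Per-group H-B category counts and the total effective rate (percent)."""

    counts: tuple[int, int, int, int]
    n: int
    effective_rate: float

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n:
            raise ValueError("category counts must sum to n")


@dataclass(frozen=True)
class TestReport:
    """Result of a two-group comparison with the α-level verdict."""

    kind: str
    statistic: float
    df: float
    p_value: float
    alpha: float
    significant: bool


def rms(x: np.ndarray) -> float:
    """Root mean square of a signal, √(mean(x²))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty signal is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def power_spectrum(
    x: np.ndarray,
    fs: float,
    nperseg: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hann window, 50 % segment overlap).

    Returns ``(frequencies, densities)``; densities are in power per Hz so
    that the trapezoidal integral approximates the signal variance.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg, x.size)
    freqs, pxx = _signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return freqs, pxx


def median_frequency(freqs: np.ndarray, pxx: np.ndarray) -> float:
    """Frequency at which cumulative power reaches half the total.

    Linear interpolation is applied inside the bin where the crossing
    occurs, which removes the bin-width bias of a plain cumulative scan.
    """
    freqs = np.asarray(freqs, dtype=float)
    pxx = np.asarray(pxx, dtype=float)
    total = float(np.sum(pxx))
    if total <= 0:
        raise ValueError("median frequency undefined for zero total power")
    cum = np.cumsum(pxx)
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(freqs[0])
    # fraction of bin k needed to reach half power
    frac = (half - cum[k - 1]) / pxx[k] if pxx[k] > 0 else 0.0
    return float(freqs[k - 1] + frac * (freqs[k] - freqs[k - 1]))


def mean_power_frequency(freqs: np.ndarray, pxx: np.ndarray) -> float:
    """Power-weighted mean frequency, Σ f·P(f) / Σ P(f)."""
    freqs = np.asarray(freqs, dtype=float)
    pxx = np.asarray(pxx, dtype=float)
    total = float(np.sum(pxx))
    if total <= 0:
        raise ValueError("mean power frequency undefined for zero total power")
    return float(np.sum(freqs * pxx) / total)


def spectral_params(x: np.ndarray, fs: float, nperseg: int = 256) -> SpectralParams:
    """Convenience: RMS/MF/MPF of one signal in a single call."""
    freqs, pxx = power_spectrum(x, fs, nperseg=nperseg)
    return SpectralParams(
        rms=rms(x),
        mf=median_frequency(freqs, pxx),
        mpf=mean_power_frequency(freqs, pxx),
    )


def _round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def hb_summary(records: list[ClinicalRecord], group: str) -> EfficacySummary:
    """H-B category counts and total effective rate for one study arm.

    The total effective rate counts every category except "ineffective",
    reported as a percentage rounded half-up to two decimals.
    """
    in_group = [r for r in records if r.group == group]
    if not in_group:
        raise ValueError(f"no records in group {group!r}")
    counts = tuple(
        sum(1 for r in in_group if r.hb_category == cat) for cat in HB_CATEGORIES
    )
    return summarize_counts(counts)


def summarize_counts(counts: tuple[int, int, int, int]) -> EfficacySummary:
    """Efficacy summary from raw H-B category counts (recovered, markedly
    effective, effective, ineffective)."""
    if len(counts) != len(HB_CATEGORIES):
        raise ValueError(f"expected {len(HB_CATEGORIES)} category counts")
    n = int(sum(counts))
    if n == 0:
        raise ValueError("empty group")
    rate = _round_half_up(100.0 * (n - counts[-1]) / n, 2)
    return EfficacySummary(counts=tuple(int(c) for c in counts), n=n, effective_rate=rate)


def compare_groups(
    control,
    treatment,
    kind: str,
    alpha: float = 0.05,
    yates: bool = False,
    welch: bool = True,
) -> TestReport:
    """Two-group comparison: chi-square on rates, t-test on means.

    ``kind="rate"`` expects two :class:`EfficacySummary` objects and runs a
    Pearson chi-square (df = 1, no Yates continuity correction unless
    ``yates=True``) on the 2×2 effective/ineffective table.  ``kind="mean"``
    expects two arrays of per-patient values and runs a two-sample t-test
    (Welch by default).
    """
    if kind == "rate":
        table = np.array(
            [
                [control.n - control.counts[-1], control.counts[-1]],
                [treatment.n - treatment.counts[-1], treatment.counts[-1]],
            ],
            dtype=float,
        )
        res = _stats.chi2_contingency(table, correction=yates)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.dof)
        return TestReport("rate", stat, df, p, alpha, bool(p < alpha))
    if kind == "mean":
        a = np.asarray(control, dtype=float)
        b = np.asarray(treatment, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per group")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both groups; t-test undefined")
        res = _stats.ttest_ind(a, b, equal_var=not welch)
        df = float(res.df)
        return TestReport(
            "mean", float(res.statistic), df, float(res.pvalue), alpha,
            bool(res.pvalue < alpha),
        )
    raise ValueError(f"unknown comparison kind {kind!r}")
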