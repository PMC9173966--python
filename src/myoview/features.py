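"""Single-channel sEMG feature primitives.

These are the classical myoelectric window features (mean absolute value,
waveform length, zero crossings, slope-sign changes, Willison amplitude,
autoregressive coefficients, spectral moments, ...) that the named feature
"views" are assembled from.  All threshold-gated counters (ZC, SSC, WAMP)
take the threshold as an argument; callers use a scale-proportional default
(1 % of window RMS) so the counters are invariant to amplitude rescaling.

Every function accepts a 1-D float array (one channel of one analysis
window) and returns a float or a small float array.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz


def mav(x: np.ndarray) -> float:
    """Mean absolute value."""
    return float(np.mean(np.abs(x)))


def iemg(x: np.ndarray) -> float:
    """Integrated EMG: sum of absolute values."""
    return float(np.sum(np.abs(x)))


def var(x: np.ndarray) -> float:
    """EMG variance, Σx²/(N−1) (the signal is taken as zero-mean)."""
    return float(np.sum(np.square(x)) / (x.size - 1))


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def wl(x: np.ndarray) -> float:
    """Waveform length: cumulative absolute first difference."""
    return float(np.sum(np.abs(np.diff(x))))


def default_threshold(x: np.ndarray) -> float:
    """Scale-proportional gate for ZC/SSC/WAMP: 1 % of window RMS."""
    return 0.01 * rms(x)


def zc(x: np.ndarray, threshold: float) -> float:
    """Zero crossings whose amplitude jump exceeds the threshold."""
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= threshold
    return float(np.count_nonzero(sign_change & big_enough))


def ssc(x: np.ndarray, threshold: float) -> float:
    """Slope-sign changes exceeding the threshold on either side."""
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    turning = d1 * d2 > 0
    big_enough = np.maximum(np.abs(d1), np.abs(d2)) >= threshold
    return float(np.count_nonzero(turning & big_enough))


def wamp(x: np.ndarray, threshold: float) -> float:
    """Willison amplitude: consecutive differences exceeding the threshold."""
    return float(np.count_nonzero(np.abs(np.diff(x)) >= threshold))


def mavs(x: np.ndarray, n_segments: int = 3) -> np.ndarray:
    """Mean-absolute-value slope: MAV differences between adjacent
    equal-length segments (``n_segments − 1`` values)."""
    segs = np.array_split(x, n_segments)
    m = np.array([mav(s) for s in segs])
    return np.diff(m)


def ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Autoregressive model coefficients via the Yule-Walker equations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= order:
        raise ValueError(f"window of {n} samples too short for AR({order})")
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] <= 0:
        return np.zeros(order)
    return solve_toeplitz(r[:order], r[1 : order + 1])


def median_amplitude(x: np.ndarray) -> float:
    return float(np.median(np.abs(x)))


def signal_power(x: np.ndarray) -> float:
    """Mean squared value."""
    return float(np.mean(np.square(x)))


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return freqs, spec


def spectral_moments(x: np.ndarray, fs: float, orders=(0, 1, 2)) -> np.ndarray:
    """Raw spectral moments Σ P(f)·f^k of the window periodogram."""
    freqs, spec = _periodogram(x, fs)
    return np.array([float(np.sum(spec * freqs**k)) for k in orders])


def mean_frequency(x: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency of the window periodogram."""
    freqs, spec = _periodogram(x, fs)
    total = float(np.sum(spec))
    if total == 0:
        return 0.0
    return float(np.sum(freqs * spec) / total)


def amplitude_histogram(x: np.ndarray, bins: int = 10, n_sigma: float = 3.0) -> np.ndarray:
    """Normalised amplitude histogram over ±``n_sigma`` standard deviations."""
    sd = float(np.std(x))
    if sd == 0:
        h = np.zeros(bins)
        h[bins // 2] = 1.0
        return h
    counts, _ = np.histogram(x, bins=bins, range=(-n_sigma * sd, n_sigma * sd))
    return counts / x.size


def autocorrelation(x: np.ndarray, lags: int) -> np.ndarray:
    """Normalised autocorrelation at lags 1..``lags``."""
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    denom = float(np.dot(x, x))
    if denom == 0:
        return np.zeros(lags)
    return np.array(
        [np.dot(x[: x.size - k], x[k:]) / denom for k in range(1, lags + 1)]
    )


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation between two channels."""
    x = x - np.mean(x)
    y = y - np.mean(y)
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0:
        return 0.0
    return float(np.dot(x, y) / denom)
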