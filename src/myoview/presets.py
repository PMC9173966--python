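"""Canned experimental conditions for the synthetic studies.

The *complementary-views* preset builds a 3-class gesture problem in which
no single view sees everything: classes 0 and 1 share a spectrum and differ
only in burst amplitude (invisible to the scale-invariant correlation
view), while classes 0 and 2 share an amplitude and differ only in
passband (weakly visible to amplitude-centric features).  A broadband
sensor-noise floor keeps every view's evidence noisy, so aggregating views
genuinely helps.
"""

from __future__ import annotations

from .synth import GestureClassParams, simulate_semg
from .training import MultiViewDataset
from .views import VIEWS, build_multiview, segment

COMPLEMENTARY_VIEW_IDS = (2, 3, 7)  # correlation, Atzori, DWT coefficients
DEFAULT_VIEW_IDS = (8, 4, 7)  # the three strongest single-view feature sets

WINDOW_MS = 200
OVERLAP = 0.5


DEFAULT_NOISE_RMS = 6.0


def complementary_classes() -> list[GestureClassParams]:
    """Three gestures with deliberately confusable signatures: 0 vs 1 differ
    only in burst amplitude (10 vs 13 μV RMS), 0 vs 2 only in passband
    (20–150 vs 50–200 Hz), under a 6 μV broadband noise floor."""
    return [
        GestureClassParams(0, (10.0,), (20.0, 150.0), 0.8),
        GestureClassParams(1, (13.0,), (20.0, 150.0), 0.8),
        GestureClassParams(2, (10.0,), (50.0, 200.0), 0.8),
    ]


def make_dataset(
    classes: list[GestureClassParams] | None = None,
    view_ids: tuple[int, ...] = COMPLEMENTARY_VIEW_IDS,
    n_trials_per_class: int = 30,
    trial_len: float = 1.0,
    fs: float = 1000.0,
    noise_rms: float = DEFAULT_NOISE_RMS,
    seed: int = 0,
) -> MultiViewDataset:
    """Simulate, segment (200 ms windows, 50 % overlap) and featurize."""
    classes = classes if classes is not None else complementary_classes()
    rec = simulate_semg(
        classes, n_trials_per_class, trial_len, fs=fs, seed=seed,
        noise_rms=noise_rms,
    )
    window = int(round(WINDOW_MS / 1000 * fs))
    step = int(round(window * (1 - OVERLAP)))
    windows = segment(rec, window, step)
    samples = build_multiview(windows, [VIEWS[v] for v in view_ids])
    return MultiViewDataset.from_samples(samples, view_ids)
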