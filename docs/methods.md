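# Methods

## Problem and scope

Surface EMG (sEMG) records the superposition of motor-unit action
potentials under skin electrodes. Two tasks are covered here:

1. **Facial-gesture recognition from multichannel sEMG**, using a
   *multiview* convolutional network: each analysis window is rendered into
   several 2-D feature images ("views", one per named feature set), each
   view gets its own convolutional branch, and branch features are fused at
   two depths before a final additive decision rule.
2. **Clinical efficacy statistics** for a two-arm treatment study of
   peripheral facial paralysis: per-muscle RMS / median frequency (MF) /
   mean power frequency (MPF), four-level House-Brackmann (H-B) outcome
   summaries with the total effective rate, Welch t-tests on group means
   and the Pearson chi-square on effective rates, all at α = 0.05.

Both tasks are exercised on synthetic data generated in-package; no
recordings or patient tables ship with the code.

## Signal model of the gesture simulator

Each gesture class is parameterized by a per-channel burst amplitude
(target RMS, μV), a passband (Hz) and a duty cycle. A trial is white
Gaussian noise band-limited to the class passband by an **ideal zero-phase
frequency-domain band-pass** (the FFT is masked outside the band), windowed
by a centred rectangular activation burst, scaled so the burst RMS equals
the class amplitude exactly, and optionally overlaid with a broadband
sensor-noise floor. Defaults: 1000 Hz sampling, two channels named for the
buccinator and frontalis muscles.

The ideal band-limiter is a deliberate choice over an IIR design: a
zero-phase Butterworth band-pass is geometrically symmetric about
√(f_lo·f_hi), which on a 20–200 Hz band biases MF and MPF several Hz below
the arithmetic band centre. With an exactly flat passband the closed forms
hold: MF = MPF = (f_lo + f_hi)/2, which the tests check at ±5 Hz (the
residual deviation is Welch-estimator variance, not generator bias).

What the generator does **not** model: motor-unit action-potential trains,
electrode geometry and crosstalk, motion artifacts, power-line
interference, amplitude non-stationarity within a burst. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and the
*relative* behaviour of architectures under controlled signal structure —
not recognition rates attainable on real facial sEMG.

## Views

Ten feature sets are registered; each maps one window to a
(channels × features) image. The named sets are citations whose exact
compositions vary across the literature, so their contents are defined in
one place (`myoview/views.py`) as configuration:

| id | name | contents |
|----|------|----------|
| 1 | Du | IEMG, VAR, WL, ZC, SSC, WAMP |
| 2 | time-domain correlation | autocorrelation lags 1–8 (normalised), zero-lag cross-channel r |
| 3 | Atzori | MAV, VAR, WL, RMS, 10-bin amplitude histogram (±3σ) |
| 4 | Phinyomark 1 | MAV, WL, ZC, SSC, AR(4), MAV-slope (3 segments) |
| 5 | Phinyomark 2 | RMS, WL, median amplitude, spectral moments SM0–SM2 |
| 6 | Doswald | MAV, WL, mean frequency, signal power |
| 7 | DWT (db4, 3 levels) | 4 subband energies + 8 leading coefficients |
| 8 | DWPT (db4, 3 levels) | 8 leaf energies + 8 leading coefficients |
| 9 | CWT (Morlet, 8 log scales) | mean |coefficient| per scale over two window halves |
| 10 | Hudgins | MAV, ZC, SSC, WL |

Threshold-gated counters (ZC, SSC, WAMP) use a scale-proportional threshold
of 1 % of window RMS, which keeps them exactly invariant to amplitude
rescaling. Windows are half-open, 0-based sample ranges; the default
segmentation is 200 ms windows with 50 % overlap, tiled within annotated
intervals only. When several views feed one multiview network their images
are zero-padded on the feature axis to a common width, a requirement of
channel-axis fusion.

## Architectures

All layers run on a small numpy engine with manual backpropagation
(`myoview/nn.py`): 'same'-padded convolutions and locally connected layers
(untied weights per spatial position) via a shared im2col, dense layers,
batch normalization, inverted dropout and Adam. Feature images here are a
few dozen values, so CPU training takes seconds; no GPU framework is
needed or used.

**Branch** (per view): conv → conv → locally-connected → locally-connected
→ fully-connected, every hidden layer as linear → batch norm → ReLU, with
dropout after layer 4. Reference widths are 64 kernels (3×3 conv, 1×1
locally connected) and 512 fully connected units; experiments at desk
scale use `NetworkSpec.small` (8 kernels, 32 units).

**Dual aggregation**: the pre-aggregation subnetwork concatenates the
first-conv-layer features H¹ of all branches along the feature-map axis,
applies ReLU at the fusion point, then conv / 2× locally-connected /
2× FC-512 / G-way FC / softmax, with dropout after its 3rd and 4th layers.
The post-aggregation subnetwork concatenates the FC outputs H⁵ (width
V·512), then FC-512 / G-way FC / softmax. The decision layer adds the two
softmax vectors without renormalization; prediction is the argmax with
ties resolved to the lowest class index (renormalizing by 2 cannot change
the argmax, so the sum is kept literal).

Open points resolved as implementation choices: the fusion operator is
concatenation (preserves all per-view information and matches the fused
widths the layer tables imply for arbitrary V); hidden-layer order is
linear → batch norm → ReLU (the conventional order; which order the
original implementation used is not recoverable); the class-count output
layer carries neither batch norm nor activation since it feeds the
softmax; dropout rate 0.5 at reference scale.

**Baselines**: single-view (one branch + G-way head; "spliced" mode
concatenates all view images feature-wise into one input);
pooling-of-view (elementwise max — or mean — across the view axis at a
configurable layer, default after the branch FC, with a second FC before
the head; pooling at an image layer requires equal view layouts);
decision fusion (per-branch softmax heads, averaged).

## Training protocol

Adam (lr 10⁻³), batch 32, up to 100 epochs with early stopping (patience
10) on validation accuracy; the best-validation parameters *and
batch-norm running moments* are restored at the end. Data are split
60/20/20 **by trial** with per-class stratification, so overlapping
windows never straddle splits; per-feature standardization is fit on the
training split only. Multi-head models (multiview, decision fusion) train
all heads jointly with equal cross-entropy weights, mirroring the
symmetric role the decision layer gives them. All randomness flows from
explicit seeds; identical configuration reproduces runs bit-exactly.

## The complementary-views preset

The architecture comparison runs on a fixed synthetic condition designed
so no single view sees everything: three gestures where classes 0 and 1
differ only in burst amplitude (10 vs 13 μV, invisible to the
scale-invariant correlation view), classes 0 and 2 differ only in
passband (20–150 vs 50–200 Hz, weakly visible to amplitude-centric
features), duty cycle 0.8, 6 μV broadband noise, 20 one-second trials per
class, views 2/3/7. At desk scale (8-kernel, 32-unit networks, 40 epochs,
5 seeds on shared splits) the multiview network reliably exceeds the best
single view by ~2–3 accuracy points; its margin over the
decision-fusion-only baseline is smaller (fractions of a point) and can
invert for individual seed sets. The comparison is directional only —
absolute accuracies on this generator say nothing about real facial sEMG.

## Clinical statistics

- RMS = √(mean x²).
- Spectra via Welch (Hann window, 256-sample segments, 50 % overlap) —
  the spectral estimator of the original acquisition software is
  proprietary, so a standard consistent estimator is used.
- MF: cumulative power reaches half the total, with linear interpolation
  inside the crossing bin (removes bin-width bias; always within one bin
  of the exhaustive cumulative scan). MPF: Σf·P(f)/ΣP(f).
- H-B summaries: counts over (recovered, markedly effective, effective,
  ineffective); total effective rate = 100·(n − ineffective)/n, rounded
  half-up to two decimals.
- Group comparisons: Welch t-test for means (pooled-variance optional);
  Pearson chi-square without Yates continuity correction (flag available)
  on the dichotomized effective/ineffective 2×2 table. On the reported
  outcome counts (59/11 vs 75/5) this statistic is 3.509 with p ≈ 0.061 —
  just above α = 0.05; which exact test variant or grouping the original
  analysis used is not recoverable, so the package reports the computed
  statistic and verdict without asserting agreement. "Mean RMS" per group
  is averaged across patients.

The cohort simulator draws H-B categories from per-arm multinomials and
RMS/MF/MPF from zero-truncated Gaussians (physical non-negativity) per
muscle and timepoint. Post-treatment defaults use the reported group
means/SDs (e.g. buccinator RMS 24.67 ± 2.4 μV treatment vs 18.42 ± 2.4
control, n = 80/70); pre-treatment means are not separately reported and
are set below both arms' post values, consistent with the reported
within-group improvement. At these parameters the effect is ~2.6 SDs, and
the Welch t-test rejects in ≈100 % of simulated cohorts — a
parameter-level power statement, not a reanalysis of patient data.

## Numerical choices and degenerate inputs

Softmax is computed with max subtraction; probability-vector invariants
are enforced at 10⁻⁶. He-normal initialization, batch-norm ε = 10⁻⁵,
momentum 0.1. Zero-variance features standardize to zero (SD clamped to
1). Zero-power spectra, empty signals, empty test splits, ragged CSV rows,
probability vectors off by >10⁻⁹, and passbands outside (0, fs/2) all
raise descriptive errors; a NaN training loss aborts with a diagnostic
rather than continuing. Windows longer than every annotated interval
produce a warning and an empty window list rather than an error.

## Problem sizes

The shipped experiments use 20 one-second trials per class (420 windows),
8-kernel/32-unit networks and 5 seeds for comparisons, 500 replicates for
the power check, and 10 s signals for spectral closed forms. These sizes
were chosen so a full test run plus the acceptance script completes in a
few minutes on a single CPU while leaving every qualitative conclusion
stable across seeds.

## Known limitations

- The numpy engine is single-threaded per matrix product and unsuitable
  for image-scale inputs; it exists because the feature images are tiny.
- Locally connected layers at reference width (64 kernels per position)
  are parameter-hungry; at desk scale this is irrelevant.
- The H-B grading rubric itself (from raw examination) is out of scope;
  only the four-category summary statistics are implemented.
- Absolute recognition accuracies on real facial sEMG are not reproducible
  from synthetic data and are not claimed.
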