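# myoview

Multiview convolutional networks for surface-EMG (sEMG) facial-gesture
recognition, together with the clinical observation indexes — RMS, median
frequency (MF), mean power frequency (MPF) and House-Brackmann (H-B)
effective rates — used to evaluate treatments for peripheral facial
paralysis. Everything runs end-to-end on seeded synthetic data, so no
patient recordings are required.

## Who this is for

Researchers in myoelectric pattern recognition and clinical
electrophysiology who want a reproducible, dependency-light reference
implementation of (a) feature-level *multiview* fusion of classical sEMG
feature sets and (b) the standard efficacy statistics of two-arm sEMG
treatment studies.

## The model

An sEMG analysis window is rendered into several *views*: 2-D feature
images, one per named feature set (Hudgins, Du, Atzori, Phinyomark 1/2,
Doswald, time-domain correlation, DWT/DWPT/CWT wavelet coefficients), with
channels as rows and features as columns. A multistream network gives each
view its own branch — two convolutional layers, two locally connected
layers and one fully connected layer; writing `Hᵢʲ` for the output of
branch `i` at hidden layer `j`, two aggregation subnetworks classify the
fused features

```
H_input-pre-fusion  = θ( fuse_F( Hᵢ¹ ) )      (first conv layer,  i = 1..V)
H_input-post-fusion = θ( fuse_F( Hᵢ⁵ ) )      (first FC layer,    i = 1..V)
```

where `fuse_F` is concatenation and `θ` is ReLU. Each subnetwork ends in a
softmax, giving `y_pre-fusion` and `y_post-fusion`, and the decision layer
adds them:

```
y_final = y_pre-fusion + y_post-fusion ,     class = argmax(y_final).
```

Comparison baselines: a single-view network (optionally fed spliced
multiview input), pooling-of-view aggregation (elementwise max across the
view axis) and decision-fusion aggregation (per-branch softmax vectors
averaged). The layers are implemented on a small numpy engine with manual
backpropagation (`myoview.nn`) — the feature images are tiny, so CPU numpy
trains every architecture in seconds.

The clinical side: `rms`, `power_spectrum` (Welch), `median_frequency`,
`mean_power_frequency`, H-B category summaries with the total effective
rate `100·(n − ineffective)/n`, Welch t-tests for group means and the
Pearson chi-square for effective rates at α = 0.05.

## Worked example

```python
import numpy as np
from myoview import (NetworkSpec, MultiViewNetwork, TrainConfig,
                     train, evaluate_result, summarize_counts, compare_groups)
from myoview.presets import make_dataset

ds = make_dataset(n_trials_per_class=20, seed=0)   # 3 gestures, 3 views
spec = NetworkSpec.small(ds.n_classes, ds.view_shapes)
res = train(MultiViewNetwork(spec, seed=0), ds, TrainConfig(epochs=40, patience=8))
print(f"multiview test accuracy: {evaluate_result(res).accuracy:.3f}")

ctrl, trt = summarize_counts((39, 17, 3, 11)), summarize_counts((51, 15, 9, 5))
print(ctrl.effective_rate, trt.effective_rate)
print(compare_groups(ctrl, trt, kind="rate"))
```

prints

```
multiview test accuracy: 0.976
84.29 93.75
TestReport(kind='rate', statistic=3.5093787…, df=1.0, p_value=0.0610…,
           alpha=0.05, significant=False)
```

i.e. the multiview network separates the three synthetic gestures almost
perfectly on held-out trials; the two study arms have total effective rates
of 84.29 % and 93.75 %; and the dichotomized 2×2 chi-square statistic is
3.51 (p ≈ 0.061 without continuity correction — the verdict at this exact
test variant sits just above the 0.05 boundary, see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
myoview run --seed 3 --out run/          # simulate → featurize → train → evaluate → clinstats
myoview simulate-cohort --seed 1 --out cohort.csv
myoview clinstats --cohort cohort.csv
```

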