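"""Training, evaluation and architecture comparison on multiview datasets.

Datasets are split *by trial*: all windows cut from one trial land in the
same split, so overlapping windows can never leak between train and test.
Per-feature standardization is fit on the training split only.  Both
aggregation heads of the multiview network are trained jointly with equal
cross-entropy weights, mirroring the symmetric role the decision layer
gives them; the comparison baselines train their own heads the same way.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .networks import NetworkBase, make_optimizer
from .nn import cross_entropy
from .views import MultiViewSample


@dataclass
class MultiViewDataset:
    """Arrays-of-views container: ``xs[v]`` is (N, 1, H_v, W_v), plus labels
    and the originating trial of every window."""

    xs: list[np.ndarray]
    y: np.ndarray
    trial_ids: np.ndarray
    view_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        for v, x in enumerate(self.xs):
            if x.shape[0] != n:
                raise ValueError(f"view {v} has {x.shape[0]} samples, labels {n}")
        if self.trial_ids.shape[0] != n:
            raise ValueError("trial_ids must align with labels")

    def __len__(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    @property
    def view_shapes(self) -> tuple[tuple[int, int], ...]:
        return tuple(x.shape[2:] for x in self.xs)

    def subset(self, idx: np.ndarray) -> "MultiViewDataset":
        return MultiViewDataset(
            xs=[x[idx] for x in self.xs],
            y=self.y[idx],
            trial_ids=self.trial_ids[idx],
            view_ids=self.view_ids,
        )

    @staticmethod
    def from_samples(
        samples: list[MultiViewSample],
        view_ids: tuple[int, ...],
        pad_to_common: bool = True,
    ) -> "MultiViewDataset":
        """Stack multiview samples into arrays.

        ``pad_to_common`` zero-pads every view image on the feature axis to
        the widest selected view, giving all branches a common layout (a
        requirement of channel-axis feature fusion and of pooling across
        views at image layers).
        """
        if not samples:
            raise ValueError("empty sample list")
        n_views = len(samples[0].images)
        xs = []
        for v in range(n_views):
            imgs = [s.images[v].values for s in samples]
            xs.append(np.stack(imgs)[:, None])
        if pad_to_common:
            w_max = max(x.shape[3] for x in xs)
            xs = [
                np.pad(x, ((0, 0), (0, 0), (0, 0), (0, w_max - x.shape[3])))
                for x in xs
            ]
        return MultiViewDataset(
            xs=xs,
            y=np.array([s.class_id for s in samples], dtype=int),
            trial_ids=np.array([s.trial_id for s in samples], dtype=int),
            view_ids=tuple(view_ids),
        )


@dataclass(frozen=True)
class Split:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def hash(self) -> str:
        h = hashlib.sha256()
        for part in (self.train, self.val, self.test):
            h.update(np.ascontiguousarray(np.sort(part)).tobytes())
        return h.hexdigest()[:16]


def split_by_trial(
    ds: MultiViewDataset,
    fractions: tuple[float, float, float],
    seed: int,
) -> Split:
    """Disjoint train/val/test window indices, allocated at trial level with
    per-class stratification so every split stays class-balanced."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    buckets: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    trials = np.unique(ds.trial_ids)
    trial_class = {
        t: int(ds.y[ds.trial_ids == t][0]) for t in trials
    }
    for cls in sorted(set(trial_class.values())):
        cls_trials = np.array([t for t in trials if trial_class[t] == cls])
        rng.shuffle(cls_trials)
        n = cls_trials.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts = {
            "train": cls_trials[:n_train],
            "val": cls_trials[n_train : n_train + n_val],
            "test": cls_trials[n_train + n_val :],
        }
        for name, tset in parts.items():
            mask = np.isin(ds.trial_ids, tset)
            buckets[name].extend(np.nonzero(mask)[0].tolist())
    return Split(
        train=np.array(sorted(buckets["train"]), dtype=int),
        val=np.array(sorted(buckets["val"]), dtype=int),
        test=np.array(sorted(buckets["test"]), dtype=int),
    )


def audit_split(ds: MultiViewDataset, split: Split) -> bool:
    """True iff no trial contributes windows to more than one split."""
    sets = [set(ds.trial_ids[idx]) for idx in (split.train, split.val, split.test)]
    return (not (sets[0] & sets[1]) and not (sets[0] & sets[2])
            and not (sets[1] & sets[2]))


@dataclass
class Standardizer:
    """Per-view, per-pixel mean/SD scaling fit on the training split only."""

    means: list[np.ndarray]
    stds: list[np.ndarray]

    @staticmethod
    def fit(ds: MultiViewDataset, idx: np.ndarray) -> "Standardizer":
        means, stds = [], []
        for x in ds.xs:
            m = x[idx].mean(axis=0)
            s = x[idx].std(axis=0)
            s[s == 0] = 1.0
            means.append(m)
            stds.append(s)
        return Standardizer(means, stds)

    def apply(self, xs: list[np.ndarray]) -> list[np.ndarray]:
        return [(x - m) / s for x, m, s in zip(xs, self.means, self.stds)]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are sized for desk-scale CPU runs."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int | None = None

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch size must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class EvalReport:
    """Test accuracy and G×G confusion matrix (rows = true class)."""

    accuracy: float
    confusion: np.ndarray
    arch: str
    seed: int

    def __post_init__(self) -> None:
        total = int(self.confusion.sum())
        trace = int(np.trace(self.confusion))
        if total and abs(self.accuracy - trace / total) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion matrix")


@dataclass
class TrainResult:
    model: NetworkBase
    history: list[dict]
    split: Split
    standardizer: Standardizer
    dataset: MultiViewDataset


def _snapshot(model: NetworkBase) -> list[np.ndarray]:
    state = [p.value.copy() for p in model.parameters()]
    for bn in model.batch_norms():
        state += [bn.running_mean.copy(), bn.running_var.copy()]
    return state


def _restore(model: NetworkBase, snap: list[np.ndarray]) -> None:
    params = model.parameters()
    for p, v in zip(params, snap):
        p.value[...] = v
    rest = snap[len(params):]
    for i, bn in enumerate(model.batch_norms()):
        bn.running_mean[...] = rest[2 * i]
        bn.running_var[...] = rest[2 * i + 1]


def train(model: NetworkBase, ds: MultiViewDataset, cfg: TrainConfig) -> TrainResult:
    """Train with Adam and early stopping on validation accuracy.

    The loss is the sum of mean cross-entropies over all classifier heads.
    The best-validation parameters are restored at the end.  Identical
    config + seeds reproduce the run exactly.
    """
    split = split_by_trial(ds, cfg.split_fractions, cfg.split_seed
                           if cfg.split_seed is not None else cfg.seed)
    std = Standardizer.fit(ds, split.train)
    xs_all = std.apply(ds.xs)
    opt = make_optimizer(model, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 10_000)
    history: list[dict] = []
    best_val, best_snap, since_best = -np.inf, _snapshot(model), 0

    def batch_views(idx):
        return [x[idx] for x in xs_all]

    for epoch in range(cfg.epochs):
        order = split.train.copy()
        rng.shuffle(order)
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.heads(batch_views(idx), train=True)
            opt.zero_grad()
            dheads, loss = {}, 0.0
            for name, lg in logits.items():
                l, dl = cross_entropy(lg, ds.y[idx])
                loss += l
                dheads[name] = dl
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate"
                )
            model.backward(dheads)
            opt.step()
            epoch_loss += loss * idx.size
        epoch_loss /= order.size
        val_idx = split.val if split.val.size else split.train
        val_acc = float(
            np.mean(model.predict(batch_views(val_idx)) == ds.y[val_idx])
        )
        history.append({"epoch": epoch, "loss": epoch_loss, "val_acc": val_acc})
        if val_acc > best_val:
            best_val, best_snap, since_best = val_acc, _snapshot(model), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    _restore(model, best_snap)
    return TrainResult(model, history, split, std, ds)


def evaluate(
    model: NetworkBase,
    ds: MultiViewDataset,
    idx: np.ndarray,
    standardizer: Standardizer | None = None,
    seed: int = 0,
) -> EvalReport:
    """Accuracy and confusion matrix on the given (test) indices."""
    if idx.size == 0:
        raise ValueError("empty test split")
    xs = [x[idx] for x in ds.xs]
    if standardizer is not None:
        xs = standardizer.apply(xs)
    pred = model.predict(xs)
    true = ds.y[idx]
    g = ds.n_classes
    confusion = np.zeros((g, g), dtype=int)
    np.add.at(confusion, (true, pred), 1)
    return EvalReport(
        accuracy=float(np.mean(pred == true)),
        confusion=confusion,
        arch=model.arch,
        seed=seed,
    )


def evaluate_result(res: TrainResult) -> EvalReport:
    return evaluate(res.model, res.dataset, res.split.test, res.standardizer,
                    seed=res.model.seed)


def compare_architectures(
    ds: MultiViewDataset,
    builders: dict[str, callable],
    n_seeds: int = 5,
    cfg: TrainConfig | None = None,
    base_seed: int = 0,
):
    """Train every architecture across seeds on identical trial-level splits.

    ``builders`` maps an architecture label to ``callable(seed) -> model``.
    Returns a pandas DataFrame with per-architecture mean ± SD test accuracy
    and the shared split hash per replicate.
    """
    import pandas as pd

    if n_seeds < 3:
        raise ValueError("need at least 3 seeds for a mean ± SD comparison")
    cfg = cfg or TrainConfig()
    rows = []
    for name, build in builders.items():
        accs, split_hashes = [], []
        for rep in range(n_seeds):
            seed = base_seed + rep
            run_cfg = replace(cfg, seed=seed, split_seed=base_seed + 90_000 + rep)
            model = build(seed)
            res = train(model, ds, run_cfg)
            rep_eval = evaluate_result(res)
            accs.append(rep_eval.accuracy)
            split_hashes.append(res.split.hash())
        rows.append(
            {
                "arch": name,
                "mean_acc": float(np.mean(accs)),
                "sd_acc": float(np.std(accs, ddof=1)),
                "accs": tuple(accs),
                "split_hashes": tuple(split_hashes),
            }
        )
    return pd.DataFrame(rows)
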