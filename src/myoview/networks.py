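"""Multiview network architectures and fusion operations.

The flagship architecture is a multistream convolutional network: one
branch per view (two convolutional layers, two locally connected layers,
one fully connected layer), plus a multiview aggregation network made of
two subnetworks.  The *pre-aggregation* subnetwork fuses the branch
features taken after the first convolutional layer (H¹) by concatenation
along the feature-map axis, applies a ReLU at the fusion point, and runs a
conv / locally-connected / fully-connected stack ending in a softmax; the
*post-aggregation* subnetwork fuses the first fully-connected outputs (H⁵)
by vector concatenation and runs two fully connected layers into a second
softmax.  The two class-probability vectors are combined at the decision
layer by elementwise addition (no renormalization); the predicted class is
the argmax, ties resolved toward the lowest index.

Three comparison architectures are provided: a single-view network (one
branch plus classifier head, optionally fed spliced multiview input),
pooling-of-view aggregation (elementwise max/mean across the view axis at a
configurable layer), and decision-fusion aggregation (per-branch softmax
heads averaged).

Every hidden layer is linear → batch norm → ReLU; dropout follows branch
layer 4 and pre-aggregation layers 3 and 4.  The class-count output layer
has neither batch norm nor activation (it feeds the softmax directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LocallyConnected2D,
    Param,
    ReLU,
    Sequential,
    softmax,
)
from .views import MultiViewSample


@dataclass(frozen=True)
class LayerSpec:
    """One layer of an architecture table."""

    kind: str  # convolutional | locally-connected | fully-connected | softmax
    kernel_size: int | None = None
    units: int | None = None
    activation: bool = True
    batch_norm: bool = True
    dropout: float = 0.0

    def __post_init__(self) -> None:
        kinds = {"convolutional", "locally-connected", "fully-connected", "softmax"}
        if self.kind not in kinds:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("convolutional", "locally-connected"):
            if not self.kernel_size or self.kernel_size <= 0:
                raise ValueError(f"{self.kind} layer needs a positive kernel size")
        if self.kind != "softmax" and (not self.units or self.units <= 0):
            raise ValueError(f"{self.kind} layer needs a positive unit count")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters shared by all architectures.

    ``view_shapes`` lists the (channels, features) layout of each selected
    view; the branch count V is its length.  Defaults follow the reference
    architecture tables: 3×3 convolutions with 64 kernels, 1×1 locally
    connected layers with 64 kernels, 512-unit fully connected layers,
    dropout 0.5.
    """

    n_classes: int
    view_shapes: tuple[tuple[int, int], ...]
    conv_channels: int = 64
    kernel_size: int = 3
    lc_kernel_size: int = 1
    fc_units: int = 512
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.view_shapes) < 1:
            raise ValueError("need at least one view shape")

    @property
    def n_views(self) -> int:
        return len(self.view_shapes)

    def branch_layers(self) -> list[LayerSpec]:
        """The five branch hidden layers (H¹ … H⁵)."""
        k, lk, c, u, d = (self.kernel_size, self.lc_kernel_size,
                          self.conv_channels, self.fc_units, self.dropout)
        return [
            LayerSpec("convolutional", kernel_size=k, units=c),
            LayerSpec("convolutional", kernel_size=k, units=c),
            LayerSpec("locally-connected", kernel_size=lk, units=c),
            LayerSpec("locally-connected", kernel_size=lk, units=c, dropout=d),
            LayerSpec("fully-connected", units=u),
        ]

    def preagg_layers(self) -> list[LayerSpec]:
        k, lk, c, u, d = (self.kernel_size, self.lc_kernel_size,
                          self.conv_channels, self.fc_units, self.dropout)
        return [
            LayerSpec("convolutional", kernel_size=k, units=c),
            LayerSpec("locally-connected", kernel_size=lk, units=c),
            LayerSpec("locally-connected", kernel_size=lk, units=c, dropout=d),
            LayerSpec("fully-connected", units=u, dropout=d),
            LayerSpec("fully-connected", units=u),
            LayerSpec("fully-connected", units=self.n_classes,
                      activation=False, batch_norm=False),
            LayerSpec("softmax"),
        ]

    def postagg_layers(self) -> list[LayerSpec]:
        return [
            LayerSpec("fully-connected", units=self.fc_units),
            LayerSpec("fully-connected", units=self.n_classes,
                      activation=False, batch_norm=False),
            LayerSpec("softmax"),
        ]

    @staticmethod
    def small(n_classes: int, view_shapes, conv_channels: int = 8,
              fc_units: int = 32, dropout: float = 0.25) -> "NetworkSpec":
        """Desk-scale spec for CPU experiments on synthetic data."""
        return NetworkSpec(
            n_classes=n_classes,
            view_shapes=tuple(tuple(s) for s in view_shapes),
            conv_channels=conv_channels,
            fc_units=fc_units,
            dropout=dropout,
        )


@dataclass(frozen=True)
class ClassProbabilities:
    """A class-probability vector tagged by its origin.

    Pre- and post-fusion vectors are softmax outputs (sum 1); the final
    vector is their elementwise sum (sum 2, unnormalized by design).
    """

    y: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if self.tag not in ("pre-fusion", "post-fusion", "final", "averaged"):
            raise ValueError(f"unknown tag {self.tag!r}")
        if np.any(y < -1e-9):
            raise ValueError("class probabilities must be non-negative")
        expected = 2.0 if self.tag == "final" else 1.0
        if abs(float(y.sum()) - expected) > 1e-6:
            raise ValueError(
                f"{self.tag} vector sums to {float(y.sum())}, expected {expected}"
            )


# --- building blocks --------------------------------------------------------


def _hidden_block(layer, n_units: int, image: bool, dropout: float,
                  drop_rng) -> list:
    block = [layer, BatchNorm(n_units, image=image), ReLU()]
    if dropout > 0:
        block.append(Dropout(dropout, drop_rng))
    return block


def _branch_modules(spec: NetworkSpec, shape: tuple[int, int], rng, drop_rng):
    """The five branch blocks for one view; block 0 produces H¹, the chain
    of blocks 0–4 produces H⁵."""
    h, w = shape
    c, k, lk, u = (spec.conv_channels, spec.kernel_size, spec.lc_kernel_size,
                   spec.fc_units)
    blocks = [
        Sequential(_hidden_block(Conv2D(1, c, k, rng), c, True, 0.0, drop_rng)),
        Sequential(_hidden_block(Conv2D(c, c, k, rng), c, True, 0.0, drop_rng)),
        Sequential(_hidden_block(
            LocallyConnected2D(c, c, lk, (h, w), rng), c, True, 0.0, drop_rng)),
        Sequential(_hidden_block(
            LocallyConnected2D(c, c, lk, (h, w), rng), c, True, spec.dropout,
            drop_rng)),
        Sequential([Flatten()] + _hidden_block(
            Dense(c * h * w, u, rng), u, False, 0.0, drop_rng)),
    ]
    return blocks


def _preagg_module(spec: NetworkSpec, shape: tuple[int, int], rng, drop_rng):
    h, w = shape
    c, k, lk, u = (spec.conv_channels, spec.kernel_size, spec.lc_kernel_size,
                   spec.fc_units)
    v = spec.n_views
    layers = [ReLU()]  # θ applied literally at the fusion point
    layers += _hidden_block(Conv2D(v * c, c, k, rng), c, True, 0.0, drop_rng)
    layers += _hidden_block(LocallyConnected2D(c, c, lk, (h, w), rng), c, True,
                            0.0, drop_rng)
    layers += _hidden_block(LocallyConnected2D(c, c, lk, (h, w), rng), c, True,
                            spec.dropout, drop_rng)
    layers += [Flatten()]
    layers += _hidden_block(Dense(c * h * w, u, rng), u, False, spec.dropout,
                            drop_rng)
    layers += _hidden_block(Dense(u, u, rng), u, False, 0.0, drop_rng)
    layers += [Dense(u, spec.n_classes, rng)]
    return Sequential(layers)


def _postagg_module(spec: NetworkSpec, rng, drop_rng):
    u = spec.fc_units
    layers = [ReLU()]
    layers += _hidden_block(Dense(spec.n_views * u, u, rng), u, False, 0.0,
                            drop_rng)
    layers += [Dense(u, spec.n_classes, rng)]
    return Sequential(layers)


def _check_views(xs, expected_shapes):
    if len(xs) != len(expected_shapes):
        raise ValueError(
            f"expected {len(expected_shapes)} views, got {len(xs)}"
        )
    for i, (x, shape) in enumerate(zip(xs, expected_shapes)):
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != tuple(shape):
            raise ValueError(
                f"view {i}: expected (N, 1, {shape[0]}, {shape[1]}) input, "
                f"got {x.shape}"
            )


class NetworkBase:
    """Shared prediction interface; subclasses define heads and backward."""

    arch: str
    spec: NetworkSpec
    seed: int

    def parameters(self) -> list[Param]:
        raise NotImplementedError

    def components(self) -> list[Sequential]:
        raise NotImplementedError

    def batch_norms(self) -> list[BatchNorm]:
        out = []

        def visit(layer):
            if isinstance(layer, BatchNorm):
                out.append(layer)
            elif isinstance(layer, Sequential):
                for sub in layer.layers:
                    visit(sub)

        for comp in self.components():
            visit(comp)
        return out

    def heads(self, xs: list[np.ndarray], train: bool = False) -> dict[str, np.ndarray]:
        """Forward pass; returns logits per classifier head."""
        raise NotImplementedError

    def backward(self, dheads: dict[str, np.ndarray]) -> None:
        raise NotImplementedError

    def decision_scores(self, xs: list[np.ndarray]) -> np.ndarray:
        """(N, G) decision scores whose argmax is the predicted class."""
        raise NotImplementedError

    def predict(self, xs: list[np.ndarray]) -> np.ndarray:
        return np.argmax(self.decision_scores(xs), axis=1)


class MultiViewNetwork(NetworkBase):
    """Multistream branches + pre/post aggregation + decision fusion."""

    arch = "multiview"

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        shapes = set(spec.view_shapes)
        if len(shapes) > 1:
            raise ValueError(
                "multiview aggregation requires a common view layout; pad the "
                f"views to one shape (got {sorted(shapes)})"
            )
        if spec.n_views < 2:
            raise ValueError("multiview network needs at least 2 views")
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        shape = spec.view_shapes[0]
        self.branches = [
            _branch_modules(spec, shape, rng, self.drop_rng)
            for _ in range(spec.n_views)
        ]
        self.preagg = _preagg_module(spec, shape, rng, self.drop_rng)
        self.postagg = _postagg_module(spec, rng, self.drop_rng)

    def parameters(self):
        ps = []
        for blocks in self.branches:
            for b in blocks:
                ps += b.params()
        return ps + self.preagg.params() + self.postagg.params()

    def components(self):
        return ([b for blocks in self.branches for b in blocks]
                + [self.preagg, self.postagg])

    def _forward_branches(self, xs, train):
        h1, h5 = [], []
        for x, blocks in zip(xs, self.branches):
            h = blocks[0].forward(x, train=train)
            h1.append(h)
            for b in blocks[1:]:
                h = b.forward(h, train=train)
            h5.append(h)
        return h1, h5

    def heads(self, xs, train=False):
        _check_views(xs, self.spec.view_shapes)
        h1, h5 = self._forward_branches(xs, train)
        pre_in = np.concatenate(h1, axis=1)
        post_in = np.concatenate(h5, axis=1)
        self._h1_channels = h1[0].shape[1]
        self._h5_width = h5[0].shape[1]
        return {
            "pre": self.preagg.forward(pre_in, train=train),
            "post": self.postagg.forward(post_in, train=train),
        }

    def backward(self, dheads):
        v = self.spec.n_views
        dpre_in = self.preagg.backward(dheads["pre"])
        dpost_in = self.postagg.backward(dheads["post"])
        dh1_pre = np.split(dpre_in, v, axis=1)
        dh5 = np.split(dpost_in, v, axis=1)
        for i, blocks in enumerate(self.branches):
            d = dh5[i]
            for b in reversed(blocks[1:]):
                d = b.backward(d)
            blocks[0].backward(d + dh1_pre[i])

    def decision_scores(self, xs):
        logits = self.heads(xs, train=False)
        return softmax(logits["pre"]) + softmax(logits["post"])

    # --- the named fusion operations ------------------------------------

    def pre_aggregate(self, h1_list: list[np.ndarray]) -> ClassProbabilities:
        """Fuse first-convolutional-layer features and classify."""
        shapes = {h.shape[2:] for h in h1_list}
        if len(shapes) > 1:
            raise ValueError(f"mismatched spatial shapes at fusion: {shapes}")
        fused = np.concatenate(list(h1_list), axis=1)
        logits = self.preagg.forward(fused, train=False)
        return ClassProbabilities(softmax(logits)[0], "pre-fusion")

    def post_aggregate(self, h5_list: list[np.ndarray]) -> ClassProbabilities:
        """Fuse first-fully-connected-layer features and classify."""
        widths = {h.shape[1] for h in h5_list}
        if len(widths) > 1:
            raise ValueError(f"mismatched feature widths at fusion: {widths}")
        fused = np.concatenate(h5_list, axis=1)
        logits = self.postagg.forward(fused, train=False)
        return ClassProbabilities(softmax(logits)[0], "post-fusion")


class SingleViewNetwork(NetworkBase):
    """One branch plus classifier head; ``mode="spliced"`` concatenates all
    view images feature-wise into one input."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 mode: str = "single-view", view_index: int = 0) -> None:
        if mode not in ("single-view", "spliced-multiview"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.arch = ("single-view" if mode == "single-view"
                     else "spliced-multiview")
        self.view_index = view_index
        self.spec = spec
        self.seed = seed
        if mode == "single-view":
            shape = spec.view_shapes[view_index]
        else:
            rows = {s[0] for s in spec.view_shapes}
            if len(rows) > 1:
                raise ValueError("spliced input needs equal channel rows")
            shape = (spec.view_shapes[0][0], sum(s[1] for s in spec.view_shapes))
        self.input_shape = shape
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        self.blocks = _branch_modules(spec, shape, rng, self.drop_rng)
        self.head = Dense(spec.fc_units, spec.n_classes, rng)

    def parameters(self):
        return [p for b in self.blocks for p in b.params()] + self.head.params()

    def components(self):
        return list(self.blocks)

    def _input(self, xs):
        if self.mode == "single-view":
            x = xs[self.view_index] if isinstance(xs, (list, tuple)) else xs
        else:
            x = np.concatenate(xs, axis=3)
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"expected input shape {self.input_shape}, got {x.shape[2:]}"
            )
        return x

    def heads(self, xs, train=False):
        h = self._input(xs)
        for b in self.blocks:
            h = b.forward(h, train=train)
        return {"logits": self.head.forward(h, train=train)}

    def backward(self, dheads):
        d = self.head.backward(dheads["logits"])
        for b in reversed(self.blocks):
            d = b.backward(d)

    def decision_scores(self, xs):
        return softmax(self.heads(xs, train=False)["logits"])


class PoolingOfViewNetwork(NetworkBase):
    """Aggregation by elementwise reduction across the view axis.

    Per-view (untied) branch blocks run up to ``pool_layer`` (1–6, counting
    the five branch layers plus a second fully connected layer); features
    are then reduced elementwise across views (max by default) and the
    remaining blocks plus the classifier head are shared.  Pooling at a
    convolutional layer requires identical view layouts.
    """

    arch = "pooling-of-view"

    def __init__(self, spec: NetworkSpec, seed: int = 0, pool_layer: int = 5,
                 reducer: str = "max") -> None:
        if not (1 <= pool_layer <= 6):
            raise ValueError("pool_layer must be in 1..6")
        if reducer not in ("max", "mean"):
            raise ValueError(f"unknown reducer {reducer!r}")
        if pool_layer <= 4 and len(set(spec.view_shapes)) > 1:
            raise ValueError("pooling at an image layer requires equal layouts")
        self.spec = spec
        self.seed = seed
        self.pool_layer = pool_layer
        self.reducer = reducer
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        u = spec.fc_units

        def all_blocks(shape):
            blocks = _branch_modules(spec, shape, rng, self.drop_rng)
            blocks.append(Sequential(_hidden_block(
                Dense(u, u, rng), u, False, 0.0, self.drop_rng)))  # second FC
            return blocks

        self.per_view = [
            all_blocks(shape)[:pool_layer] for shape in spec.view_shapes
        ]
        shared_shape = spec.view_shapes[0]
        self.shared = all_blocks(shared_shape)[pool_layer:]
        self.head = Dense(u, spec.n_classes, rng)

    def parameters(self):
        ps = [p for blocks in self.per_view for b in blocks for p in b.params()]
        ps += [p for b in self.shared for p in b.params()]
        return ps + self.head.params()

    def components(self):
        return ([b for blocks in self.per_view for b in blocks]
                + list(self.shared))

    def _reduce(self, stacked):
        if self.reducer == "max":
            self._argmax = np.argmax(stacked, axis=0)
            return np.max(stacked, axis=0)
        return np.mean(stacked, axis=0)

    def _reduce_backward(self, d):
        v = len(self.per_view)
        if self.reducer == "max":
            out = np.zeros((v,) + d.shape)
            grid = np.ogrid[tuple(slice(s) for s in d.shape)]
            out[(self._argmax,) + tuple(grid)] = d
            return out
        return np.repeat(d[None] / v, v, axis=0)

    def heads(self, xs, train=False):
        _check_views(xs, self.spec.view_shapes)
        feats = []
        for x, blocks in zip(xs, self.per_view):
            h = x
            for b in blocks:
                h = b.forward(h, train=train)
            feats.append(h)
        shapes = {f.shape for f in feats}
        if len(shapes) > 1:
            raise ValueError(f"mismatched shapes at the pooling point: {shapes}")
        h = self._reduce(np.stack(feats, axis=0))
        for b in self.shared:
            h = b.forward(h, train=train)
        return {"logits": self.head.forward(h, train=train)}

    def backward(self, dheads):
        d = self.head.backward(dheads["logits"])
        for b in reversed(self.shared):
            d = b.backward(d)
        dviews = self._reduce_backward(d)
        for dv, blocks in zip(dviews, self.per_view):
            g = dv
            for b in reversed(blocks):
                g = b.backward(g)

    def decision_scores(self, xs):
        return softmax(self.heads(xs, train=False)["logits"])


class DecisionFusionNetwork(NetworkBase):
    """Per-branch softmax heads; the class-probability vectors are averaged
    at the decision layer."""

    arch = "decision-fusion"

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        self.branches = [
            _branch_modules(spec, shape, rng, self.drop_rng)
            for shape in spec.view_shapes
        ]
        self.heads_fc = [
            Dense(spec.fc_units, spec.n_classes, rng)
            for _ in range(spec.n_views)
        ]

    def parameters(self):
        ps = [p for blocks in self.branches for b in blocks for p in b.params()]
        for h in self.heads_fc:
            ps += h.params()
        return ps

    def components(self):
        return [b for blocks in self.branches for b in blocks]

    def heads(self, xs, train=False):
        _check_views(xs, self.spec.view_shapes)
        out = {}
        for i, (x, blocks) in enumerate(zip(xs, self.branches)):
            h = x
            for b in blocks:
                h = b.forward(h, train=train)
            out[f"branch{i}"] = self.heads_fc[i].forward(h, train=train)
        return out

    def backward(self, dheads):
        for i, blocks in enumerate(self.branches):
            d = self.heads_fc[i].backward(dheads[f"branch{i}"])
            for b in reversed(blocks):
                d = b.backward(d)

    def decision_scores(self, xs):
        logits = self.heads(xs, train=False)
        probs = [softmax(v) for v in logits.values()]
        return np.mean(probs, axis=0)


# --- module-level operations ------------------------------------------------


def build_network(spec: NetworkSpec, seed: int = 0) -> MultiViewNetwork:
    """Build the multistream + dual-aggregation network with seeded init."""
    return MultiViewNetwork(spec, seed=seed)


def build_single_view(spec: NetworkSpec, seed: int = 0,
                      mode: str = "single-view",
                      view_index: int = 0) -> SingleViewNetwork:
    return SingleViewNetwork(spec, seed=seed, mode=mode, view_index=view_index)


def pre_aggregate(model: MultiViewNetwork,
                  h1_list: list[np.ndarray]) -> ClassProbabilities:
    return model.pre_aggregate(h1_list)


def post_aggregate(model: MultiViewNetwork,
                   h5_list: list[np.ndarray]) -> ClassProbabilities:
    return model.post_aggregate(h5_list)


def decision_fuse(
    y_pre: ClassProbabilities, y_post: ClassProbabilities
) -> tuple[ClassProbabilities, int]:
    """Elementwise sum of the two fusion heads; argmax decides, ties going
    to the lowest class index.  The sum is deliberately not renormalized."""
    if y_pre.y.shape != y_post.y.shape:
        raise ValueError(
            f"length mismatch: {y_pre.y.shape} vs {y_post.y.shape}"
        )
    y_final = ClassProbabilities(y_pre.y + y_post.y, "final")
    return y_final, int(np.argmax(y_final.y))


def forward_multiview(
    sample: MultiViewSample, model: MultiViewNetwork,
    standardizer=None,
) -> tuple[ClassProbabilities, int]:
    """Run one multiview sample through branches, both aggregation heads and
    decision fusion (inference mode: dropout off, running batch-norm stats)."""
    xs = [img.values[None, None] for img in sample.images]
    if standardizer is not None:
        xs = standardizer.apply(xs)
    logits = model.heads(xs, train=False)
    y_pre = ClassProbabilities(softmax(logits["pre"])[0], "pre-fusion")
    y_post = ClassProbabilities(softmax(logits["post"])[0], "post-fusion")
    return decision_fuse(y_pre, y_post)


def aggregate_pooling_of_view(features: list[np.ndarray],
                              reducer: str = "max") -> np.ndarray:
    """Elementwise reduction of per-view feature arrays across the view axis."""
    shapes = {np.asarray(f).shape for f in features}
    if len(shapes) != 1:
        raise ValueError(f"mismatched feature shapes: {shapes}")
    stacked = np.stack([np.asarray(f, dtype=float) for f in features], axis=0)
    if reducer == "max":
        return np.max(stacked, axis=0)
    if reducer == "mean":
        return np.mean(stacked, axis=0)
    raise ValueError(f"unknown reducer {reducer!r}")


def aggregate_decision_fusion(
    prob_vectors: list[np.ndarray],
) -> ClassProbabilities:
    """Average per-branch softmax vectors into one decision vector."""
    arrs = [np.asarray(p, dtype=float) for p in prob_vectors]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"mismatched probability-vector shapes: {shapes}")
    for a in arrs:
        if abs(float(a.sum()) - 1.0) > 1e-6:
            raise ValueError("branch outputs must be softmax vectors (sum 1)")
    return ClassProbabilities(np.mean(arrs, axis=0), "averaged")


def make_optimizer(model: NetworkBase, lr: float = 1e-3) -> Adam:
    return Adam(model.parameters(), lr=lr)
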