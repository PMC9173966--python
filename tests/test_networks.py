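"""Architecture wiring and fusion algebra, including the explicit
matrix-arithmetic oracle on a 2-view, 2-class, 2-unit toy network."""

import numpy as np
import pytest

from myoview import networks as N
from myoview.nn import Conv2D, Dense, LocallyConnected2D, Sequential, softmax

from conftest import set_identity_batchnorm


def _fill_weights(model, seed=0, scale=0.8):
    """Deterministically hand-set every non-batch-norm parameter."""
    rng = np.random.default_rng(seed)
    for p in model.parameters():
        if not p.name.startswith("bn"):
            p.value[...] = scale * rng.standard_normal(p.value.shape)
    set_identity_batchnorm(model)


def _chain(blocks):
    """Extract the (weight, bias) pairs of a block chain on 1×1 images, in
    application order, so the oracle can replay them as plain matrix math."""
    pairs = []
    for block in blocks:
        seq = block.layers if isinstance(block, Sequential) else [block]
        for layer in seq:
            if isinstance(layer, Conv2D):
                pairs.append((layer.w.value, layer.b.value))
            elif isinstance(layer, LocallyConnected2D):
                pairs.append((layer.w.value[0], layer.b.value[0]))
            elif isinstance(layer, Dense):
                pairs.append((layer.w.value, layer.b.value))
    return pairs


def _relu_chain(h, pairs, final_linear=True):
    for i, (w, b) in enumerate(pairs):
        h = h @ w + b
        if not (final_linear and i == len(pairs) - 1):
            h = np.maximum(h, 0.0)
    return h


def _softmax1(z):
    e = np.exp(z - z.max())
    return e / e.sum()


class TestToyNetworkOracle:
    """Hand-set weights vs explicit matrix arithmetic, all architectures."""

    def _inputs(self):
        rng = np.random.default_rng(42)
        return [rng.standard_normal((1, 1, 1, 1)) for _ in range(2)]

    def test_multiview_matches_explicit_arithmetic(self, toy_spec):
        m = N.MultiViewNetwork(toy_spec, seed=0)
        _fill_weights(m)
        xs = self._inputs()

        h1, h5 = [], []
        for x, blocks in zip(xs, m.branches):
            w1, b1 = _chain([blocks[0]])[0]
            h1_i = np.maximum(x.reshape(1, -1) @ w1 + b1, 0.0)
            h1.append(h1_i)
            h5.append(_relu_chain(h1_i, _chain(blocks[1:]), final_linear=False))

        pre_in = np.maximum(np.concatenate(h1, axis=1), 0.0)
        logits_pre = _relu_chain(pre_in, _chain([m.preagg]))
        post_in = np.maximum(np.concatenate(h5, axis=1), 0.0)
        logits_post = _relu_chain(post_in, _chain([m.postagg]))
        expected = _softmax1(logits_pre[0]) + _softmax1(logits_post[0])

        got = m.decision_scores(xs)[0]
        assert np.allclose(got, expected, atol=1e-6)
        assert got.sum() == pytest.approx(2.0, abs=1e-6)

    def test_single_view_matches_explicit_arithmetic(self, toy_spec):
        m = N.SingleViewNetwork(toy_spec, seed=0, view_index=0)
        _fill_weights(m)
        xs = self._inputs()
        pairs = _chain(m.blocks) + [(m.head.w.value, m.head.b.value)]
        logits = _relu_chain(xs[0].reshape(1, -1), pairs)
        assert np.allclose(m.decision_scores(xs)[0], _softmax1(logits[0]),
                           atol=1e-6)

    def test_pooling_of_view_matches_explicit_arithmetic(self, toy_spec):
        m = N.PoolingOfViewNetwork(toy_spec, seed=0, pool_layer=5, reducer="max")
        _fill_weights(m)
        xs = self._inputs()
        feats = [
            _relu_chain(x.reshape(1, -1), _chain(blocks), final_linear=False)
            for x, blocks in zip(xs, m.per_view)
        ]
        pooled = np.maximum(feats[0], feats[1])
        h = _relu_chain(pooled, _chain(m.shared), final_linear=False)
        logits = h @ m.head.w.value + m.head.b.value
        assert np.allclose(m.decision_scores(xs)[0], _softmax1(logits[0]),
                           atol=1e-6)

    def test_decision_fusion_matches_explicit_arithmetic(self, toy_spec):
        m = N.DecisionFusionNetwork(toy_spec, seed=0)
        _fill_weights(m)
        xs = self._inputs()
        probs = []
        for x, blocks, head in zip(xs, m.branches, m.heads_fc):
            h = _relu_chain(x.reshape(1, -1), _chain(blocks), final_linear=False)
            probs.append(_softmax1((h @ head.w.value + head.b.value)[0]))
        assert np.allclose(m.decision_scores(xs)[0], np.mean(probs, axis=0),
                           atol=1e-6)


class TestNetworkSpec:
    def test_postaggregation_has_two_weight_layers_before_softmax(self):
        spec = N.NetworkSpec(n_classes=4, view_shapes=((2, 14),) * 3)
        layers = spec.postagg_layers()
        assert [l.kind for l in layers] == [
            "fully-connected", "fully-connected", "softmax"
        ]
        assert layers[0].units == 512
        assert layers[1].units == 4

    def test_branch_has_five_hidden_layers_with_dropout_after_fourth(self):
        spec = N.NetworkSpec(n_classes=4, view_shapes=((2, 14),) * 3)
        layers = spec.branch_layers()
        assert [l.kind for l in layers] == [
            "convolutional", "convolutional", "locally-connected",
            "locally-connected", "fully-connected",
        ]
        assert [l.dropout > 0 for l in layers] == [False, False, False, True, False]

    def test_preaggregation_dropout_at_layers_three_and_four(self):
        spec = N.NetworkSpec(n_classes=4, view_shapes=((2, 14),) * 3)
        layers = spec.preagg_layers()
        assert [l.dropout > 0 for l in layers[:6]] == [
            False, False, True, True, False, False
        ]

    def test_fused_fc_width_is_views_times_units(self):
        spec = N.NetworkSpec(n_classes=4, view_shapes=((2, 14),) * 3)
        m = N.MultiViewNetwork(spec, seed=0)
        first_dense = next(
            l for l in m.postagg.layers if isinstance(l, Dense)
        )
        assert first_dense.in_features == 3 * 512

    def test_mismatched_view_layouts_fail_at_build_time(self):
        spec = N.NetworkSpec(n_classes=3, view_shapes=((2, 9), (2, 14)))
        with pytest.raises(ValueError, match="common view layout"):
            N.MultiViewNetwork(spec, seed=0)


class TestFusionHeads:
    def test_softmax_heads_normalized(self, toy_spec, preset_dataset):
        spec = N.NetworkSpec.small(3, preset_dataset.view_shapes)
        m = N.MultiViewNetwork(spec, seed=1)
        xs = [x[:8] for x in preset_dataset.xs]
        logits = m.heads(xs, train=False)
        for v in logits.values():
            p = softmax(v)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
            assert v.shape == (8, 3)
        assert np.allclose(m.decision_scores(xs).sum(axis=1), 2.0, atol=1e-6)

    def test_zero_final_layers_give_uniform_heads(self, toy_spec):
        m = N.MultiViewNetwork(toy_spec, seed=0)
        m.preagg.layers[-1].w.value[...] = 0.0
        m.preagg.layers[-1].b.value[...] = 0.0
        m.postagg.layers[-1].w.value[...] = 0.0
        m.postagg.layers[-1].b.value[...] = 0.0
        xs = [np.random.default_rng(0).standard_normal((3, 1, 1, 1))
              for _ in range(2)]
        logits = m.heads(xs, train=False)
        for v in logits.values():
            assert np.allclose(softmax(v), 0.5, atol=1e-12)

    def test_same_seed_same_initial_parameters(self, toy_spec):
        a = N.MultiViewNetwork(toy_spec, seed=5)
        b = N.MultiViewNetwork(toy_spec, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_inference_invariant_to_batch_composition(self, preset_dataset):
        spec = N.NetworkSpec.small(3, preset_dataset.view_shapes)
        m = N.MultiViewNetwork(spec, seed=2)
        xs = [x[:16] for x in preset_dataset.xs]
        full = m.decision_scores(xs)
        solo = m.decision_scores([x[3:4] for x in xs])
        assert np.allclose(full[3], solo[0], atol=1e-10)
        again = m.decision_scores(xs)
        assert np.array_equal(full, again)

    def test_post_aggregate_permutation_equivariance(self, toy_spec):
        m = N.MultiViewNetwork(toy_spec, seed=3)
        _fill_weights(m, seed=9)
        rng = np.random.default_rng(1)
        h5 = [np.abs(rng.standard_normal((1, 2))) for _ in range(2)]
        base = m.post_aggregate(h5)
        # swap branch order and permute the fused dense weight rows to match
        dense = next(l for l in m.postagg.layers if isinstance(l, Dense))
        u = 2
        dense.w.value[...] = np.vstack([dense.w.value[u:], dense.w.value[:u]])
        swapped = m.post_aggregate([h5[1], h5[0]])
        assert np.allclose(base.y, swapped.y, atol=1e-12)


class TestDecisionFuse:
    def test_elementwise_sum_and_argmax(self):
        y_pre = N.ClassProbabilities(np.array([0.7, 0.3]), "pre-fusion")
        y_post = N.ClassProbabilities(np.array([0.6, 0.4]), "post-fusion")
        y_final, cls = N.decision_fuse(y_pre, y_post)
        assert np.allclose(y_final.y, [1.3, 0.7])
        assert cls == 0

    def test_tie_goes_to_lowest_index(self):
        y = N.ClassProbabilities(np.array([0.5, 0.5]), "pre-fusion")
        y2 = N.ClassProbabilities(np.array([0.5, 0.5]), "post-fusion")
        y_final, cls = N.decision_fuse(y, y2)
        assert np.allclose(y_final.y, [1.0, 1.0])
        assert cls == 0

    def test_length_mismatch_rejected(self):
        a = N.ClassProbabilities(np.array([0.5, 0.5]), "pre-fusion")
        b = N.ClassProbabilities(np.array([0.2, 0.3, 0.5]), "post-fusion")
        with pytest.raises(ValueError, match="mismatch"):
            N.decision_fuse(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_argmax_equals_argmax_of_mean(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(4))
        b = rng.dirichlet(np.ones(4))
        _, cls = N.decision_fuse(
            N.ClassProbabilities(a, "pre-fusion"),
            N.ClassProbabilities(b, "post-fusion"),
        )
        assert cls == int(np.argmax((a + b) / 2))


class TestAggregationBaselines:
    def test_max_pooling_idempotent_on_identical_views(self):
        f = np.random.default_rng(0).standard_normal((4, 8))
        out = N.aggregate_pooling_of_view([f, f.copy(), f.copy()], "max")
        assert np.array_equal(out, f)

    def test_max_dominates_mean_elementwise(self):
        rng = np.random.default_rng(1)
        feats = [rng.standard_normal((3, 5)) for _ in range(4)]
        mx = N.aggregate_pooling_of_view(feats, "max")
        mn = N.aggregate_pooling_of_view(feats, "mean")
        assert np.all(mx >= mn - 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            N.aggregate_pooling_of_view([np.zeros((2, 2)), np.zeros((2, 3))])

    def test_pooling_at_second_fc_builds_and_runs(self, toy_spec):
        m = N.PoolingOfViewNetwork(toy_spec, seed=0, pool_layer=6)
        xs = [np.random.default_rng(0).standard_normal((2, 1, 1, 1))
              for _ in range(2)]
        scores = m.decision_scores(xs)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_decision_average_of_identical_vectors(self):
        p = np.array([0.2, 0.3, 0.5])
        out = N.aggregate_decision_fusion([p, p, p])
        assert np.allclose(out.y, p)
        assert out.y.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_branch_average_is_half_the_decision_sum(self):
        a = np.array([0.7, 0.3])
        b = np.array([0.1, 0.9])
        avg = N.aggregate_decision_fusion([a, b])
        y_final, _ = N.decision_fuse(
            N.ClassProbabilities(a, "pre-fusion"),
            N.ClassProbabilities(b, "post-fusion"),
        )
        assert np.allclose(avg.y, y_final.y / 2.0)

    def test_spliced_input_width_is_sum_of_view_widths(self):
        spec = N.NetworkSpec.small(3, ((2, 9), (2, 14), (2, 12)))
        m = N.SingleViewNetwork(spec, seed=0, mode="spliced-multiview")
        assert m.input_shape == (2, 9 + 14 + 12)
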