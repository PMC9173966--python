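import numpy as np
import pytest

from myoview import networks as N
from myoview import presets, synth, training


@pytest.fixture(scope="session")
def preset_dataset() -> training.MultiViewDataset:
    """The complementary-views synthetic dataset (3 classes, 3 views)."""
    return presets.make_dataset(n_trials_per_class=20, seed=0)


@pytest.fixture(scope="session")
def flat_band_recording() -> synth.EmgRecording:
    """10 s of flat-spectrum [20, 200] Hz noise at 10 μV RMS, duty 1."""
    cls = synth.GestureClassParams(0, (10.0,), (20.0, 200.0), 1.0)
    return synth.simulate_semg([cls], 1, 10.0, fs=1000.0, seed=0)


@pytest.fixture()
def toy_spec() -> N.NetworkSpec:
    """2-view, 2-class, 2-unit spec with 1×1 kernels on 1×1 images, no
    dropout: every layer reduces to a small matrix product, so explicit
    matrix arithmetic can serve as an oracle."""
    return N.NetworkSpec(
        n_classes=2,
        view_shapes=((1, 1), (1, 1)),
        conv_channels=2,
        kernel_size=1,
        lc_kernel_size=1,
        fc_units=2,
        dropout=0.0,
    )


def set_identity_batchnorm(model: N.NetworkBase) -> None:
    """Make every batch-norm layer an exact identity in inference mode
    (running mean 0, var 1, gamma = √(1+ε))."""
    from myoview.nn import BatchNorm, Sequential

    def visit(obj):
        if isinstance(obj, BatchNorm):
            obj.gamma.value[...] = np.sqrt(1.0 + obj.eps)
            obj.beta.value[...] = 0.0
            obj.running_mean[...] = 0.0
            obj.running_var[...] = 1.0
        elif isinstance(obj, Sequential):
            for layer in obj.layers:
                visit(layer)

    for attr in ("branches", "per_view"):
        for blocks in getattr(model, attr, []):
            for b in blocks:
                visit(b)
    for attr in ("preagg", "postagg"):
        if hasattr(model, attr):
            visit(getattr(model, attr))
    for b in getattr(model, "blocks", []):
        visit(b)
    for b in getattr(model, "shared", []):
        visit(b)
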