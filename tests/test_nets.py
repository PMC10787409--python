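"""Architecture contracts: variant factory, shape laws, gating, subgraph diffs."""

import numpy as np
import pytest

from cuffseg.errors import ConfigurationError, ShapeError
from cuffseg.nets import (ChannelAttention, DenseASPP, ModelConfig,
                          build_model, build_variant, count_params,
                          parameter_names, VARIANT_NAMES)
from cuffseg.nn import Tensor, no_grad


EXPECTED_FLAGS = {
    "baseline": (18, False, False),
    "scheme1": (34, False, False),
    "scheme2": (34, True, False),
    "scheme3": (34, False, True),
    "full": (34, True, True),
}


@pytest.mark.parametrize("name", VARIANT_NAMES)
def test_variant_factory_flags(name):
    cfg = build_variant(name)
    assert (cfg.encoder_depth, cfg.use_attention, cfg.use_denseaspp) == \
        EXPECTED_FLAGS[name]


def test_unknown_variant_lists_valid_names():
    with pytest.raises(ConfigurationError, match="baseline"):
        build_variant("resnet50")


def test_model_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(encoder_depth=50)
    with pytest.raises(ConfigurationError):
        ModelConfig(dilation_rates=(6, 3))
    with pytest.raises(ConfigurationError):
        ModelConfig(attention_reduction=48)   # does not divide 64


@pytest.mark.parametrize("size,batch", [(64, 2), (128, 1)])
def test_encoder_stride_algebra(size, batch):
    model = build_model("baseline", seed=0).eval()
    x = np.zeros((batch, 3, size, size), dtype=np.float32)
    with no_grad():
        (f1, f2, f3), f4 = model.encode(x)
    assert f1.shape == (batch, 64, size // 4, size // 4)
    assert f2.shape == (batch, 128, size // 8, size // 8)
    assert f3.shape == (batch, 256, size // 16, size // 16)
    assert f4.shape == (batch, 512, size // 32, size // 32)


def test_encoder_block_counts_by_depth():
    # depth 18 -> (2,2,2,2) blocks, depth 34 -> (3,4,6,3)
    for depth, counts in ((18, (2, 2, 2, 2)), (34, (3, 4, 6, 3))):
        enc = build_model(ModelConfig(encoder_depth=depth, use_attention=False,
                                      use_denseaspp=False), seed=0).encoder
        for i, n in enumerate(counts):
            stage = getattr(enc, f"stage{i + 1}")
            assert len(stage._list) == n


def test_indivisible_input_raises_shape_error():
    model = build_model("baseline", seed=0)
    with pytest.raises(ShapeError, match="32"):
        model.encode(np.zeros((1, 3, 96, 100), dtype=np.float32))


@pytest.mark.parametrize("size", [64, 128])
def test_full_forward_shape_and_range(size):
    model = build_model("full", seed=0).eval()
    x = np.random.default_rng(0).random((1, 3, size, size), dtype=np.float32)
    with no_grad():
        y = model(x)
    assert y.shape == (1, 1, size, size)
    # logistic output; float32 rounding may saturate the open interval's ends
    out = y.numpy()
    assert np.isfinite(out).all() and (out >= 0).all() and (out <= 1).all()


def test_forward_is_deterministic():
    model = build_model("scheme2", seed=3).eval()
    x = np.random.default_rng(1).random((1, 3, 64, 64), dtype=np.float32)
    with no_grad():
        a = model(x).numpy()
        b = model(x).numpy()
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

def test_attention_preserves_shape_and_zeros():
    att = ChannelAttention(256, 16, np.random.default_rng(0))
    x = np.random.default_rng(2).normal(size=(2, 256, 8, 8)).astype(np.float32)
    with no_grad():
        y = att(Tensor(x))
    assert y.shape == (2, 256, 8, 8)
    with no_grad():
        z = att(Tensor(np.zeros((1, 256, 4, 4), np.float32)))
    np.testing.assert_array_equal(z.numpy(), 0.0)


def test_attention_gates_shrink_magnitudes():
    """Every logistic gate is < 1, so |out| <= |in| elementwise."""
    att = ChannelAttention(64, 16, np.random.default_rng(5))
    x = np.random.default_rng(3).normal(size=(2, 64, 6, 6))
    with no_grad():
        y = att(Tensor(x)).numpy()
    assert (np.abs(y) <= np.abs(x) + 1e-12).all()
    assert np.sign(y[x != 0]).tolist() == np.sign(x[x != 0]).tolist()


def test_attention_requires_divisible_reduction():
    with pytest.raises(ConfigurationError):
        ChannelAttention(100, 16)


# ---------------------------------------------------------------------------
# DenseASPP
# ---------------------------------------------------------------------------

def test_denseaspp_preserves_bottleneck_shape():
    aspp = DenseASPP(512, (3, 6, 12, 18, 24), rng=np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, 512, 16, 16)).astype(np.float32)
    with no_grad():
        y = aspp(Tensor(x))
    assert y.shape == (1, 512, 16, 16)


def test_denseaspp_rejects_non_ascending_rates():
    with pytest.raises(ConfigurationError):
        DenseASPP(512, (3, 3, 6))


def test_dense_connectivity_branch_input_widths():
    """Branch i consumes the bottleneck plus all previous branch outputs."""
    aspp = DenseASPP(512, (3, 6, 12), reduce=128, growth=64,
                     rng=np.random.default_rng(0))
    widths = [b[0].weight.shape[1] for b in aspp.branches]
    assert widths == [512, 512 + 64, 512 + 128]
    assert aspp.project.weight.shape == (512, 512 + 3 * 64, 1, 1)


def test_dilated_receptive_field_algebra():
    # a single 3x3 conv at dilation d spans 2d + 1 pixels
    for d in (3, 6, 12):
        assert 2 * d + 1 == (3 - 1) * d + 1
    # two cascaded 3x3 convs at rates (3, 6) span 1 + 2*(3 + 6)
    assert 1 + 2 * (3 + 6) == 19


# ---------------------------------------------------------------------------
# parameter counts / subgraph diffs
# ---------------------------------------------------------------------------

def test_parameter_count_ordering():
    counts = {name: count_params(name) for name in VARIANT_NAMES}
    assert counts["baseline"] < counts["scheme1"]
    assert counts["scheme1"] < counts["scheme2"]
    assert counts["scheme1"] < counts["scheme3"]
    assert counts["scheme2"] < counts["full"]
    assert counts["scheme3"] < counts["full"]


def test_toggling_flags_changes_only_named_subgraph():
    base = parameter_names("scheme1")
    with_att = parameter_names("scheme2")
    with_aspp = parameter_names("scheme3")
    both = parameter_names("full")
    assert base < with_att
    added_att = with_att - base
    assert added_att and all(n.startswith("attention.") for n in added_att)
    added_aspp = with_aspp - base
    assert added_aspp and all(n.startswith("bridge.") for n in added_aspp)
    assert both == base | added_att | added_aspp


def test_attention_off_bypasses_gating():
    cfg = build_variant("scheme1")
    assert not cfg.use_attention
    model = build_model(cfg, seed=0)
    assert not any(n.startswith("attention.") for n, _ in model.named_parameters())
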