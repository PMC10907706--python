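"""Architectural blocks: shape contracts, oracles with pinned weights."""

import numpy as np
import pytest

from dsfnet import nn
from dsfnet.blocks import CBAM, CBG, FCM, FCMConfig, MFFM, TransformerBlock
from dsfnet.nn.tensor import Tensor


def rand(shape, seed=0):
    return Tensor(np.random.default_rng(seed).random(shape).astype(np.float32))


# ---------------------------------------------------------------------- CBG

def test_cbg_preserves_shape_and_is_deterministic_in_eval():
    nn.seed_all(0)
    cbg = CBG(16).eval()
    x = rand((2, 16, 14, 14))
    y = cbg(x)
    assert y.shape == x.shape
    assert np.array_equal(y.data, cbg(x).data)


def test_cbg_zero_input_finite():
    nn.seed_all(0)
    cbg = CBG(8).eval()
    y = cbg(Tensor(np.zeros((1, 8, 6, 6), np.float32)))
    assert np.all(np.isfinite(y.data))


def test_cbg_channel_mismatch_raises():
    with pytest.raises(ValueError):
        CBG(8)(rand((1, 4, 6, 6)))


# --------------------------------------------------------- transformer path

def test_transformer_block_shape_and_batch_independence():
    nn.seed_all(0)
    tb = TransformerBlock(dim=8, token_grid=4, heads=2, patch_size=2).eval()
    x = rand((3, 8, 8, 8), seed=1)
    y = tb(x)
    assert y.shape == x.shape
    perm = [2, 0, 1]
    y_perm = tb(Tensor(x.data[perm]))
    assert np.allclose(y_perm.data, y.data[perm], atol=1e-6)


def test_transformer_block_zero_parameter_oracle():
    """With MSA/MLP output weights zeroed, the block is the linear patch
    round-trip of embed -> +pos -> unembed, reproduced here in plain numpy."""
    nn.seed_all(0)
    g, p, d = 4, 2, 8
    tb = TransformerBlock(dim=d, token_grid=g, heads=2, patch_size=p).eval()
    for lin in (tb.msa.proj, tb.fc2):
        lin.weight.data[:] = 0.0
        lin.bias.data[:] = 0.0
    x = np.random.default_rng(3).random((2, d, g * p, g * p)).astype(np.float32)
    out = tb(Tensor(x)).data

    B = x.shape[0]
    tok = x.reshape(B, d, g, p, g, p).transpose(0, 2, 4, 1, 3, 5).reshape(
        B, g * g, d * p * p
    )
    z = tok @ tb.embed.weight.data + tb.embed.bias.data + tb.pos.data
    rec = z @ tb.unembed.weight.data + tb.unembed.bias.data
    expected = rec.reshape(B, g, g, d, p, p).transpose(0, 3, 1, 4, 2, 5).reshape(x.shape)
    assert np.allclose(out, expected, atol=1e-5)

    # fully zeroed embedding/positional parameters give the zero map
    for lin in (tb.embed, tb.unembed):
        lin.weight.data[:] = 0.0
        lin.bias.data[:] = 0.0
    tb.pos.data[:] = 0.0
    assert np.allclose(tb(Tensor(x)).data, 0.0)


def test_transformer_block_rejects_wrong_spatial_size():
    tb = TransformerBlock(dim=8, token_grid=4, heads=2, patch_size=2)
    with pytest.raises(ValueError, match="token_grid"):
        tb(rand((1, 8, 12, 12)))


# ------------------------------------------------------------------------ FCM

def test_fcm_shape_contract():
    nn.seed_all(0)
    fcm = FCM(FCMConfig(channels=16, heads=2, token_grid=4), spatial_size=16).eval()
    x = rand((2, 16, 16, 16))
    assert fcm(x).shape == x.shape


def test_fcm_zero_projection_is_identity():
    """Zero-initialized expanding 1x1 conv makes a fresh FCM the identity."""
    nn.seed_all(0)
    fcm = FCM(FCMConfig(channels=16, heads=2, token_grid=4), spatial_size=8).eval()
    x = rand((2, 16, 8, 8), seed=5)
    assert np.array_equal(fcm(x).data, x.data)


def test_fcm_invalid_channels_raise():
    with pytest.raises(ValueError, match="divisible by 4"):
        FCMConfig(channels=18, heads=2)
    with pytest.raises(ValueError, match="heads"):
        FCMConfig(channels=16, heads=3)
    with pytest.raises(ValueError, match="token_grid"):
        FCM(FCMConfig(channels=16, heads=2, token_grid=4), spatial_size=10)


def test_fcm_cheaper_than_plain_double_conv():
    """At C=64, token_grid 14 the FCM has fewer parameters than two plain
    3x3 convolutions (with batch norm) at full width."""
    nn.seed_all(0)
    fcm = FCM(FCMConfig(channels=64, heads=4, token_grid=14), spatial_size=56)
    double_conv = nn.Sequential(
        CBG(64), CBG(64)
    )
    assert fcm.n_parameters() < double_conv.n_parameters()


# ----------------------------------------------------------------------- CBAM

def test_cbam_gating_bounds_and_zero_input():
    nn.seed_all(0)
    cbam = CBAM(8, reduction=4).eval()
    x = rand((2, 8, 9, 9), seed=2)
    y = cbam(x)
    assert y.shape == x.shape
    assert np.all(np.abs(y.data) <= np.abs(x.data) + 1e-7)
    z = cbam(Tensor(np.zeros((1, 8, 5, 5), np.float32)))
    assert np.allclose(z.data, 0.0)


def test_cbam_channel_attention_fixed_weight_oracle():
    """Channel attention on (zeros, ones) channels vs. explicit arithmetic."""
    nn.seed_all(0)
    cbam = CBAM(2, reduction=2).eval()
    w1 = np.array([[0.5], [-0.25]], np.float32)   # (C=2, hidden=1)
    w2 = np.array([[2.0, -1.0]], np.float32)      # (hidden=1, C=2)
    cbam.fc1.weight.data = w1
    cbam.fc2.weight.data = w2
    x = np.zeros((1, 2, 4, 4), np.float32)
    x[:, 1] = 1.0
    mc = cbam.channel_attention(Tensor(x)).data

    def mlp(v):  # v: (C,)
        h = np.maximum(v @ w1, 0.0)
        return h @ w2

    pooled_avg = np.array([0.0, 1.0])
    pooled_max = np.array([0.0, 1.0])
    expected = 1.0 / (1.0 + np.exp(-(mlp(pooled_avg) + mlp(pooled_max))))
    assert np.allclose(mc[0], expected, atol=1e-6)


def test_cbam_attention_maps_bounded():
    nn.seed_all(1)
    cbam = CBAM(8, reduction=4).eval()
    x = rand((2, 8, 6, 6), seed=3) * 10.0 - 5.0
    mc = cbam.channel_attention(x).data
    ms = cbam.spatial_attention(x).data
    for m in (mc, ms):
        assert np.all(m >= 0.0) and np.all(m <= 1.0)


def test_cbam_rejects_too_few_channels():
    with pytest.raises(ValueError):
        CBAM(2, reduction=4)


# ----------------------------------------------------------------------- MFFM

def test_mffm_channel_arithmetic_and_four_scale_attention():
    nn.seed_all(0)
    mffm = MFFM(8, reduction=4).eval()
    feats = [rand((1, 8, 16, 16), seed=i) for i in range(4)]
    y = mffm(*feats)
    assert y.shape == (1, 32, 16, 16)  # concat of 4 gated C-channel maps
    # the inter-scale attention stack has exactly 4 channels
    assert mffm.interscale_conv.out_ch == 4
    from dsfnet.nn.tensor import concat
    A = mffm.interscale_conv(concat(feats, axis=1)).sigmoid()
    assert A.shape == (1, 4, 16, 16)
    assert np.all(A.data >= 0.0) and np.all(A.data <= 1.0)


def test_mffm_mismatched_shapes_raise():
    nn.seed_all(0)
    mffm = MFFM(8, reduction=4)
    feats = [rand((1, 8, 8, 8)) for _ in range(3)] + [rand((1, 8, 4, 4))]
    with pytest.raises(ValueError, match="share shape"):
        mffm(*feats)


def test_mffm_per_scale_dataflow_isolation():
    """With the inter-scale attention frozen to a constant, zeroing one input
    changes only its own block of the concatenated features."""
    nn.seed_all(0)
    mffm = MFFM(4, reduction=2).eval()
    mffm.interscale_conv.weight.data[:] = 0.0
    mffm.interscale_conv.bias.data[:] = 0.0  # A = sigmoid(0) = 0.5 everywhere
    feats = [rand((1, 4, 8, 8), seed=10 + i) for i in range(4)]

    def gated_blocks(fs):
        from dsfnet.nn.tensor import concat
        A = mffm.interscale_conv(concat(fs, axis=1)).sigmoid()
        return [
            (mffm.cbam[i](fs[i]) * A[:, i: i + 1]).data for i in range(4)
        ]

    ref = gated_blocks(feats)
    feats_mod = list(feats)
    feats_mod[2] = Tensor(np.zeros_like(feats[2].data))
    mod = gated_blocks(feats_mod)
    assert np.allclose(mod[2], 0.0)
    for i in (0, 1, 3):
        assert np.array_equal(ref[i], mod[i])
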