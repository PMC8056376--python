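"""Backbone building blocks, shape chain, gender embedding and parameter
count of the assembled regression network."""

import dataclasses

import numpy as np
import pytest

from handage import nn
from handage.architecture import (MOBILENETV3_ROWS, BlockSpec, BoneAgeNet,
                                  DepthwiseSeparable, GenderEmbedding,
                                  build_backbone, count_parameters, h_swish,
                                  prepare_batch)


# ----------------------------------------------------------------- h-swish

@pytest.mark.parametrize("x,expected", [(0.0, 0.0), (3.0, 3.0), (-3.0, 0.0),
                                        (-5.0, 0.0), (6.0, 6.0)])
def test_h_swish_closed_form(x, expected):
    assert h_swish(x) == pytest.approx(expected, abs=1e-12)


def test_h_swish_properties_on_dense_grid():
    grid = np.linspace(-10, 10, 4001)
    vals = h_swish(grid)
    pos = grid >= 0
    assert np.all(vals[pos] >= 0) and np.all(vals[pos] <= grid[pos] + 1e-12)
    assert np.all(vals[~pos] <= 0)
    # continuity: no jump exceeds the grid spacing times the max slope
    assert np.max(np.abs(np.diff(vals))) < 0.05


# ------------------------------------------------------- depthwise separable

def test_depthwise_separable_parameter_count(rng):
    block = DepthwiseSeparable(16, 16, 3, rng=rng)
    # k^2 * C_in + C_in * C_out = 9*16 + 256 = 400
    assert block.n_parameters() == 3 * 3 * 16 + 16 * 16 == 400


def test_depthwise_separable_identity_construction(rng):
    block = DepthwiseSeparable(3, 3, 3, rng=rng)
    block.depthwise.weight.data[:] = 0.0
    block.depthwise.weight.data[:, 1, 1] = 1.0          # unit impulse
    block.pointwise.weight.data[:] = np.eye(3)[:, :, None, None]
    x = nn.Tensor(np.random.default_rng(0).random((1, 3, 6, 6), dtype=np.float32))
    np.testing.assert_allclose(block(x).data, x.data, rtol=1e-6)


def test_depthwise_separable_composes_to_separable_full_conv(rng):
    """A separable full kernel K[c_out, c_in] = pw[c_out, c_in] * dw[c_in]
    applied by dense convolution must equal the two-stage result."""
    block = DepthwiseSeparable(2, 3, 3, rng=rng)
    x = nn.Tensor(rng.random((1, 2, 5, 5)).astype(np.float32))
    two_stage = block(x).data
    full_kernel = (block.pointwise.weight.data[:, :, 0, 0, None, None]
                   * block.depthwise.weight.data[None, :, :, :])
    dense = x.conv2d(nn.Tensor(full_kernel), padding=1).data
    np.testing.assert_allclose(two_stage, dense, rtol=1e-4, atol=1e-6)


# ------------------------------------------------------------------ SE gate

def test_squeeze_excite_neutral_gate(rng):
    se = nn.SqueezeExcite(4, 2, rng=rng)
    se.fc2.weight.data[:] = 0.0
    se.fc2.bias.data[:] = 100.0                          # hard-sigmoid -> 1
    x = nn.Tensor(rng.random((2, 4, 5, 5)).astype(np.float32))
    np.testing.assert_allclose(se(x).data, x.data, rtol=1e-6)


def test_squeeze_is_channel_mean(rng):
    se = nn.SqueezeExcite(3, 2, rng=rng)
    const = np.array([1.5, -2.0, 0.25])
    x = nn.Tensor(np.broadcast_to(const[None, :, None, None], (1, 3, 4, 4)).copy()
                  .astype(np.float32))
    np.testing.assert_allclose(se.squeeze(x).data[0], const, rtol=1e-6)


def test_squeeze_excite_never_amplifies(rng):
    se = nn.SqueezeExcite(5, 2, rng=rng)
    x = nn.Tensor(rng.normal(size=(3, 5, 6, 6)).astype(np.float32))
    assert np.all(np.abs(se(x).data) <= np.abs(x.data) + 1e-7)


# -------------------------------------------------------- inverted residual

def test_inverted_residual_pure_skip(rng):
    block = nn.InvertedResidual(4, 8, 4, 3, 1, False, "RE", rng=rng)
    for p in block.project.parameters():
        p.data[:] = 0.0
    x = nn.Tensor(rng.random((1, 4, 6, 6)).astype(np.float32))
    np.testing.assert_allclose(block(x).data, x.data, rtol=1e-6)


def test_inverted_residual_stride_two_halves_dims(rng):
    block = nn.InvertedResidual(4, 8, 6, 3, 2, False, "HS", rng=rng)
    x = nn.Tensor(rng.random((1, 4, 8, 8)).astype(np.float32))
    assert block(x).shape == (1, 6, 4, 4)
    assert not block.use_skip


def test_inverted_residual_table_row_shape(rng):
    # 28 x 28 x 40 -> 3 x 3, 80 channels, stride 2 -> 14 x 14 x 80
    block = nn.InvertedResidual(40, 240, 80, 3, 2, False, "HS", rng=rng)
    x = nn.Tensor(rng.random((1, 40, 28, 28)).astype(np.float32))
    assert block(x).shape == (1, 80, 14, 14)


def test_inverted_residual_rejects_bad_stride(rng):
    with pytest.raises(ValueError):
        nn.InvertedResidual(4, 8, 4, 3, 3, False, "RE", rng=rng)


# ---------------------------------------------------------------- backbone

def test_backbone_shape_chain_follows_architecture_rows(rng):
    backbone = build_backbone(seed=0)
    x = nn.Tensor(rng.random((1, 3, 224, 224)).astype(np.float32))
    backbone.eval()
    out, shapes = backbone.forward_with_shapes(x)
    rows = MOBILENETV3_ROWS
    for i in range(len(rows) - 1):
        expected = rows[i + 1].input_dims          # next row's input = this row's output
        assert shapes[i] == (1, expected[2], expected[0], expected[1]), f"row {i}"
    assert shapes[len(rows) - 1] == (1, 960)       # adaptive average pool
    assert shapes[-1] == (1, 1280)                 # feature layer
    assert np.all(np.isfinite(out.data))


@pytest.mark.parametrize("size", [96, 224])
def test_backbone_feature_dim_independent_of_input_size(rng, size):
    backbone = build_backbone(seed=0)
    backbone.eval()
    x = nn.Tensor(rng.random((1, 3, size, size)).astype(np.float32))
    assert backbone(x).shape == (1, 1280)


def test_backbone_rejects_inconsistent_rows():
    rows = list(MOBILENETV3_ROWS)
    rows[3] = dataclasses.replace(rows[3], input_dims=(56, 56, 99))
    with pytest.raises(ValueError, match="row 3"):
        build_backbone(tuple(rows), seed=0)


def test_blockspec_invariants():
    with pytest.raises(ValueError):
        BlockSpec((8, 8, 4), "mobile-block", 7, 8, False, "relu", 1)
    with pytest.raises(ValueError):
        BlockSpec((8, 8, 4), "mobile-block", 3, 8, False, "relu", 3)


# --------------------------------------------------------- gender embedding

def test_gender_embedding_output_contract(rng):
    emb = GenderEmbedding(rng=rng)
    for g in (0.0, 1.0):
        out = emb(nn.Tensor(np.array([[g]], dtype=np.float32)))
        assert out.shape == (1, 24)
        assert np.all(out.data >= 0.0)


def test_gender_embedding_hand_computed():
    emb = GenderEmbedding()
    emb.fc.weight.data[:] = 1.0
    emb.fc.bias.data[:] = -0.5
    one = emb(nn.Tensor(np.array([[1.0]], dtype=np.float32))).data
    zero = emb(nn.Tensor(np.array([[0.0]], dtype=np.float32))).data
    np.testing.assert_allclose(one, 0.5)
    np.testing.assert_allclose(zero, 0.0)


def test_gender_zero_input_uses_only_bias(rng):
    emb = GenderEmbedding(rng=rng)
    out = emb(nn.Tensor(np.array([[0.0]], dtype=np.float32))).data
    np.testing.assert_allclose(out[0], np.maximum(emb.fc.bias.data, 0.0), rtol=1e-6)


# ------------------------------------------------------------- full network

@pytest.fixture(scope="module")
def model():
    return BoneAgeNet(seed=0)


def test_fused_feature_dimension(model, rng):
    x = nn.Tensor(prepare_batch(rng.random((2, 64, 64))))
    model.eval()
    feat = model.backbone(x)
    fused = model.fuse(feat, nn.Tensor(np.array([[1.0], [0.0]], dtype=np.float32)))
    assert fused.shape == (2, 1304)
    assert model.fused_dim == 1280 + 24 == 1304


def test_predict_batch_of_scalars(model, rng):
    images = rng.random((10, 64, 64))
    male = np.array([True, False] * 5)
    preds = model.predict(images, male)
    assert preds.shape == (10,)
    assert np.all(np.isfinite(preds))


def test_flipping_gender_changes_prediction(model, rng):
    images = rng.random((1, 64, 64))
    a = model.predict(images, np.array([True]))
    b = model.predict(images, np.array([False]))
    assert a[0] != b[0]


def test_genderless_model_ignores_gender(rng):
    model = BoneAgeNet(use_gender=False, seed=1)
    assert model.fused_dim == 1280
    images = rng.random((2, 64, 64))
    preds = model.predict(images)
    assert preds.shape == (2,)


def test_parameter_count_closed_forms(model):
    # gender embedding: 1*24 weights + 24 biases
    assert model.gender_embed.n_parameters() == 48
    # prediction stage: fusion 1304x1304+1304, hidden 1304x1304+1304, out 1304+1
    head = (model.fusion.n_parameters() + model.hidden.n_parameters()
            + model.out.n_parameters())
    assert head == 2 * (1304 * 1304 + 1304) + 1304 + 1 == 3_404_745
    # feature layer: 960*1280 + 1280
    assert model.backbone.feature_layer.n_parameters() == 1_230_080


def test_total_parameters_approximately_7_6_million(model):
    total = count_parameters(model)
    assert abs(total - 7.6e6) / 7.6e6 < 0.05
    assert total == 7_604_905        # exact count of this construction


def test_parameter_count_invariant_to_input_size(model, rng):
    n0 = count_parameters(model)
    for size in (96, 160):
        model.eval()
        model.predict(rng.random((1, size, size)), np.array([True]))
        assert count_parameters(model) == n0
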