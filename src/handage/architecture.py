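"""Gender-embedded bone-age regression network.

The image branch is a MobileNetV3-Large backbone: a strided 3x3 stem, 15
inverted-residual blocks (1x1 expansion -> depthwise -> optional
squeeze-and-excitation -> 1x1 linear projection, with a skip connection when
stride is 1 and channel counts match), a 1x1 convolution to 960 channels,
adaptive average pooling and a 1280-wide feature layer.  h-swish,
x * ReLU(x+3)/6, replaces sigmoid-based gating in the deeper stages.

The binary gender flag (male=1, female=0) passes through a rectified linear
embedding of width 24 and is concatenated with the 1280-dim image feature.
The 1304-dim fused vector is mixed by a rectified 1304-wide fusion layer and
regressed to a single standardized bone-age scalar by a one-hidden-layer MLP
(1304 -> 1304 -> 1).  Assembled this way the network carries approximately
7.6 million learnable parameters.

Adaptive pooling makes the backbone input-size agnostic: 224, 500 or 700
pixel inputs (and smaller test sizes) all map to a 1280-vector, and the
parameter count is independent of image size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "h_swish", "BlockSpec", "MOBILENETV3_ROWS", "DepthwiseSeparable",
    "build_backbone", "GenderEmbedding", "BoneAgeNet", "count_parameters",
    "GENDER_EMBED_DIM", "IMAGE_FEATURE_DIM",
]

IMAGE_FEATURE_DIM = 1280
GENDER_EMBED_DIM = 24


def h_swish(x):
    """h-swish(x) = x * ReLU(x + 3) / 6 = x * clamp(x + 3, 0, 6) / 6."""
    x = np.asarray(x, dtype=np.float64)
    out = x * np.clip(x + 3.0, 0.0, 6.0) / 6.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BlockSpec:
    """One architecture row: input size, operator and its settings."""

    input_dims: tuple[int, int, int]       # (H, W, C) at 224-pixel input
    operator: str                          # standard-conv | mobile-block | pointwise-conv | pooling
    kernel: int
    out_channels: int
    use_se: bool
    nonlinearity: str                      # h-swish | relu | none
    stride: int
    expanded: int = 0                      # mobile-block expansion width

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.kernel not in (1, 3, 5):
            raise ValueError("kernel must be 1, 3 or 5")


#: The backbone stack, one row per layer, input sizes quoted at 224 x 224.
#: Expansion widths follow the published MobileNetV3-Large values.
MOBILENETV3_ROWS: tuple[BlockSpec, ...] = (
    BlockSpec((224, 224, 3), "standard-conv", 3, 16, False, "h-swish", 2),
    BlockSpec((112, 112, 16), "mobile-block", 3, 16, False, "relu", 1, expanded=16),
    BlockSpec((112, 112, 16), "mobile-block", 3, 24, False, "relu", 2, expanded=64),
    BlockSpec((56, 56, 24), "mobile-block", 3, 24, False, "relu", 1, expanded=72),
    BlockSpec((56, 56, 24), "mobile-block", 5, 40, True, "relu", 2, expanded=72),
    BlockSpec((28, 28, 40), "mobile-block", 5, 40, True, "relu", 1, expanded=120),
    BlockSpec((28, 28, 40), "mobile-block", 3, 40, True, "relu", 1, expanded=120),
    BlockSpec((28, 28, 40), "mobile-block", 3, 80, False, "h-swish", 2, expanded=240),
    BlockSpec((14, 14, 80), "mobile-block", 3, 80, False, "h-swish", 1, expanded=200),
    BlockSpec((14, 14, 80), "mobile-block", 3, 80, False, "h-swish", 1, expanded=184),
    BlockSpec((14, 14, 80), "mobile-block", 3, 80, False, "h-swish", 1, expanded=184),
    BlockSpec((14, 14, 80), "mobile-block", 3, 112, True, "h-swish", 1, expanded=480),
    BlockSpec((14, 14, 112), "mobile-block", 3, 112, True, "h-swish", 1, expanded=672),
    BlockSpec((14, 14, 112), "mobile-block", 5, 160, True, "h-swish", 2, expanded=672),
    BlockSpec((7, 7, 160), "mobile-block", 5, 160, True, "h-swish", 1, expanded=960),
    BlockSpec((7, 7, 160), "mobile-block", 5, 160, True, "h-swish", 1, expanded=960),
    BlockSpec((7, 7, 160), "pointwise-conv", 1, 960, False, "h-swish", 1),
    BlockSpec((7, 7, 960), "pooling", 1, 960, False, "none", 1),
)

_NL = {"h-swish": nn.HSwish, "relu": nn.ReLU, "none": nn.Identity}


def _validate_rows(rows) -> None:
    for i in range(1, len(rows)):
        prev, cur = rows[i - 1], rows[i]
        if cur.input_dims[2] != prev.out_channels:
            raise ValueError(f"row {i}: input channels {cur.input_dims[2]} do not "
                             f"chain from previous out {prev.out_channels}")
        if prev.operator != "pooling":
            expect = tuple((d + prev.stride - 1) // prev.stride for d in prev.input_dims[:2])
            if cur.input_dims[:2] != expect:
                raise ValueError(f"row {i}: spatial dims {cur.input_dims[:2]} do not "
                                 f"chain from {prev.input_dims[:2]} at stride {prev.stride}")


class DepthwiseSeparable(nn.Module):
    """Depthwise spatial filtering followed by 1x1 pointwise channel mixing.

    Parameter count (bias-free): k^2 * C_in + C_in * C_out.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.depthwise = nn.DepthwiseConv2d(in_channels, kernel_size, stride=stride,
                                            padding=(kernel_size - 1) // 2,
                                            bias=bias, rng=rng)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, bias=bias, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.pointwise(self.depthwise(x))


class _Backbone(nn.Module):
    def __init__(self, rows, rng: np.random.Generator):
        super().__init__()
        _validate_rows(rows)
        self.rows = rows
        stages: list[nn.Module] = []
        for spec in rows:
            cin = spec.input_dims[2]
            if spec.operator == "standard-conv":
                stages.append(nn.Sequential(
                    nn.Conv2d(cin, spec.out_channels, spec.kernel, stride=spec.stride,
                              padding=(spec.kernel - 1) // 2, rng=rng),
                    nn.BatchNorm2d(spec.out_channels), _NL[spec.nonlinearity]()))
            elif spec.operator == "mobile-block":
                stages.append(nn.InvertedResidual(
                    cin, spec.expanded, spec.out_channels, spec.kernel,
                    spec.stride, spec.use_se,
                    {"h-swish": "HS", "relu": "RE"}[spec.nonlinearity], rng=rng))
            elif spec.operator == "pointwise-conv":
                stages.append(nn.Sequential(
                    nn.Conv2d(cin, spec.out_channels, 1, rng=rng),
                    nn.BatchNorm2d(spec.out_channels), _NL[spec.nonlinearity]()))
            elif spec.operator == "pooling":
                stages.append(nn.GlobalAvgPool2d())
            else:
                raise ValueError(f"unknown operator {spec.operator!r}")
        self.stages = nn.Sequential(*stages)
        # 1x1 conv on a 1x1 map == linear layer; no batch norm (bias instead)
        self.feature_layer = nn.Linear(rows[-1].out_channels, IMAGE_FEATURE_DIM, rng=rng)
        self.feature_nl = nn.HSwish()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.feature_nl(self.feature_layer(self.stages(x)))

    def forward_with_shapes(self, x: nn.Tensor):
        """Forward pass returning the output plus every stage's output shape."""
        shapes = []
        for stage in self.stages.layers:
            x = stage(x)
            shapes.append(tuple(x.shape))
        x = self.feature_nl(self.feature_layer(x))
        shapes.append(tuple(x.shape))
        return x, shapes


def build_backbone(rows=MOBILENETV3_ROWS, rng: np.random.Generator | None = None,
                   seed: int = 0) -> _Backbone:
    """Assemble the image backbone; maps (N, 3, H, W) to a 1280-vector."""
    return _Backbone(rows, rng or np.random.default_rng(seed))


class GenderEmbedding(nn.Module):
    """Rectified affine map of the 0/1 gender scalar to a 24-vector."""

    def __init__(self, dim: int = GENDER_EMBED_DIM, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc = nn.Linear(1, dim, rng=rng or np.random.default_rng(0))

    def forward(self, g: nn.Tensor) -> nn.Tensor:
        return self.fc(g).relu()


class BoneAgeNet(nn.Module):
    """Backbone + gender embedding + fusion layer + MLP prediction head.

    The head input is the 1304-dim concatenation of the 1280-dim image
    feature and the 24-dim rectified gender embedding (1280-dim when the
    gender branch is disabled).  Prediction stage: fusion linear (width =
    fused dim, ReLU) then a one-hidden-layer MLP of the same width ending in
    one standardized-age output.
    """

    def __init__(self, use_gender: bool = True, rows=MOBILENETV3_ROWS,
                 rng: np.random.Generator | None = None, seed: int = 0):
        super().__init__()
        rng = rng or np.random.default_rng(seed)
        self.use_gender = use_gender
        self.backbone = _Backbone(rows, rng)
        self.gender_embed = GenderEmbedding(rng=rng) if use_gender else None
        fused = IMAGE_FEATURE_DIM + (GENDER_EMBED_DIM if use_gender else 0)
        self.fused_dim = fused
        self.fusion = nn.Linear(fused, fused, rng=rng)
        self.hidden = nn.Linear(fused, fused, rng=rng)
        self.out = nn.Linear(fused, 1, rng=rng)

    def fuse(self, image_feature: nn.Tensor, gender: nn.Tensor | None) -> nn.Tensor:
        if self.use_gender:
            if gender is None:
                raise ValueError("model was built with gender embedding; pass gender")
            emb = self.gender_embed(gender)
            return nn.Tensor.concat([image_feature, emb], axis=1)
        return image_feature

    def forward(self, x: nn.Tensor, gender: nn.Tensor | None = None) -> nn.Tensor:
        feat = self.backbone(x)
        fused = self.fuse(feat, gender)
        z = self.fusion(fused).relu()
        z = self.hidden(z).relu()
        return self.out(z).reshape(-1)

    def predict(self, images: np.ndarray, male: np.ndarray | None = None) -> np.ndarray:
        """Standardized-age predictions for a batch.

        ``images``: (N, H, W) grayscale in [0, 1] or (N, 3, H, W);
        grayscale is replicated to the three backbone input channels.
        """
        x = prepare_batch(images)
        g = None
        if self.use_gender:
            if male is None:
                raise ValueError("gender flags required")
            g = nn.Tensor(np.asarray(male, dtype=np.float32).reshape(-1, 1))
            if x.shape[0] != g.shape[0]:
                raise ValueError("batch size mismatch between images and gender")
        was_training = self.training
        self.eval()
        try:
            out = self.forward(nn.Tensor(x), g).data.copy()
        finally:
            self.train(was_training)
        return out


def prepare_batch(images: np.ndarray) -> np.ndarray:
    """Grayscale (N, H, W) -> replicated (N, 3, H, W) float32."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = np.repeat(images[:, None], 3, axis=1)
    if images.ndim != 4 or images.shape[1] != 3:
        raise ValueError("expected (N, H, W) grayscale or (N, 3, H, W) batch")
    return images


def count_parameters(model: nn.Module) -> int:
    """Total number of learnable scalars (batch-norm running stats excluded)."""
    return model.n_parameters()
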