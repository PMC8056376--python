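"""Radiograph pre-processing: background removal, largest-component hand
localization, cropping and histogram equalization.

Pipeline: per-image clustering -> background removal (the cluster owning the
most frame-border pixels is background) -> 8-connected component analysis ->
bounding box of the maximum-area component (the hand), expanded by a small
margin -> crop -> global histogram equalization -> pad to square and resize
to the model input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.transform import resize

from .geometry import BoundingBox
from .localization import ClusterNetConfig, segment_image

__all__ = [
    "ComponentSummary", "PreprocessConfig", "PipelineStageError",
    "foreground_mask", "connected_components", "hand_bbox", "crop",
    "equalize", "pad_to_square", "preprocess_pipeline",
]


@dataclass(frozen=True)
class ComponentSummary:
    label: int
    area: int
    bbox: BoundingBox
    touches_border: bool


class PipelineStageError(RuntimeError):
    """Failure inside a named pre-processing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def foreground_mask(labels: np.ndarray) -> np.ndarray:
    """Remove the background cluster.

    The background is taken to be the cluster label owning the largest count
    of image-border pixels (radiograph background always touches the frame
    edge); ties resolve to the lower label index.  Returns the boolean mask
    of all non-background pixels.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("no foreground separable: label map has a single label")
    border = np.concatenate([labels[0, :], labels[-1, :],
                             labels[1:-1, 0], labels[1:-1, -1]])
    background = int(np.bincount(border).argmax())  # argmax -> lowest on ties
    return labels != background


def connected_components(mask: np.ndarray) -> list[ComponentSummary]:
    """8-connected components of a binary mask, sorted by area descending."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=2)
    h, w = mask.shape
    out = []
    for region in measure.regionprops(labeled):
        rmin, cmin, rmax, cmax = region.bbox
        touches = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        out.append(ComponentSummary(label=int(region.label), area=int(region.area),
                                    bbox=BoundingBox(rmin, cmin, rmax, cmax),
                                    touches_border=touches))
    out.sort(key=lambda c: (-c.area, c.label))
    return out


def hand_bbox(components: list[ComponentSummary], frame_shape: tuple[int, int],
              margin: float = 0.02) -> BoundingBox:
    """Bounding box of the maximum-area component, expanded by ``margin``
    (a fraction of each frame dimension) and clipped to the frame."""
    if not components:
        raise ValueError("no hand found: component list is empty")
    biggest = max(components, key=lambda c: c.area)
    h, w = frame_shape
    return biggest.bbox.expand(int(round(margin * h)), int(round(margin * w)), h, w)


def crop(image: np.ndarray, bbox: BoundingBox) -> np.ndarray:
    """Extract the half-open window [row_min,row_max) x [col_min,col_max)."""
    h, w = image.shape[:2]
    if bbox.row_max > h or bbox.col_max > w:
        raise ValueError(f"bbox {bbox} outside {h}x{w} frame")
    return image[bbox.row_min:bbox.row_max, bbox.col_min:bbox.col_max].copy()


def equalize(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization on 8-bit quantized intensities.

    Uses the classical CDF remapping with cdf_min normalization,
    level -> round(255 * (cdf(level) - cdf_min) / (n_pixels - cdf_min)),
    so the darkest occupied level maps to 0 and the brightest to 255.
    Accepts uint8 or float-in-[0,1] input; returns uint8 of the same shape.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("equalize expects a single-channel image")
    if image.dtype != np.uint8:
        image = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    hist = np.bincount(image.ravel(), minlength=256)
    cdf = hist.cumsum()
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    n = image.size
    if n == cdf_min:  # constant image: nothing to equalize
        return image.copy()
    lut = np.round(255.0 * (cdf - cdf_min) / (n - cdf_min)).clip(0, 255).astype(np.uint8)
    return lut[image]


def pad_to_square(image: np.ndarray, fill: float | None = None) -> np.ndarray:
    """Pad to square with the background level (median of the border pixels
    unless ``fill`` is given), preserving the aspect ratio for resizing."""
    h, w = image.shape
    if h == w:
        return image
    if fill is None:
        border = np.concatenate([image[0, :], image[-1, :], image[1:-1, 0], image[1:-1, -1]])
        fill = np.median(border)
    side = max(h, w)
    out = np.full((side, side), fill, dtype=image.dtype)
    r0, c0 = (side - h) // 2, (side - w) // 2
    out[r0:r0 + h, c0:c0 + w] = image
    return out


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings of the full pre-processing pipeline."""

    size: int = 224                 # square model input side, pixels
    margin: float = 0.02            # bbox expansion, fraction of each dimension
    apply_equalization: bool = True
    enabled: bool = True            # False = pass-through (resize only)
    clustering: ClusterNetConfig = field(default_factory=ClusterNetConfig)


def preprocess_pipeline(image: np.ndarray, config: PreprocessConfig | None = None,
                        seed: int = 0, label_map: np.ndarray | None = None,
                        return_intermediates: bool = False):
    """Raw radiograph -> cropped, equalized, square hand image.

    With ``config.enabled`` False the localization/crop/equalization stages
    are skipped (the pass-through ablation) and the image is only padded to
    square and resized.  A precomputed ``label_map`` skips the clustering
    stage.  ``return_intermediates`` additionally returns the per-stage
    artifacts (label map, mask, box, crop).  Errors are tagged with the name
    of the failing stage.
    """
    config = config or PreprocessConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise PipelineStageError("input", "expected a 2-D grayscale image")
    intermediates: dict = {}

    if not config.enabled:
        final = resize(pad_to_square(image), (config.size, config.size),
                       anti_aliasing=True)
        final = np.clip(np.round(final * 255.0), 0, 255).astype(np.uint8)
        return (final, intermediates) if return_intermediates else final

    try:
        if label_map is None:
            label_map = segment_image(image, config.clustering, seed=seed)
        intermediates["label_map"] = label_map
    except Exception as exc:  # noqa: BLE001 - tag with stage
        raise PipelineStageError("segment", str(exc)) from exc
    try:
        mask = foreground_mask(label_map)
        intermediates["mask"] = mask
    except Exception as exc:
        raise PipelineStageError("foreground", str(exc)) from exc
    try:
        components = connected_components(mask)
        box = hand_bbox(components, image.shape, margin=config.margin)
        intermediates["bbox"] = box
    except Exception as exc:
        raise PipelineStageError("bbox", str(exc)) from exc
    try:
        cropped = crop(image, box)
        intermediates["crop"] = cropped
    except Exception as exc:
        raise PipelineStageError("crop", str(exc)) from exc
    try:
        eq = equalize(cropped) if config.apply_equalization else \
            np.clip(np.round(cropped * 255.0), 0, 255).astype(np.uint8)
        square = pad_to_square(eq.astype(np.float64) / 255.0)
        final = resize(square, (config.size, config.size), anti_aliasing=True)
        final = np.clip(np.round(final * 255.0), 0, 255).astype(np.uint8)
    except Exception as exc:
        raise PipelineStageError("equalize-resize", str(exc)) from exc
    return (final, intermediates) if return_intermediates else final
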