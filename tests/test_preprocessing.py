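"""Background removal, component analysis vs flood-fill oracle, bounding-box
arithmetic, cropping and histogram equalization."""

import numpy as np
import pytest
from scipy import ndimage

from handage.geometry import BoundingBox
from handage.localization import ClusterNetConfig
from handage.preprocessing import (PipelineStageError, PreprocessConfig,
                                   connected_components, crop, equalize,
                                   foreground_mask, hand_bbox, pad_to_square,
                                   preprocess_pipeline)

EIGHT = np.ones((3, 3), dtype=int)


# -------------------------------------------------------------- foreground

def test_foreground_mask_border_rule():
    labels = np.zeros((10, 10), dtype=int)
    labels[3:7, 3:7] = 3
    mask = foreground_mask(labels)
    np.testing.assert_array_equal(mask, labels == 3)


def test_foreground_mask_tie_breaks_to_lower_label():
    labels = np.zeros((4, 6), dtype=int)
    labels[2:, :] = 1                       # labels 0 and 1 tie on border count
    mask = foreground_mask(labels)
    np.testing.assert_array_equal(mask, labels == 1)


def test_foreground_mask_single_label_error():
    with pytest.raises(ValueError, match="no foreground"):
        foreground_mask(np.zeros((5, 5), dtype=int))


# -------------------------------------------------------------- components

def test_components_sorted_by_area():
    mask = np.zeros((12, 12), dtype=bool)
    mask[1:4, 1:4] = True                   # area 9
    mask[8:10, 8:10] = True                 # area 4
    comps = connected_components(mask)
    assert [c.area for c in comps] == [9, 4]
    assert comps[0].bbox == BoundingBox(1, 1, 4, 4)


def test_components_full_frame():
    comps = connected_components(np.ones((6, 8), dtype=bool))
    assert len(comps) == 1
    assert comps[0].bbox == BoundingBox(0, 0, 6, 8)
    assert comps[0].touches_border


def test_components_empty_mask():
    assert connected_components(np.zeros((4, 4), dtype=bool)) == []


def test_components_match_floodfill_oracle(rng):
    for _ in range(100):
        mask = rng.random((20, 20)) < 0.35
        comps = connected_components(mask)
        labeled, n = ndimage.label(mask, structure=EIGHT)
        assert len(comps) == n
        oracle_areas = sorted(
            (ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
             .astype(int)), reverse=True)
        assert [c.area for c in comps] == oracle_areas
        if n:
            slices = ndimage.find_objects(labeled)
            oracle_boxes = {(s[0].start, s[1].start, s[0].stop, s[1].stop)
                            for s in slices}
            ours = {(c.bbox.row_min, c.bbox.col_min, c.bbox.row_max, c.bbox.col_max)
                    for c in comps}
            assert ours == oracle_boxes


# -------------------------------------------------------------------- bbox

def _component(area, box):
    from handage.preprocessing import ComponentSummary

    return ComponentSummary(label=1, area=area, bbox=box, touches_border=False)


def test_hand_bbox_zero_margin_identity():
    box = BoundingBox(10, 20, 50, 60)
    assert hand_bbox([_component(100, box)], (100, 100), margin=0.0) == box


def test_hand_bbox_picks_max_area():
    boxes = [_component(900, BoundingBox(0, 0, 30, 30)),
             _component(50, BoundingBox(40, 40, 50, 50)),
             _component(50, BoundingBox(60, 60, 70, 70))]
    assert hand_bbox(boxes, (100, 100), margin=0.0) == BoundingBox(0, 0, 30, 30)


def test_hand_bbox_margin_arithmetic():
    # 2% of a 100x100 frame = 2 px on each side
    box = BoundingBox(10, 20, 50, 60)
    out = hand_bbox([_component(100, box)], (100, 100), margin=0.02)
    assert out == BoundingBox(8, 18, 52, 62)


def test_hand_bbox_clips_to_frame():
    box = BoundingBox(0, 0, 50, 50)
    out = hand_bbox([_component(100, box)], (50, 50), margin=0.1)
    assert out == BoundingBox(0, 0, 50, 50)


def test_hand_bbox_empty_error():
    with pytest.raises(ValueError, match="no hand"):
        hand_bbox([], (10, 10))


def test_hand_bbox_contains_component():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) < 0.2
        comps = connected_components(mask)
        if not comps:
            continue
        out = hand_bbox(comps, mask.shape, margin=rng.uniform(0, 0.1))
        biggest = comps[0].bbox
        assert out.row_min <= biggest.row_min and out.row_max >= biggest.row_max
        assert out.col_min <= biggest.col_min and out.col_max >= biggest.col_max


# -------------------------------------------------------------------- crop

def test_crop_identity_and_minimal(rng):
    image = rng.random((8, 10))
    np.testing.assert_array_equal(crop(image, BoundingBox(0, 0, 8, 10)), image)
    single = crop(image, BoundingBox(3, 4, 4, 5))
    assert single.shape == (1, 1) and single[0, 0] == image[3, 4]


def test_crop_roundtrip_reembed(rng):
    image = rng.random((12, 12))
    box = BoundingBox(2, 3, 9, 11)
    piece = crop(image, box)
    canvas = np.zeros_like(image)
    canvas[box.row_min:box.row_max, box.col_min:box.col_max] = piece
    np.testing.assert_array_equal(canvas[2:9, 3:11], image[2:9, 3:11])


def test_crop_outside_frame_error(rng):
    with pytest.raises(ValueError):
        crop(np.zeros((5, 5)), BoundingBox(0, 0, 6, 5))


# ---------------------------------------------------------------- equalize

def test_equalize_two_level_cdf_formula():
    # 25% of pixels at level 10, 75% at level 200:
    # cdf(10) = 0.25 n = cdf_min -> maps to 0; cdf(200) = n -> maps to 255
    image = np.full((20, 20), 200, dtype=np.uint8)
    image[:5, :] = 10
    out = equalize(image)
    assert set(np.unique(out)) == {0, 255}
    np.testing.assert_array_equal(out == 0, image == 10)


def test_equalize_range_shape_and_monotonicity(rng):
    image = (rng.random((17, 23)) * 255).astype(np.uint8)
    out = equalize(image)
    assert out.shape == image.shape
    assert out.min() >= 0 and out.max() <= 255
    # the CDF mapping is monotone: ordering of distinct levels is preserved
    a, b = image.ravel()[:100], out.ravel()[:100]
    for i in range(100):
        for j in range(100):
            if a[i] < a[j]:
                assert b[i] <= b[j]


def test_equalize_uniform_histogram_stays_uniform():
    # every level occupied equally: mapping keeps the histogram uniform
    image = np.tile(np.arange(256, dtype=np.uint8), (8, 1))
    out = equalize(image)
    hist = np.bincount(out.ravel(), minlength=256)
    occupied = hist[hist > 0]
    assert occupied.max() - occupied.min() <= 8  # quantization slack


def test_equalize_constant_image_unchanged():
    image = np.full((5, 5), 77, dtype=np.uint8)
    np.testing.assert_array_equal(equalize(image), image)


# ---------------------------------------------------------------- pipeline

FAST = PreprocessConfig(size=64, clustering=ClusterNetConfig(p=8, q=8, n_iterations=20))


def test_pipeline_contains_hand_on_noise_free_scene():
    from handage.synthetic import SceneSpec, render_scene

    rec, gt = render_scene(SceneSpec(seed=2, noise_sd=0.0, n_distractors=2))
    final, inter = preprocess_pipeline(rec.image, FAST, seed=0,
                                       return_intermediates=True)
    assert final.shape == (64, 64)
    box = inter["bbox"]
    # the detected crop covers the whole ground-truth hand box
    assert box.row_min <= gt.hand_bbox.row_min and box.row_max >= gt.hand_bbox.row_max
    assert box.col_min <= gt.hand_bbox.col_min and box.col_max >= gt.hand_bbox.col_max


def test_pipeline_mask_overlaps_ground_truth():
    from handage.synthetic import SceneSpec, render_scene

    rec, gt = render_scene(SceneSpec(seed=2, noise_sd=0.0, n_distractors=0))
    _, inter = preprocess_pipeline(rec.image, FAST, seed=0, return_intermediates=True)
    overlap = (inter["mask"] & gt.hand_mask).sum() / gt.hand_mask.sum()
    assert overlap >= 0.8


def test_pipeline_shape_idempotent(two_region_image):
    out1 = preprocess_pipeline(two_region_image, FAST, seed=0)
    out2 = preprocess_pipeline(out1.astype(np.float64) / 255.0, FAST, seed=0)
    assert out1.shape == out2.shape == (64, 64)


def test_pipeline_passthrough_mode(two_region_image):
    config = PreprocessConfig(size=32, enabled=False)
    out = preprocess_pipeline(two_region_image, config)
    assert out.shape == (32, 32)
    # pass-through must not run localization: constant image stays untouched
    flat = preprocess_pipeline(np.full((40, 40), 0.5), config)
    assert np.unique(flat).size <= 2


def test_pipeline_errors_tagged_with_stage():
    with pytest.raises(PipelineStageError, match=r"\[foreground\]"):
        # constant image: clustering collapses to one label
        preprocess_pipeline(np.full((48, 48), 0.4), FAST, seed=0,
                            label_map=np.zeros((48, 48), dtype=int))


def test_pad_to_square(rng):
    image = rng.random((10, 6))
    out = pad_to_square(image, fill=0.0)
    assert out.shape == (10, 10)
    assert np.isin(image, out).all()
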