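"""Segmentation: feature stack, pixel classifier, thresholding, particle
extraction, erosion, 3D labeling, EM downsampling."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import mitomorph as mm
from mitomorph.preprocess import Image2D
from mitomorph.segment import ANNOT_BACKGROUND, ANNOT_MITO

from _oracles import flood_fill_components, otsu_threshold


def im(arr, s=0.1):
    return Image2D(np.asarray(arr, dtype=float), s)


# ---------------------------------------------------------------------------
# feature stack
# ---------------------------------------------------------------------------

def test_feature_stack_count_and_names():
    stack, names = mm.build_feature_stack(im(np.zeros((8, 8))), [1, 2, 4])
    assert stack.shape == (8, 8, 12)  # 1 raw + 3 G + 3 |∇| + 3 Δ + 2 DoG
    assert len(names) == 12 and names[0] == "raw"


def test_feature_stack_constant_image():
    stack, names = mm.build_feature_stack(im(np.full((8, 8), 5.0)), [1, 2])
    for k, name in enumerate(names):
        if name.startswith(("gradmag", "laplacian", "dog")):
            # zero up to the truncation error of the discrete operators
            assert np.abs(stack[..., k]).max() < 5e-3
        else:
            assert np.allclose(stack[..., k], 5.0)


def test_gradient_magnitude_of_ramp_matches_slope():
    slope = 3.0
    arr = np.tile(slope * np.arange(32), (32, 1))
    stack, names = mm.build_feature_stack(im(arr), [1.0])
    grad = stack[..., names.index("gradmag_1")]
    assert np.allclose(grad[8:-8, 8:-8], slope, rtol=1e-3)


# ---------------------------------------------------------------------------
# pixel classifier
# ---------------------------------------------------------------------------

def _two_class_fixture(seed=0, shape=(120, 120)):
    rng = np.random.default_rng(seed)
    fg = np.zeros(shape, dtype=bool)
    fg[30:60, 30:90] = True
    fg[80:100, 20:50] = True
    img = rng.normal(20, 3, shape)
    img[fg] = rng.normal(100, 5, fg.sum())
    return im(np.clip(img, 0, None)), fg


def _annotate(fg, rng, n=500):
    ann = np.zeros(fg.shape, dtype=np.uint8)
    for value, idx in ((ANNOT_MITO, np.argwhere(fg)),
                       (ANNOT_BACKGROUND, np.argwhere(~fg))):
        take = idx[rng.choice(len(idx), n, replace=False)]
        ann[tuple(take.T)] = value
    return ann


def test_pixel_classifier_separable_accuracy(rng):
    img, fg = _two_class_fixture()
    ann = _annotate(fg, rng)
    model = mm.train_pixel_classifier([img], [ann], seed=0)
    pred = mm.classify_pixels(img, model)
    held_out = ann == 0
    acc = (pred[held_out] == fg[held_out]).mean()
    assert acc > 0.95


def test_pixel_classifier_deterministic(rng):
    img, fg = _two_class_fixture()
    ann = _annotate(fg, rng)
    a = mm.classify_pixels(img, mm.train_pixel_classifier([img], [ann], seed=1))
    b = mm.classify_pixels(img, mm.train_pixel_classifier([img], [ann], seed=1))
    assert np.array_equal(a, b)


def test_pixel_classifier_rejects_single_class():
    img, fg = _two_class_fixture()
    ann = np.zeros(fg.shape, dtype=np.uint8)
    ann[:5, :5] = ANNOT_BACKGROUND
    with pytest.raises(ValueError, match="both"):
        mm.train_pixel_classifier([img], [ann])


def test_pixel_classifier_feature_mismatch_rejected(rng):
    img, fg = _two_class_fixture()
    model = mm.train_pixel_classifier([img], [_annotate(fg, rng)], sigmas=[1, 2])
    model2 = mm.PixelClassifierModel(
        forest=model.forest, feature_names=model.feature_names, sigmas=(1.0, 4.0)
    )
    with pytest.raises(ValueError, match="feature configuration"):
        mm.classify_pixels(img, model2)


def test_pixel_classifier_background_only_image_gives_empty_mask(rng):
    img, fg = _two_class_fixture()
    model = mm.train_pixel_classifier([img], [_annotate(fg, rng)], seed=0)
    blank = im(np.clip(rng.normal(20, 3, (64, 64)), 0, None))
    assert mm.classify_pixels(blank, model).sum() == 0


def test_classify_pixels_jaccard_on_noise_free_render(rng):
    spec = mm.SynthSpec2D(n_per_class=3, image_shape=(400, 400), seed=8,
                          psf_sigma_px=0, background_level=0,
                          gradient_amplitude=0, poisson_scale=0,
                          gaussian_noise_sd=0)
    arr, truth = mm.render_image(spec)
    fg = truth.label_map > 0
    img = im(arr)
    model = mm.train_pixel_classifier([img], [_annotate(fg, rng)], seed=0)
    pred = mm.classify_pixels(img, model)
    jaccard = (pred & fg).sum() / (pred | fg).sum()
    assert jaccard >= 0.9
    assert set(np.unique(pred.astype(int))) <= {0, 1}


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_otsu_between_the_two_levels():
    arr = np.full((25, 40), 20.0)
    arr[12:, :] = 80.0
    from skimage.filters import threshold_otsu
    t = threshold_otsu(arr)
    assert 20.0 < t < 80.0
    mask = mm.threshold_segment(im(arr), "otsu")
    assert mask.sum() == (arr == 80.0).sum()


def test_fixed_level_zero_selects_everything():
    assert mm.threshold_segment(im(np.ones((4, 4))), "fixed", 0.0).all()
    with pytest.raises(ValueError):
        mm.threshold_segment(im(np.ones((4, 4))), "fixed")
    with pytest.raises(ValueError):
        mm.threshold_segment(im(np.ones((4, 4))), "quantile")


def test_otsu_matches_exhaustive_variance_maximization(rng):
    from skimage.filters import threshold_otsu
    arr = rng.integers(0, 256, size=(32, 32)).astype(float)
    t = threshold_otsu(arr)
    t_brute = otsu_threshold(arr, np.unique(arr))
    assert abs(t - t_brute) <= (arr.max() - arr.min()) / 256 + 1e-9


# ---------------------------------------------------------------------------
# particle extraction
# ---------------------------------------------------------------------------

def test_min_area_filter_in_physical_units():
    mask = np.zeros((40, 40), dtype=bool)
    rr, cc = np.ogrid[:40, :40]
    mask[(rr - 10) ** 2 + (cc - 10) ** 2 <= 16] = True  # ~50 px -> 0.5 µm²
    mask[30, 30] = mask[30, 31] = True  # 2 px -> 0.02 µm²
    objs = mm.extract_objects_2d(mask, 0.1, min_area_um2=0.30)
    assert len(objs) == 1
    assert objs[0].area_um2 >= 0.30


def test_extract_empty_mask():
    assert mm.extract_objects_2d(np.zeros((8, 8), dtype=bool), 0.1) == []


@pytest.mark.parametrize("seed", range(0, 50, 5))
def test_component_count_matches_flood_fill(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((24, 24)) < 0.35
    objs = mm.extract_objects_2d(mask, 0.1, min_area_um2=0.0)
    labels = flood_fill_components(mask, connectivity=8)
    assert len(objs) == labels.max()


def test_extract_idempotent_on_own_output():
    rng = np.random.default_rng(3)
    mask = rng.random((32, 32)) < 0.3
    objs = mm.extract_objects_2d(mask, 0.1, min_area_um2=0.05)
    rebuilt = np.zeros_like(mask)
    for o in objs:
        rebuilt[tuple(o.pixel_coords.T)] = True
    objs2 = mm.extract_objects_2d(rebuilt, 0.1, min_area_um2=0.05)
    assert len(objs2) == len(objs)
    assert sum(len(o.pixel_coords) for o in objs2) == rebuilt.sum()


# ---------------------------------------------------------------------------
# erosion
# ---------------------------------------------------------------------------

def test_erosion_of_square_with_cross():
    mask = np.zeros((7, 7), dtype=bool)
    mask[1:6, 1:6] = True
    out = mm.erode_mask(mask)
    expected = np.zeros_like(mask)
    expected[2:5, 2:5] = True  # 3×3 interior survives a cross erosion
    assert np.array_equal(out, expected)


def test_erosion_removes_thin_objects_and_is_subset(rng):
    thin = np.zeros((10, 10), dtype=bool)
    thin[5, 2:8] = True  # 1-px line
    assert mm.erode_mask(thin).sum() == 0
    for _ in range(10):
        m = rng.random((16, 16)) < 0.5
        assert not (mm.erode_mask(m) & ~m).any()


# ---------------------------------------------------------------------------
# 3D labeling
# ---------------------------------------------------------------------------

def test_connectivity_6_splits_in_plane_diagonals():
    stack = np.zeros((3, 4, 4), dtype=bool)
    stack[1, 1, 1] = stack[1, 2, 2] = True
    _, objs6 = mm.label_3d(stack, 6)
    _, objs26 = mm.label_3d(stack, 26)
    assert len(objs6) == 2
    assert len(objs26) == 1


@pytest.mark.parametrize("seed", range(0, 50, 5))
def test_label_3d_matches_bfs(seed):
    rng = np.random.default_rng(seed)
    stack = rng.random((20, 20, 20)) < 0.2
    lmap, objs = mm.label_3d(stack, 6)
    ref = flood_fill_components(stack, connectivity=6)
    assert len(objs) == ref.max()
    # identical partitions: one-to-one label correspondence
    for lab in range(1, len(objs) + 1):
        vals = np.unique(ref[lmap.labels == lab])
        assert len(vals) == 1


def test_count_6_never_below_count_26(rng):
    for _ in range(10):
        stack = rng.random((12, 12, 12)) < 0.3
        _, o6 = mm.label_3d(stack, 6)
        _, o26 = mm.label_3d(stack, 26)
        assert len(o6) >= len(o26)


# ---------------------------------------------------------------------------
# EM downsampling
# ---------------------------------------------------------------------------

def test_downsample_shapes_and_scale():
    out = mm.downsample_em(im(np.full((10, 10), 5.0), 0.02), 5)
    assert out.pixels.shape == (2, 2)
    assert np.allclose(out.pixels, 5.0)
    assert out.pixel_size_um == pytest.approx(0.1)


def test_downsample_ramp_closed_form():
    ramp = np.add.outer(np.arange(20) * 2.0, np.arange(25) * 3.0)
    out = mm.downsample_em(im(ramp), 5)
    expected = np.add.outer((np.arange(4) * 5 + 2) * 2.0,
                            (np.arange(5) * 5 + 2) * 3.0)
    assert np.abs(out.pixels - expected).max() <= 1e-6


def test_downsample_rejects_tiny_output():
    with pytest.raises(ValueError):
        mm.downsample_em(im(np.ones((8, 8))), 5)
    with pytest.raises(ValueError):
        mm.downsample_em(im(np.ones((100, 100))), 1)


# ---------------------------------------------------------------------------
# end-to-end segmentation of noise-free scenes
# ---------------------------------------------------------------------------

def test_noise_free_scene_recovers_every_object():
    spec = mm.SynthSpec2D(n_per_class=3, image_shape=(512, 512), seed=6,
                          min_object_gap_px=3, psf_sigma_px=0,
                          background_level=0, gradient_amplitude=0,
                          poisson_scale=0, gaussian_noise_sd=0)
    img, truth = mm.render_image(spec)
    mask = mm.threshold_segment(im(img), "fixed", 0.0)
    objs = mm.extract_objects_2d(mask, 0.1)
    assert len(objs) == truth.label_map.max()
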