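"""Grayscale, histogram, thresholding, counting, and pixel-area calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk
from skimage.filters import threshold_otsu as skimage_otsu

from phenotray import (
    CalibrationReference,
    PlantSpec,
    TrayScene,
    count_plants,
    intensity_histogram,
    measure_quadrant,
    otsu_threshold,
    pixels_to_cm2,
    render_tray,
    segment_plants,
    to_grayscale,
)

from .conftest import disc_pixels_bruteforce, exhaustive_otsu_variances, flood_fill_components


@pytest.mark.parametrize(
    "rgb,expected",
    [((255, 255, 255), 255), ((100, 150, 50), 124), ((0, 0, 0), 0), ((255, 0, 0), 76)],
)
def test_grayscale_luma_rounded_half_up(rgb, expected):
    img = np.full((3, 3, 3), rgb, dtype=np.uint8)
    assert np.all(to_grayscale(img) == expected)


def test_grayscale_rejects_wrong_channel_count():
    with pytest.raises(ValueError, match="RGB"):
        to_grayscale(np.zeros((4, 4), dtype=np.uint8))


def test_histogram_uniform_image():
    hist = intensity_histogram(np.full((10, 10), 7, dtype=np.uint8))
    assert hist[7] == 100
    assert hist.sum() == 100
    assert np.count_nonzero(hist) == 1


def test_histogram_matches_per_pixel_tally():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
    hist = intensity_histogram(img)
    tally = [0] * 256
    for v in img.ravel():
        tally[int(v)] += 1
    assert hist.tolist() == tally
    assert hist.sum() == 256


def test_otsu_bimodal_threshold_lies_between_modes():
    img = np.concatenate([np.full(100, 50), np.full(100, 200)]).astype(np.uint8).reshape(10, 20)
    result = segment_plants(img, method="otsu")
    assert 50 < result.threshold_used < 200
    assert int(result.mask.sum()) == 100
    # the chosen threshold attains the exhaustive-search maximum variance
    variances = exhaustive_otsu_variances(img)
    assert variances[int(np.floor(result.threshold_used))] == pytest.approx(variances.max())


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_otsu_attains_exhaustive_maximum_on_random_images(seed):
    rng = np.random.default_rng(seed)
    # bimodal-ish random image so the threshold is meaningful
    img = np.where(
        rng.random((32, 32)) < 0.4,
        rng.integers(0, 90, (32, 32)),
        rng.integers(120, 256, (32, 32)),
    ).astype(np.uint8)
    t = otsu_threshold(img)
    variances = exhaustive_otsu_variances(img)
    assert variances[int(np.floor(t))] == pytest.approx(variances.max(), rel=1e-12)
    # cross-check against the reference library implementation
    t_ref = skimage_otsu(img)
    assert variances[int(np.floor(t_ref))] == pytest.approx(variances.max(), rel=1e-9)


def test_otsu_constant_image_degenerate():
    result = segment_plants(np.full((8, 8), 42, dtype=np.uint8), method="otsu")
    assert result.degenerate
    assert not result.mask.any()


def test_fixed_threshold_half_and_half():
    img = np.zeros((10, 10), dtype=np.uint8)
    img[:, 5:] = 255
    result = segment_plants(img, method="fixed", fixed_threshold=128)
    assert int(result.mask.sum()) == 50
    assert np.array_equal(result.mask, img == 255)


def test_excess_green_picks_green_discs_ignores_red():
    img = np.full((50, 50, 3), 30, dtype=np.uint8)
    for r, c in disc_pixels_bruteforce((25, 25), 6):
        img[r, c] = (0, 200, 0)
    rr, cc = disk((10, 10), 4)
    img[rr, cc] = (255, 0, 0)  # fiducial-colored clutter
    result = segment_plants(img, method="excess_green")
    assert int(result.mask.sum()) == len(disc_pixels_bruteforce((25, 25), 6))


def test_count_plants_empty_mask():
    count, area, _ = count_plants(np.zeros((20, 20), dtype=bool))
    assert count == 0 and area == 0


def test_count_two_separate_discs_matches_flood_fill():
    mask = np.zeros((60, 100), dtype=bool)
    for center in [(30, 25), (30, 65)]:  # 40 px apart, radius 10
        rr, cc = disk(center, 10, shape=mask.shape)
        mask[rr, cc] = True
    count, area, _ = count_plants(mask, min_area_px=5)
    oracle = flood_fill_components(mask)
    assert count == len(oracle) == 2
    assert area == sum(oracle)


def test_overlapping_discs_merge_into_one_component():
    mask = np.zeros((60, 60), dtype=bool)
    for center in [(30, 25), (30, 35)]:
        rr, cc = disk(center, 10, shape=mask.shape)
        mask[rr, cc] = True
    count, _, _ = count_plants(mask)
    assert count == len(flood_fill_components(mask)) == 1


def test_min_area_filter_drops_specks():
    mask = np.zeros((30, 30), dtype=bool)
    mask[5, 5] = True  # 1-px speck
    rr, cc = disk((20, 20), 4, shape=mask.shape)
    mask[rr, cc] = True
    count, area, _ = count_plants(mask, min_area_px=5)
    assert count == 1
    assert area == int(mask.sum()) - 1


def test_count_plants_rejects_negative_min_area():
    with pytest.raises(ValueError, match="min_area_px"):
        count_plants(np.zeros((5, 5), dtype=bool), min_area_px=-1)


@pytest.mark.parametrize("connectivity", [4, 8])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_component_counts_match_flood_fill_on_random_masks(seed, connectivity):
    rng = np.random.default_rng(seed)
    mask = rng.random((64, 64)) < 0.35
    count, area, _ = count_plants(mask, min_area_px=1, connectivity=connectivity)
    oracle = flood_fill_components(mask, connectivity=connectivity)
    assert count == len(oracle)
    assert area == sum(oracle)


def test_diagonal_connectivity_semantics():
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = mask[1, 1] = True  # touch only diagonally
    assert count_plants(mask, min_area_px=1, connectivity=8)[0] == 1
    assert count_plants(mask, min_area_px=1, connectivity=4)[0] == 2


def test_pixels_to_cm2_hand_computed(calib_10px_per_cm):
    assert pixels_to_cm2(0, calib_10px_per_cm) == 0.0
    assert pixels_to_cm2(400, calib_10px_per_cm) == pytest.approx(4.0)
    unit = CalibrationReference(a=7.0, b=7.0)  # 1 px per cm
    assert pixels_to_cm2(1234, unit) == pytest.approx(1234.0)


@settings(max_examples=50, derandomize=True)
@given(
    x=st.floats(0, 1e7),
    k=st.floats(0, 100),
    a=st.floats(1, 1e4),
    b=st.floats(0.1, 100),
)
def test_pixels_to_cm2_is_linear(x, k, a, b):
    calib = CalibrationReference(a=a, b=b)
    assert pixels_to_cm2(k * x, calib) == pytest.approx(k * pixels_to_cm2(x, calib), abs=1e-9)


def test_pixels_to_cm2_rejects_bad_inputs(calib_10px_per_cm):
    with pytest.raises(ValueError):
        pixels_to_cm2(-1, calib_10px_per_cm)
    with pytest.raises(ValueError):
        CalibrationReference(a=0, b=10)
    with pytest.raises(ValueError):
        CalibrationReference(a=10, b=-1)


def _gray_quadrant_with_discs(centers, radius=5, shape=(100, 100), value=220):
    img = np.full(shape, 15, dtype=np.uint8)
    for center in centers:
        for r, c in disc_pixels_bruteforce(center, radius, shape=shape):
            img[r, c] = value
    return img


def test_measure_quadrant_germination_from_eleven_of_twelve():
    centers = [(15 + 22 * (i // 4), 15 + 22 * (i % 4)) for i in range(11)]
    img = _gray_quadrant_with_discs(centers)
    m = measure_quadrant(img, CalibrationReference(100, 10), n_sown=12, method="otsu")
    assert m.plant_count == 11
    assert m.germination_pct == pytest.approx(100 * 11 / 12, abs=0.01)  # 91.67


def test_measure_quadrant_blank():
    img = np.full((80, 80), 15, dtype=np.uint8)
    m = measure_quadrant(img, CalibrationReference(100, 10), n_sown=12, method="otsu")
    assert m.plant_count == 0
    assert m.pcs_cm2 == 0.0
    assert m.germination_pct == 0.0
    assert "degenerate_image" in m.flags


def test_measure_quadrant_area_conversion_on_square_block():
    img = np.full((100, 100), 10, dtype=np.uint8)
    img[30:60, 30:60] = 230  # exactly 900 foreground px
    m = measure_quadrant(img, CalibrationReference(100, 10), n_sown=4, method="otsu")
    assert m.area_px == 900
    assert m.pcs_cm2 == pytest.approx(9.0)


def test_germination_capped_and_flagged_when_count_exceeds_sown():
    centers = [(15 + 22 * (i // 4), 15 + 22 * (i % 4)) for i in range(6)]
    img = _gray_quadrant_with_discs(centers)
    m = measure_quadrant(img, CalibrationReference(100, 10), n_sown=4, method="otsu")
    assert m.plant_count == 6
    assert m.germination_pct == 100.0
    assert "count_exceeds_sown" in m.flags


def test_pcs_is_resolution_invariant():
    """The same physical scene imaged at 2x resolution (areas x4, calibration
    a x2) yields the same canopy size in cm² to within rasterization error."""
    m1 = measure_quadrant(
        _gray_quadrant_with_discs([(50, 50)], radius=10),
        CalibrationReference(100, 10),
        n_sown=1,
        method="otsu",
    )
    m2 = measure_quadrant(
        _gray_quadrant_with_discs([(100, 100)], radius=20, shape=(200, 200)),
        CalibrationReference(200, 10),
        n_sown=1,
        method="otsu",
    )
    assert m2.pcs_cm2 == pytest.approx(m1.pcs_cm2, rel=0.02)


def test_noiseless_rendered_quadrants_measure_exactly_ground_truth():
    scene = TrayScene(
        plants=(
            PlantSpec(1, (60.0, 60.0), 9.0),
            PlantSpec(2, (55.0, 170.0), 7.0),
            PlantSpec(4, (170.0, 170.0), 12.0),
        )
    )
    img, gt = render_tray(scene)
    from phenotray import detect_markers, rectify_to_square, split_quadrants

    square = rectify_to_square(img, detect_markers(img), 200)
    for quad in split_quadrants(square):
        m = measure_quadrant(
            quad.image, CalibrationReference(100, 10), n_sown=4, method="excess_green"
        )
        assert m.plant_count == gt.plant_count[quad.quadrant_id]
        assert m.area_px == gt.area_px[quad.quadrant_id]
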