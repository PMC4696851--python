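"""Phantom evaluation, the pairwise contrast matrix, Otsu segmentation and
contrast-improvement measurement."""

import numpy as np
import pytest

from bistain import (
    EmptyForegroundError,
    apply_map_to_phantom,
    contrast_improvement,
    deconvolve,
    design_map,
    fit_stain_model,
    foreground_mask,
    generate_ihc,
    make_phantom,
    packaged_phantom_colors,
    pairwise_matrix,
    phantom_contrast,
    restain_image,
    rgb_to_lab,
    delta_e,
)
from bistain.evaluation import default_phantom_coords, otsu_threshold

BLUE, ORANGE = "#006EFF", "#FFAD00"
BROWN, STDBLUE = "#B58C70", "#5C5FA1"


# --- phantom geometry -------------------------------------------------------


def test_default_coords_cover_both_axes():
    c = default_phantom_coords()
    assert c.shape == (36, 2)
    assert set(np.round(np.unique(c[:, 0]), 6)) == set(
        np.round((np.arange(6) + 1) / 6, 6)
    )
    assert c.min() > 0 and c.max() == 1.0


def test_circles_disjoint_and_inside_canvas():
    p = make_phantom()
    masks = p.fg_masks()
    total = np.zeros_like(p.label_image, dtype=int)
    for m in masks:
        total += m
    assert total.max() == 1  # pairwise disjoint
    assert all(m.any() for m in masks)
    border = np.concatenate(
        [p.label_image[0], p.label_image[-1], p.label_image[:, 0], p.label_image[:, -1]]
    )
    assert np.all(border == -1)


def test_foreground_area_fraction_matches_geometry():
    p = make_phantom(cell=64)
    frac = float(np.mean(p.label_image >= 0))
    expected = 36 * np.pi * p.radius**2 / p.label_image.size
    assert np.isclose(frac, expected, rtol=0.02)  # pixelated circles


def test_phantom_rejects_bad_levels():
    with pytest.raises(ValueError):
        make_phantom(coords=np.zeros((10, 2)))
    with pytest.raises(ValueError):
        make_phantom(coords=np.full((36, 2), 1.5))


# --- rendering and contrast -------------------------------------------------


def test_background_is_homogeneous_counterstain():
    p = make_phantom()
    img = apply_map_to_phantom(p, BLUE, ORANGE)
    bg = img[p.bg_mask()]
    assert np.all(bg == bg[0])
    # background renders the pure background hue, (u, v) = (0, 1)
    m = design_map(BLUE, ORANGE)
    assert np.allclose(bg[0], np.round(m.evaluate(0.0, 1.0)), atol=1.0)


def test_full_intensity_circle_is_darkest():
    p = make_phantom()
    img = apply_map_to_phantom(p, BLUE, ORANGE)
    labs = rgb_to_lab(img)
    k_full = int(np.argmax(p.circle_coords.sum(axis=1)))
    full_L = labs[p.label_image == k_full][..., 0].mean()
    assert full_L < 15.0  # near-black mixture corner


def test_same_hue_pair_has_low_contrast():
    mean_same, _ = phantom_contrast(make_phantom(), STDBLUE, STDBLUE)
    mean_diff, _ = phantom_contrast(make_phantom(), BLUE, ORANGE)
    assert mean_same < 0.6 * mean_diff


def test_contrast_resolution_invariant():
    """Scores depend on (u, v) levels, not on canvas resolution."""
    a = phantom_contrast(make_phantom(cell=32), BROWN, STDBLUE)
    b = phantom_contrast(make_phantom(cell=96), BROWN, STDBLUE)
    assert np.allclose(a, b, atol=1e-9)


def test_swap_symmetry_against_recomputation():
    """Swapping fg/bg is the map transpose; verified by recomputation with
    the transposed circle coordinates and background coordinate."""
    p = make_phantom()
    fwd = phantom_contrast(p, BROWN, STDBLUE)
    p_swapped = make_phantom(coords=p.circle_coords[:, ::-1])
    m = design_map(STDBLUE, BROWN)
    circ = m.evaluate(
        p_swapped.circle_coords[:, 0], p_swapped.circle_coords[:, 1], space="lab"
    )
    bg = m.evaluate(1.0, 0.0, space="lab")
    d = delta_e(circ, bg)
    # transposing both map and coordinates reproduces the forward scores
    assert np.allclose(fwd, (d.mean(), d.std()), atol=1e-9)


def test_standard_pair_far_below_best_pair():
    brown_blue, _ = phantom_contrast(make_phantom(), BROWN, STDBLUE)
    blue_orange, _ = phantom_contrast(make_phantom(), BLUE, ORANGE)
    assert brown_blue < 0.5 * blue_orange


# --- pairwise matrix --------------------------------------------------------


@pytest.fixture(scope="module")
def matrix():
    return pairwise_matrix()


def test_matrix_normalization(matrix):
    assert matrix.mean_grid.shape == (15, 15)
    assert matrix.mean_grid.max() == 1.0
    assert matrix.mean_grid.min() >= 0.0
    assert not matrix.duplicates


def test_standard_pair_in_printed_band(matrix):
    """Brown-on-blue scores 39% +- 7% of the best achievable contrast."""
    mean, sd = matrix.lookup(BROWN, STDBLUE)
    assert abs(mean - 0.39) <= 0.07
    assert 0.0 < sd < 0.25


def test_improvement_factor_over_standard(matrix):
    mean, _ = matrix.lookup(BROWN, STDBLUE)
    assert abs(1.0 / mean - 2.56) <= 0.4


def test_best_pair_is_chroma_separated(matrix):
    i, j = np.unravel_index(np.argmax(matrix.mean_grid), (15, 15))
    labs = rgb_to_lab(
        np.stack([np.array([int(matrix.colors[k][s:s+2], 16) for s in (1, 3, 5)], float)
                  for k in (i, j)])
    )
    chroma = np.hypot(labs[:, 1], labs[:, 2])
    assert np.all(chroma > 30)  # both hues strongly chromatic
    # and on opposite sides of the a*/b* plane
    assert np.dot(labs[0, 1:], labs[1, 1:]) < 0


def test_packaged_colors_fixture():
    colors = packaged_phantom_colors()
    assert len(colors) == 15
    for must in (BROWN, STDBLUE, BLUE, ORANGE, "#000000", "#FFFFFF"):
        assert must in colors


def test_duplicate_colors_flagged():
    mat = pairwise_matrix(colors=[BLUE, BLUE, ORANGE])
    assert mat.duplicates == [BLUE]


# --- Otsu segmentation ------------------------------------------------------


def test_otsu_matches_library_on_bimodal(rng):
    from skimage.filters import threshold_otsu

    vals = np.concatenate(
        [rng.normal(0.2, 0.05, 4000), rng.normal(0.9, 0.05, 2000)]
    )
    ours = otsu_threshold(vals)
    theirs = threshold_otsu(vals, nbins=256)
    assert abs(ours - theirs) < 0.02  # same split up to binning convention


def test_foreground_mask_recovers_blobs(hdab_sample, fitted_model):
    conc = deconvolve(hdab_sample.image, fitted_model.basis)
    mask = foreground_mask(conc)
    gt = hdab_sample.object_mask()
    dice = 2 * np.sum(mask & gt) / (mask.sum() + gt.sum())
    assert dice > 0.9


def test_blank_image_has_no_foreground():
    s = generate_ihc(seed=3, n_objects=0)
    conc = deconvolve(s.image, fit_stain_model(s.image, reference="ruifrok").basis)
    with pytest.raises(EmptyForegroundError):
        foreground_mask(conc, min_object_px=64)


def test_small_blob_removed_by_cleaning():
    s = generate_ihc(seed=31, n_objects=1, radius_range=(3, 4), noise_sd=0.0)
    conc = deconvolve(s.image, s.true_basis)
    with pytest.raises(EmptyForegroundError):
        foreground_mask(conc, min_object_px=500)


# --- contrast improvement ---------------------------------------------------


def test_identity_improvement_is_zero(hdab_sample, fitted_model):
    conc = deconvolve(hdab_sample.image, fitted_model.basis)
    mask = foreground_mask(conc)
    rep = contrast_improvement(hdab_sample.image, hdab_sample.image, mask)
    assert rep.improvement_pct == 0.0


def test_restaining_improves_contrast(hdab_sample, fitted_model):
    conc = deconvolve(hdab_sample.image, fitted_model.basis)
    conc.normalize()
    mask = foreground_mask(conc)
    res = restain_image(
        hdab_sample.image,
        fitted_model,
        design_map(BLUE, ORANGE),
        norm_lo=conc.norm_lo,
        norm_hi=conc.norm_hi,
    )
    rep = contrast_improvement(hdab_sample.image, res.image, mask)
    assert rep.improvement_pct > 0.0


def test_swapping_images_inverts_ratio(hdab_sample, fitted_model):
    conc = deconvolve(hdab_sample.image, fitted_model.basis)
    conc.normalize()
    mask = foreground_mask(conc)
    res = restain_image(
        hdab_sample.image, fitted_model, design_map(BLUE, ORANGE),
        norm_lo=conc.norm_lo, norm_hi=conc.norm_hi,
    )
    fwd = contrast_improvement(hdab_sample.image, res.image, mask)
    rev = contrast_improvement(res.image, hdab_sample.image, mask)
    r_fwd = fwd.contrast_after / fwd.contrast_before
    r_rev = rev.contrast_after / rev.contrast_before
    assert np.isclose(np.log(r_fwd), -np.log(r_rev), atol=1e-9)


def test_degenerate_mask_rejected(hdab_sample):
    with pytest.raises(ValueError):
        contrast_improvement(
            hdab_sample.image,
            hdab_sample.image,
            np.zeros(hdab_sample.image.shape[:2], bool),
        )
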