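"""Candidate trees, rule-based nucleus selection, ellipses, cytosol, spots."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cycliq import (
    NucleusParams,
    SpotParams,
    build_cell_regions,
    detect_spots,
    expand_cytosol,
    extract_candidates,
    fit_ellipse,
    select_nuclei,
)
from cycliq._geometry import ellipse_interior

from _oracles import enumerate_nuclei


def _disk(shape, center, radius, value=1.0):
    img = np.zeros(shape)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return img


# ---------------------------------------------------------------------------
# candidate tree


def test_single_disk_yields_single_root_chain():
    img = gaussian_filter(_disk((64, 64), (32, 32), 10), 2)
    tree = extract_candidates(img, n_levels=8)
    assert len(tree) > 0
    # one component per level -> every region has <= 1 child
    assert all(len(r.children) <= 1 for r in tree.regions)
    roots = [r for r in tree.regions if r.parent is None]
    assert len(roots) == 1


def test_two_blobs_merge_into_one_root_with_two_children():
    img = (
        np.exp(-((np.indices((64, 64))[0] - 32) ** 2 + (np.indices((64, 64))[1] - 22) ** 2) / 50)
        + np.exp(-((np.indices((64, 64))[0] - 32) ** 2 + (np.indices((64, 64))[1] - 42) ** 2) / 50)
    )
    tree = extract_candidates(img, n_levels=16)
    branching = [r for r in tree.regions if len(r.children) == 2]
    assert branching, "expected a region splitting into two children"
    # verify containment by brute-force pixel comparison
    for r in branching:
        parent_mask = r.full_mask(tree.shape)
        for ci in r.children:
            child_mask = tree.regions[ci].full_mask(tree.shape)
            assert (child_mask & ~parent_mask).sum() == 0


def test_child_masks_are_subsets_of_parents():
    rng = np.random.default_rng(0)
    img = gaussian_filter(rng.random((48, 48)), 2)
    tree = extract_candidates(img, n_levels=10)
    for r in tree.regions:
        if r.parent is not None:
            pm = tree.regions[r.parent].full_mask(tree.shape)
            assert (r.full_mask(tree.shape) & ~pm).sum() == 0


def test_all_zero_and_constant_images_give_empty_tree():
    assert len(extract_candidates(np.zeros((32, 32)), 8)) == 0
    assert len(extract_candidates(np.full((32, 32), 0.7), 8)) == 0


# ---------------------------------------------------------------------------
# nucleus selection rules


def test_small_disk_rejected_by_min_area():
    # radius 15 -> area ~707, below the 1200 px minimum
    img = _disk((128, 128), (64, 64), 15, 0.9)
    tree = extract_candidates(img, n_levels=8)
    params = NucleusParams(peak_intensity_threshold=0.1)
    assert select_nuclei(tree, params) == []


def test_rectangle_rejected_by_circularity():
    img = np.zeros((64, 128))
    img[26:38, 10:110] = 0.9  # 12 x 100 = 1200 px
    tree = extract_candidates(img, n_levels=4)
    rect = max(tree.regions, key=lambda r: r.area)
    assert rect.area == 1200
    assert rect.circularity < 0.8  # elongated: fails the isoperimetric rule
    params = NucleusParams(peak_intensity_threshold=0.1)
    assert select_nuclei(tree, params) == []


def test_nested_qualifying_candidates_keep_largest():
    img = _disk((160, 160), (80, 80), 30, 0.5)  # halo, area ~2827
    img += _disk((160, 160), (80, 80), 25, 0.5)  # core at 1.0, area ~1963
    tree = extract_candidates(img, n_levels=8)
    params = NucleusParams(peak_intensity_threshold=0.3)
    masks = select_nuclei(tree, params)
    assert len(masks) == 1
    assert masks[0].sum() == pytest.approx(math.pi * 30**2, rel=0.02)


def test_auto_threshold_requires_resolution():
    img = _disk((128, 128), (64, 64), 25, 0.9)
    tree = extract_candidates(img, n_levels=8)
    with pytest.raises(ValueError, match="auto"):
        select_nuclei(tree, NucleusParams())
    resolved = NucleusParams().resolve(img)
    assert isinstance(resolved.peak_intensity_threshold, float)
    assert len(select_nuclei(tree, resolved)) == 1


@pytest.mark.parametrize("seed", range(3))
def test_selection_matches_literal_enumeration_oracle(seed):
    """Tree-based selection == brute-force (threshold, component) enumeration."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.random((64, 64)), 3)
    img = (img - img.min()) / np.ptp(img)
    params = NucleusParams(
        min_area=60, max_area=2000, circularity_min=0.8,
        peak_intensity_threshold=0.5, n_threshold_levels=12,
    )
    tree = extract_candidates(img, params.n_threshold_levels)
    got = select_nuclei(tree, params)
    expected = enumerate_nuclei(img, 60, 2000, 0.8, 0.5, 12)
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        np.testing.assert_array_equal(g, e)


def test_raising_min_area_never_adds_regions():
    rng = np.random.default_rng(5)
    img = gaussian_filter(rng.random((64, 64)), 2.5)
    img = (img - img.min()) / np.ptp(img)
    tree = extract_candidates(img, 12)
    counts = []
    for min_area in (20, 60, 120, 300):
        p = NucleusParams(min_area=min_area, max_area=3000,
                          circularity_min=0.5, peak_intensity_threshold=0.4)
        counts.append(len(select_nuclei(tree, p)))
    assert all(b <= a for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# ellipse fitting


def test_fit_axis_aligned_ellipse():
    mask = ellipse_interior((128, 128), (64, 64), 40, 20, 0.0)
    e = fit_ellipse(mask)
    assert e.semi_major == pytest.approx(40, rel=0.02)
    assert e.semi_minor == pytest.approx(20, rel=0.02)
    assert min(e.orientation, math.pi - e.orientation) < math.radians(2)


def test_fit_rotated_ellipse():
    theta = 0.7
    mask = ellipse_interior((160, 160), (80, 80), 45, 18, theta)
    e = fit_ellipse(mask)
    assert e.semi_major == pytest.approx(45, rel=0.02)
    assert e.semi_minor == pytest.approx(18, rel=0.02)
    assert min(abs(e.orientation - theta), math.pi - abs(e.orientation - theta)) < math.radians(2)


def test_fit_disk_is_symmetric_with_zero_orientation():
    mask = _disk((96, 96), (48, 48), 20) > 0
    e = fit_ellipse(mask)
    assert e.semi_major == pytest.approx(e.semi_minor, rel=0.02)
    assert e.orientation == 0.0


def test_fit_matches_direct_moment_computation(rng):
    blob = gaussian_filter(rng.random((48, 48)), 3) > 0.5
    if blob.sum() < 5:
        pytest.skip("degenerate draw")
    e = fit_ellipse(blob)
    ys, xs = np.nonzero(blob)
    dr, dc = ys - ys.mean(), xs - xs.mean()
    cov = np.array(
        [[np.mean(dr * dr) + 1 / 12, np.mean(dr * dc)],
         [np.mean(dr * dc), np.mean(dc * dc) + 1 / 12]]
    )
    lam = np.linalg.eigvalsh(cov)
    assert e.semi_minor == pytest.approx(2 * math.sqrt(lam[0]), abs=1e-9)
    assert e.semi_major == pytest.approx(2 * math.sqrt(lam[1]), abs=1e-9)


def test_fit_empty_mask_raises():
    with pytest.raises(ValueError):
        fit_ellipse(np.zeros((10, 10), dtype=bool))


# ---------------------------------------------------------------------------
# cytosol rings


def test_isolated_ring_area_matches_analytic():
    mask = ellipse_interior((256, 256), (128, 128), 30, 15, 0.0)
    e = fit_ellipse(mask)
    ring = expand_cytosol(e, mask, (256, 256))
    analytic = math.pi * ((30 + 25) * (15 + 15) - 30 * 15)
    assert ring.sum() == pytest.approx(analytic, rel=0.03)
    assert not (ring & mask).any()


def test_adjacent_cells_share_no_cytosol_and_split_by_distance():
    shape = (200, 260)
    m1 = ellipse_interior(shape, (100, 90), 25, 20, 0.0)
    m2 = ellipse_interior(shape, (100, 170), 25, 20, 0.0)
    regions = build_cell_regions([m1, m2], shape)
    c1, c2 = regions.cytosol_mask(1), regions.cytosol_mask(2)
    assert not (c1 & c2).any()
    assert not (c1 & (m1 | m2)).any() and not (c2 & (m1 | m2)).any()
    # contested midline pixels go to the nearer centroid
    ys, xs = np.nonzero(c1)
    d1 = (ys - 100.0) ** 2 + (xs - 90.0) ** 2
    d2 = (ys - 100.0) ** 2 + (xs - 170.0) ** 2
    assert (d1 <= d2).all()


def test_border_nucleus_ring_is_clipped():
    shape = (120, 120)
    mask = ellipse_interior(shape, (10, 60), 20, 12, 0.0)
    regions = build_cell_regions([mask], shape)
    ring = regions.cytosol_mask(1)
    assert ring.sum() > 0  # clipped but present; no exception, no wraparound
    assert regions.border_flags()[0]


# ---------------------------------------------------------------------------
# spots


def _blob(shape, center, sigma, peak):
    rr, cc = np.indices(shape, dtype=float)
    return peak * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


def test_single_qualifying_blob_is_one_spot():
    img = 0.02 + _blob((96, 96), (48, 48), 4.0, 0.5)
    spots = detect_spots(img, SpotParams())
    assert len(spots) == 1
    assert spots.iloc[0]["row"] == pytest.approx(48, abs=1.0)
    assert spots.iloc[0]["peak"] >= 0.2


def test_blob_below_peak_threshold_rejected():
    img = 0.02 + _blob((96, 96), (48, 48), 4.0, 0.1)
    assert len(detect_spots(img, SpotParams())) == 0


def test_ten_separated_blobs_counted_exactly():
    img = np.full((256, 256), 0.02)
    centers = [(40 * (i // 5) + 60, 40 * (i % 5) + 40) for i in range(10)]
    for c in centers:
        img += _blob((256, 256), c, 3.0, 0.6)
    spots = detect_spots(img, SpotParams())
    assert len(spots) == 10
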