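"""Background subtraction, outline rasterization and the three masks."""
import numpy as np
import pytest
from shapely.geometry import Polygon

from ajquant import (
    MultiChannelImage,
    derive_membrane_ring,
    load_cell_outlines,
    segment,
    subtract_background,
    threshold_nucleus,
)
from ajquant.segmentation import PlacementError, rasterize_polygons

from conftest import rect_labels


def _img(arr, **kw):
    return MultiChannelImage({"ch": np.asarray(arr, float)}, **kw)


# ---------------------------------------------------------------- background
class TestSubtractBackground:
    def test_constant_channel_goes_to_zero_and_records_scalar(self):
        out = subtract_background(_img(np.full((4, 4), 7.0)))
        assert np.all(out["ch"] == 0)
        assert out.metadata["background"]["ch"] == 7.0

    def test_zero_median_leaves_image_unchanged(self):
        arr = np.array([[0.0, 0.0], [0.0, 10.0]])
        out = subtract_background(_img(arr))
        assert out.metadata["background"]["ch"] == 0.0
        assert np.array_equal(out["ch"], arr)

    def test_median_on_toy_grid(self):
        # 20 background pixels at 4, 5 signal pixels at 104: median of the
        # 25 sorted values is 4 (independent enumeration), signal -> 100
        arr = np.full((5, 5), 4.0)
        arr.ravel()[[3, 7, 11, 17, 22]] = 104.0
        assert float(np.sort(arr.ravel())[12]) == 4.0  # oracle: middle of 25
        out = subtract_background(_img(arr))
        assert out.metadata["background"]["ch"] == 4.0
        assert np.sort(out["ch"].ravel())[-5:].tolist() == [100.0] * 5

    def test_mode_statistic(self):
        arr = np.full((4, 4), 12.0)
        arr[0, :2] = [90.0, 95.0]
        out = subtract_background(_img(arr), stat="mode")
        assert out.metadata["background"]["ch"] == 12.0

    def test_negative_fixed_value_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            subtract_background(_img(np.ones((2, 2))), stat="fixed", values={"ch": -1.0})

    def test_median_idempotent_once_majority_is_zero(self):
        arr = np.full((6, 6), 5.0)
        arr[:2, :2] = 50.0
        once = subtract_background(_img(arr))
        twice = subtract_background(once)
        assert np.array_equal(once["ch"], twice["ch"])


# ---------------------------------------------------------------- outlines
class TestLoadCellOutlines:
    def test_integer_rectangle_center_sampling(self):
        # (0,0)-(4,3) rectangle covers pixel centers (c+0.5, r+0.5) for
        # c in 0..3, r in 0..2 -> 12 pixels
        poly = Polygon([(0, 0), (4, 0), (4, 3), (0, 3)])
        lab = load_cell_outlines({1: poly}, shape=(10, 10))
        assert lab.sum() == 12
        assert np.all(lab[:3, :4] == 1)

    def test_label_mask_passes_through(self):
        lab = rect_labels((1, 0, 3, 0, 3), (2, 5, 8, 5, 8), shape=(10, 10))
        out = load_cell_outlines(lab)
        assert np.array_equal(out, lab)
        assert out is not lab

    def test_triangles_sharing_edge_rasterize_disjoint(self):
        """Two triangles sharing the diagonal: disjoint pixel sets whose
        union matches an independent point-in-polygon oracle."""
        from matplotlib.path import Path as MplPath

        t1 = Polygon([(1, 1), (9, 1), (9, 9)])
        t2 = Polygon([(1, 1), (9, 9), (1, 9)])
        lab = load_cell_outlines({1: t1, 2: t2}, shape=(12, 12))
        assert set(np.unique(lab)) == {0, 1, 2}
        m1, m2 = lab == 1, lab == 2
        assert not np.any(m1 & m2)
        cols, rows = np.meshgrid(np.arange(12) + 0.5, np.arange(12) + 0.5)
        pts = np.c_[cols.ravel(), rows.ravel()]
        inside1 = MplPath(np.asarray(t1.exterior.coords)).contains_points(
            pts, radius=-1e-9).reshape(12, 12)
        inside2 = MplPath(np.asarray(t2.exterior.coords)).contains_points(
            pts, radius=-1e-9).reshape(12, 12)
        # every strictly-interior center is labeled with its triangle;
        # centers outside both triangles stay background
        assert np.all(lab[inside1 & ~inside2] == 1)
        assert np.all(lab[inside2 & ~inside1] == 2)
        assert np.all(lab[~inside1 & ~inside2] == 0)

    def test_overlapping_polygons_rejected(self):
        a = Polygon([(0, 0), (6, 0), (6, 6), (0, 6)])
        b = Polygon([(3, 3), (9, 3), (9, 9), (3, 9)])
        with pytest.raises(PlacementError, match="overlap"):
            load_cell_outlines({1: a, 2: b}, shape=(12, 12))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (4, 4), (4, 0), (0, 4)])
        with pytest.raises(PlacementError, match="invalid"):
            load_cell_outlines({1: bowtie}, shape=(8, 8))

    def test_zero_pixel_cell_rejected(self):
        tiny = Polygon([(0.4, 0.4), (0.45, 0.4), (0.45, 0.45)])
        with pytest.raises(PlacementError, match="0 pixels"):
            load_cell_outlines({1: tiny}, shape=(8, 8))

    def test_rasterization_matches_point_in_polygon_oracle(self):
        """Arbitrary convex polygon vs matplotlib.path containment."""
        from matplotlib.path import Path as MplPath

        poly = Polygon([(2.3, 1.1), (11.7, 2.9), (13.2, 9.4), (6.1, 12.8), (1.4, 7.7)])
        lab = rasterize_polygons({1: poly}, (15, 15))
        cols, rows = np.meshgrid(np.arange(15) + 0.5, np.arange(15) + 0.5)
        oracle = MplPath(np.asarray(poly.exterior.coords)).contains_points(
            np.c_[cols.ravel(), rows.ravel()]
        ).reshape(15, 15)
        assert np.array_equal(lab == 1, oracle)


# ---------------------------------------------------------------- nucleus
def _bfs_components(mask):
    """Independent 8-connected component enumeration (BFS oracle)."""
    comps, seen = [], np.zeros_like(mask, bool)
    for seed in zip(*np.nonzero(mask)):
        if seen[seed]:
            continue
        queue, comp = [seed], []
        seen[seed] = True
        while queue:
            r, c = queue.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    p = (r + dr, c + dc)
                    if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                            and mask[p] and not seen[p]):
                        seen[p] = True
                        queue.append(p)
        comps.append(comp)
    return comps


class TestThresholdNucleus:
    def test_strict_inequality_at_threshold(self):
        cells = rect_labels((1, 0, 6, 0, 6), shape=(6, 6))
        for val, expect_pixels in ((59.0, 0), (60.0, 0), (61.0, 36)):
            nuc, missing = threshold_nucleus(np.full((6, 6), val), cells, threshold=60)
            assert (nuc == 1).sum() == expect_pixels
            assert (missing == [1]) == (expect_pixels == 0)

    def test_clean_block_detected(self):
        cells = rect_labels((1, 0, 9, 0, 9), shape=(9, 9))
        dapi = np.zeros((9, 9))
        dapi[3:6, 3:6] = 200.0
        nuc, missing = threshold_nucleus(dapi, cells, threshold=60)
        assert np.array_equal(nuc == 1, dapi > 60)
        assert missing == []

    def test_largest_component_kept(self):
        """Two supra-threshold blobs (9 and 4 px): the 9-px one wins,
        checked against an independent BFS component enumeration."""
        cells = rect_labels((1, 0, 12, 0, 12), shape=(12, 12))
        dapi = np.zeros((12, 12))
        dapi[1:4, 1:4] = 100.0   # 9 px
        dapi[7:9, 7:9] = 100.0   # 4 px
        comps = _bfs_components(dapi > 60)
        biggest = max(comps, key=len)
        assert sorted(len(c) for c in comps) == [4, 9]
        nuc, _ = threshold_nucleus(dapi, cells, threshold=60)
        assert sorted(zip(*np.nonzero(nuc == 1))) == sorted(biggest)

    def test_membrane_pixels_excluded(self):
        cells = rect_labels((1, 0, 10, 0, 10), shape=(10, 10))
        ring = derive_membrane_ring(cells, ring_width=2)
        dapi = np.full((10, 10), 100.0)
        nuc, _ = threshold_nucleus(dapi, cells, threshold=60, membrane_labels=ring)
        assert not np.any((nuc == 1) & (ring == 1))
        assert (nuc == 1).sum() == 36  # 6x6 interior


# ---------------------------------------------------------------- ring
class TestMembraneRing:
    def test_square_cell_square_element(self):
        cells = rect_labels((1, 0, 10, 0, 10), shape=(12, 12))
        ring = derive_membrane_ring(cells, ring_width=1, element="square")
        assert (ring == 1).sum() == 100 - 64

    def test_thin_cell_becomes_all_membrane(self):
        cells = rect_labels((1, 0, 3, 0, 3), shape=(5, 5))
        ring = derive_membrane_ring(cells, ring_width=2)
        assert np.array_equal(ring, cells)

    def test_disk_element_matches_distance_oracle(self):
        """Erosion by a disk footprint == brute-force footprint-fit test."""
        from skimage.morphology import disk

        cells = rect_labels((1, 2, 10, 2, 14), shape=(14, 18))
        ring = derive_membrane_ring(cells, ring_width=2, element="disk")
        fp = disk(2)
        offs = np.argwhere(fp) - 2
        cell = cells == 1
        interior = np.zeros_like(cell)
        for r, c in np.argwhere(cell):
            pts = offs + (r, c)
            ok = np.all((pts >= 0) & (pts < cell.shape), axis=1)
            interior[r, c] = ok.all() and cell[pts[:, 0], pts[:, 1]].all()
        assert np.array_equal(ring == 1, cell & ~interior)

    def test_invalid_ring_width(self):
        with pytest.raises(ValueError, match="ring_width"):
            derive_membrane_ring(np.ones((4, 4), np.int32), ring_width=0)


# ---------------------------------------------------------------- combined
def test_segment_recovers_true_masks_on_clean_scene(clean_scene):
    image, truth = clean_scene
    corrected, seg = segment(image, truth.cells,
                             ring_width=truth.spec.membrane_ring_width)
    seg.validate()
    assert np.array_equal(seg.cells, truth.cells)
    assert np.array_equal(seg.membrane, truth.membrane)
    assert np.array_equal(seg.nucleus, truth.nucleus)


def test_derived_nuclei_overlap_truth_under_noise(noisy_scene):
    """Jaccard(derived, true) >= 0.9 per cell at high DAPI contrast."""
    image, truth = noisy_scene
    _, seg = segment(image, truth.cells, ring_width=truth.spec.membrane_ring_width)
    for cid in truth.table.cell_id:
        a, b = seg.nucleus == cid, truth.nucleus == cid
        jac = (a & b).sum() / (a | b).sum()
        assert jac >= 0.9, f"cell {cid}: Jaccard {jac:.3f}"
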