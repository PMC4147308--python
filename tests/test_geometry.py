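"""Perimeter, shared perimeter, percent contact and axis metrics."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk as draw_disk

from ajquant import (
    SceneSpec,
    axis_lengths,
    cell_perimeter,
    contact_morphology,
    generate_scene,
    percent_contact,
    shared_perimeter,
)

from conftest import NOISE_OFF, rect_labels


# ---------------------------------------------------------------- perimeter
class TestCellPerimeter:
    def test_single_pixel_convention(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert cell_perimeter(m) == 4.0

    def test_square_boundary_chain(self):
        # 10x10 square: 36 boundary pixels traversed with straight steps
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        assert cell_perimeter(m) == pytest.approx(4 * 9)

    def test_line_runs_out_and_back(self):
        m = np.zeros((3, 34), bool)
        m[1, 2:32] = True
        assert cell_perimeter(m) == pytest.approx(2 * 29)

    def test_digitized_disk_vs_analytic_circumference(self):
        """Crofton is within 3% of 2*pi*r on a smooth disk; the raw
        (1, sqrt2)-weighted chain carries its documented +~5% bias."""
        m = np.zeros((50, 50), bool)
        rr, cc = draw_disk((25, 25), 20.5)
        m[rr, cc] = True
        true = 2 * math.pi * 20
        assert cell_perimeter(m, "crofton") == pytest.approx(true, rel=0.03)
        chain = cell_perimeter(m, "chain")
        assert true < chain < 1.08 * true

    def test_empty_and_disconnected_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cell_perimeter(np.zeros((4, 4), bool))
        m = np.zeros((5, 5), bool)
        m[0, 0] = m[4, 4] = True
        with pytest.raises(ValueError, match="component"):
            cell_perimeter(m)


# ---------------------------------------------------------------- shared
class TestSharedPerimeter:
    def test_isolated_cell_shares_nothing(self):
        lab = rect_labels((1, 2, 8, 2, 8), shape=(12, 12))
        assert shared_perimeter(lab, 1) == 0.0

    def test_abutting_squares_full_edge(self):
        # two 10x10 squares along a full edge, contact distance 1:
        # 10 contact boundary pixels -> 9 chain steps
        lab = rect_labels((1, 2, 12, 2, 12), (2, 2, 12, 12, 22), shape=(14, 24))
        assert shared_perimeter(lab, 1, contact_distance=1) == pytest.approx(9.0)
        assert shared_perimeter(lab, 2, contact_distance=1) == pytest.approx(9.0)

    def test_enclosed_cell_is_all_contact(self):
        lab = rect_labels((2, 2, 16, 2, 16), (1, 6, 12, 6, 12), shape=(20, 20))
        tot = cell_perimeter(lab == 1)
        sh = shared_perimeter(lab, 1)
        assert percent_contact(sh, tot) == 100.0

    def test_unknown_cell_id(self):
        with pytest.raises(ValueError, match="unknown"):
            shared_perimeter(rect_labels((1, 0, 4, 0, 4), shape=(6, 6)), 9)


# ---------------------------------------------------------------- percent
class TestPercentContact:
    @given(
        total=st.floats(min_value=1e-6, max_value=1e6),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_formula_exact(self, total, frac):
        shared = frac * total
        assert percent_contact(shared, total) == 100.0 * shared / total

    def test_worked_values(self):
        assert percent_contact(50, 200) == 25.0
        assert percent_contact(0, 10) == 0.0
        assert percent_contact(10, 10) == 100.0

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            percent_contact(1, 0)
        with pytest.raises(ValueError):
            percent_contact(5, 4)


# ---------------------------------------------------------------- axes
class TestAxisLengths:
    def test_disk_is_round(self):
        m = np.zeros((60, 60), bool)
        rr, cc = draw_disk((30, 30), 22.5)
        m[rr, cc] = True
        _, _, ratio = axis_lengths(m)
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_ellipse_moment_axes(self):
        from ajquant.scenes import _superellipse
        from ajquant.segmentation import rasterize_polygons

        mask = rasterize_polygons({1: _superellipse(30, 30, 20, 10, 2, 0.4)}, (60, 60)) == 1
        major, minor, ratio = axis_lengths(mask)
        assert major == pytest.approx(40, rel=0.05)
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_degenerate_line_floors_minor_axis(self):
        m = np.zeros((3, 34), bool)
        m[1, 2:32] = True
        major, minor, ratio = axis_lengths(m)
        # moment axis of a uniform 30-px segment: 30 * sqrt(4/3)
        assert major == pytest.approx(30 * math.sqrt(4 / 3), rel=0.01)
        assert minor == 1.0
        assert math.isfinite(ratio) and ratio > 20


# ---------------------------------------------------------------- recovery
def test_contact_fraction_recovered_on_chained_scene():
    """Chained scene: mean measured %contact within 5 points of target."""
    for c in (0.0, 0.5):
        spec = SceneSpec(n_cells=30, adjacency_mode="chained", cell_size=100,
                         target_contact_fraction=c, noise=NOISE_OFF, seed=5)
        _, truth = generate_scene(spec)
        morph = contact_morphology(truth.cells)
        assert morph.percent_contact.mean() == pytest.approx(100 * c, abs=5.0)
        assert morph.percent_contact.between(0, 100).all()


def test_contact_monotone_in_planted_fraction():
    means = []
    for c in (0.1, 0.3, 0.5):
        spec = SceneSpec(n_cells=16, adjacency_mode="chained", cell_size=60,
                         target_contact_fraction=c, noise=NOISE_OFF, seed=6)
        _, truth = generate_scene(spec)
        means.append(contact_morphology(truth.cells).percent_contact.mean())
    assert means[0] < means[1] < means[2]


def test_perimeter_scale_covariance():
    """2x nearest-neighbor upscaling doubles perimeters within 2% and
    moves percent contact by at most 2 points (rectilinear cells; on
    diagonal boundaries nearest-neighbor resampling itself lengthens the
    digital staircase, so the property is tested where the mask, not the
    resampler, sets the boundary)."""
    spec = SceneSpec(n_cells=8, adjacency_mode="clustered", cell_size=60,
                     target_contact_fraction=0.3, noise=NOISE_OFF, seed=8)
    _, truth = generate_scene(spec)
    lab = truth.cells
    big = np.kron(lab, np.ones((2, 2), dtype=lab.dtype))
    m1 = contact_morphology(lab).set_index("cell_id")
    m2 = contact_morphology(big).set_index("cell_id")
    ratio = m2.total_perimeter / m1.total_perimeter
    assert np.allclose(ratio, 2.0, rtol=0.02)
    assert np.all(np.abs(m2.percent_contact - m1.percent_contact) <= 2.0)
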