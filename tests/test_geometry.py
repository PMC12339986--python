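"""Window geometry, nearest neighbours and isotropic edge correction."""

import numpy as np
import pytest
from _oracles import (circle_inside_fraction_sampled, nnd_bruteforce,
                      shoelace_area)

from sppa.geometry import (InsufficientPointsError, InvalidGeometryError,
                           ObservationWindow, PointPattern,
                           intensity_estimate_scalar, isotropic_weight,
                           nnd_summary, polygon_area)


class TestPolygonArea:
    @pytest.mark.parametrize("verts,expected", [
        ([(0, 0), (10, 0), (10, 2), (0, 2)], 20.0),
        ([(0, 0), (3, 0), (0, 4)], 6.0),
    ])
    def test_simple_shapes(self, verts, expected):
        assert polygon_area(ObservationWindow(verts)) == pytest.approx(expected)

    def test_random_octagon_matches_shoelace(self, octagon_window):
        assert polygon_area(octagon_window) == pytest.approx(
            shoelace_area(octagon_window.vertices), abs=1e-12)

    def test_invariant_under_rigid_motion_and_reversal(self, octagon_window):
        v = np.asarray(octagon_window.vertices)
        a0 = polygon_area(octagon_window)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = (v @ rot.T) + [3.2, -1.5]
        assert polygon_area(ObservationWindow(moved)) == pytest.approx(a0)
        assert polygon_area(ObservationWindow(v[::-1])) == pytest.approx(a0)

    def test_self_intersecting_ring_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ObservationWindow([(0, 0), (1, 1), (1, 0), (0, 1)])  # bowtie

    def test_degenerate_ring_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ObservationWindow([(0, 0), (1, 0), (2, 0)])


class TestPointPattern:
    def test_outside_points_rejected_with_indices(self, transect_window):
        with pytest.raises(ValueError, match=r"\[1\]"):
            PointPattern([1, 11], [1, 1], transect_window)

    def test_boundary_points_count_as_inside(self, transect_window):
        pat = PointPattern([0, 10], [0, 2], transect_window)
        assert pat.n == 2

    def test_duplicates_rejected_unless_overridden(self, transect_window):
        with pytest.raises(ValueError, match="duplicate"):
            PointPattern([1, 1], [1, 1], transect_window)
        with pytest.warns(UserWarning):
            pat = PointPattern([1, 1], [1, 1], transect_window,
                               allow_duplicates=True)
        assert pat.n == 2

    def test_mark_outside_label_set_rejected(self, transect_window):
        with pytest.raises(ValueError, match="label set"):
            PointPattern([1], [1], transect_window, marks=["X"],
                         mark_levels=("A", "B"))


class TestNND:
    def test_two_points(self, transect_window):
        pat = PointPattern([1.0, 1.5], [1.0, 1.0], transect_window)
        s = nnd_summary(pat)
        assert s.min == s.mean == pytest.approx(0.5)

    def test_collinear_triple(self, transect_window):
        pat = PointPattern([0, 1, 3], [1, 1, 1], transect_window)
        s = nnd_summary(pat)
        assert sorted(s.distances) == [1, 1, 2]
        assert s.min == 1 and s.mean == pytest.approx(4 / 3)

    def test_matches_bruteforce_and_order_invariant(self, csr60):
        s = nnd_summary(csr60)
        oracle = nnd_bruteforce(csr60.coords)
        np.testing.assert_allclose(np.sort(s.distances), np.sort(oracle),
                                   rtol=0, atol=1e-12)
        perm = np.random.default_rng(1).permutation(csr60.n)
        shuffled = PointPattern(csr60.x[perm], csr60.y[perm], csr60.window)
        np.testing.assert_allclose(np.sort(nnd_summary(shuffled).distances),
                                   np.sort(oracle), atol=1e-12)

    def test_insufficient_points(self, transect_window):
        with pytest.raises(InsufficientPointsError):
            nnd_summary(PointPattern([1], [1], transect_window))


class TestIsotropicWeight:
    def test_interior_edge_corner(self, transect_window):
        assert isotropic_weight((5, 1), 0.5, transect_window) == pytest.approx(1.0)
        assert isotropic_weight((5, 0), 0.1, transect_window) == pytest.approx(2.0)
        assert isotropic_weight((0, 0), 0.1, transect_window) == pytest.approx(4.0)

    def test_invalid_radius(self, transect_window):
        with pytest.raises(ValueError):
            isotropic_weight((5, 1), 0.0, transect_window)

    @pytest.mark.parametrize("case", range(20))
    def test_matches_circumference_sampling_oracle(self, case, octagon_window):
        """Inside fraction agrees with dense circumference sampling.

        Tolerance reflects the sampling oracle's own discretisation error
        (a handful of boundary-straddling samples out of 1e6).
        """
        rng = np.random.default_rng(100 + case)
        verts = np.asarray(octagon_window.vertices)
        while True:
            cx = rng.uniform(verts[:, 0].min(), verts[:, 0].max())
            cy = rng.uniform(verts[:, 1].min(), verts[:, 1].max())
            if octagon_window.contains(cx, cy)[0]:
                break
        r = rng.uniform(0.1, 3.0)
        frac = 1.0 / isotropic_weight((cx, cy), r, octagon_window)
        oracle = circle_inside_fraction_sampled(cx, cy, r, verts, m=200_000)
        assert frac == pytest.approx(oracle, abs=5e-5)

    def test_rectangle_fast_path_matches_polygon_path(self, transect_window):
        """The closed-form rectangle correction equals the generic
        circle-segment arc computation on the same rectangle."""
        from sppa.geometry import (_polygon_inside_fraction,
                                   _rect_inside_fraction)
        rng = np.random.default_rng(3)
        for _ in range(25):
            px, py = rng.uniform(0.05, 9.95), rng.uniform(0.05, 1.95)
            r = rng.uniform(0.05, 1.0)
            fast = float(_rect_inside_fraction(px, py, r, 0, 10, 0, 2))
            slow = _polygon_inside_fraction(px, py, r, transect_window)
            assert fast == pytest.approx(slow, abs=1e-9)


def test_scalar_intensity(transect_window, csr60):
    assert intensity_estimate_scalar(csr60) == pytest.approx(3.0)
    empty = PointPattern([], [], transect_window)
    assert intensity_estimate_scalar(empty) == 0.0
    pat32 = PointPattern(np.linspace(0.1, 9.9, 32), np.full(32, 1.0),
                         transect_window)
    # density printed the way transect tables report it: 32 pts / 53.33 m^2
    big = ObservationWindow.rectangle(0, 0, 26.665, 2)
    pat = PointPattern(np.linspace(0.1, 26, 32), np.full(32, 1.0), big)
    assert intensity_estimate_scalar(pat) == pytest.approx(0.6, abs=1e-3)
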