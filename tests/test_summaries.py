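"""Pair correlation, K and L estimators against brute-force oracles."""

import numpy as np
import pytest
from _oracles import k_direct, pcf_direct

from sppa.geometry import ObservationWindow, PointPattern
from sppa.models import GibbsParams, simulate_csr, simulate_gibbs
from sppa.summaries import (ScaleRuleError, k_function, l_function, pcf,
                            pcf_inhom, pcf_multitype)


class TestPcf:
    def test_matches_direct_summation_oracle(self, toy6):
        """Estimator equals the naive ordered-pair summation to 1e-10."""
        h = 0.25
        est = pcf(toy6, r_max=1.0, smoothing_bandwidth=h, n_grid=64)
        oracle = pcf_direct(toy6, est.r, h)
        np.testing.assert_allclose(est.values[1:], oracle[1:], atol=1e-10)

    def test_csr_limit_is_one(self):
        win = ObservationWindow.rectangle(0, 0, 20, 20)
        pat = simulate_csr(win, n=2000, seed=8)
        g = pcf(pat, r_max=2.0)
        sel = (g.r >= 0.5) & (g.r <= 2.0)
        assert np.nanmean(np.abs(g.values[sel] - 1)) < 0.05

    def test_point_order_invariance(self, csr60):
        g0 = pcf(csr60, r_max=1.0)
        perm = np.random.default_rng(0).permutation(csr60.n)
        g1 = pcf(PointPattern(csr60.x[perm], csr60.y[perm], csr60.window),
                 r_max=1.0)
        np.testing.assert_allclose(g0.values[1:], g1.values[1:], atol=1e-10)

    def test_rigid_motion_invariance(self, csr60):
        g0 = pcf(csr60, r_max=1.0)
        win = ObservationWindow.rectangle(3, -2, 13, 0)
        moved = PointPattern(csr60.x + 3, csr60.y - 2, win)
        g1 = pcf(moved, r_max=1.0)
        np.testing.assert_allclose(g0.values[1:], g1.values[1:], atol=1e-10)

    def test_scale_rule_enforced(self, csr60):
        with pytest.raises(ScaleRuleError):
            pcf(csr60, r_max=1.5)
        est = pcf(csr60, r_max=1.5, allow_beyond_scale=True)
        assert est.r[-1] == pytest.approx(1.5)

    def test_r_zero_flagged_unreliable(self, csr60):
        est = pcf(csr60, r_max=1.0)
        assert np.isnan(est.values[0])
        assert est.metadata["unreliable_below_r"] == pytest.approx(
            est.smoothing_bandwidth / 2)


class TestPcfInhom:
    def test_reduces_to_pcf_for_constant_intensity(self, csr60):
        lam = np.full(csr60.n, csr60.n / csr60.window.area)
        g0 = pcf(csr60, r_max=1.0)
        g1 = pcf_inhom(csr60, lam, r_max=1.0)
        np.testing.assert_allclose(g0.values[1:], g1.values[1:], atol=1e-9)

    def test_zero_intensity_rejected(self, csr60):
        lam = np.zeros(csr60.n)
        with pytest.raises(ValueError):
            pcf_inhom(csr60, lam, r_max=1.0)


class TestMultitype:
    def test_symmetry(self, marked_pattern):
        g12 = pcf_multitype(marked_pattern, "Pennatuloidea", "Cerianthidae",
                            r_max=1.0)
        g21 = pcf_multitype(marked_pattern, "Cerianthidae", "Pennatuloidea",
                            r_max=1.0)
        np.testing.assert_allclose(g12.values[1:], g21.values[1:], atol=1e-10)

    def test_independent_superposition_near_one(self):
        win = ObservationWindow.rectangle(0, 0, 20, 5)
        n = 200
        devs = []
        for seed in range(20):
            a = simulate_csr(win, n=n, seed=seed)
            b = simulate_csr(win, n=n, seed=1000 + seed)
            pat = PointPattern(np.r_[a.x, b.x], np.r_[a.y, b.y], win,
                               marks=["A"] * n + ["B"] * n)
            g = pcf_multitype(pat, "A", "B", r_max=1.0, allow_beyond_scale=False)
            sel = (g.r >= 0.3) & (g.r <= 1.0)
            devs.append(np.nanmean(np.abs(g.values[sel] - 1)))
        assert np.mean(devs) < 0.07

    def test_missing_mark_named(self, marked_pattern):
        with pytest.raises(ValueError, match="Hyalonema"):
            pcf_multitype(marked_pattern, "Pennatuloidea", "Hyalonema")


class TestKAndL:
    def test_k_matches_pair_count_oracle(self, toy6):
        est = k_function(toy6, r_max=1.0, n_grid=64)
        oracle = k_direct(toy6, est.r)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)

    def test_csr_l_identity(self):
        win = ObservationWindow.rectangle(0, 0, 20, 20)
        pat = simulate_csr(win, n=2000, seed=9)
        L = l_function(pat, r_max=1.0)
        assert np.nanmax(np.abs(L.values - L.r)) < 0.05

    def test_hardcore_l_zero_below_core(self, transect_window):
        pat = simulate_gibbs(GibbsParams(family="hardcore", hc_radius=0.3),
                             transect_window, n_target=40, seed=2,
                             n_sweeps=5000)
        L = l_function(pat, r_max=1.0)
        assert np.all(L.values[L.r < 0.3] == 0)

    def test_pcf_consistent_with_k_derivative(self, transect_window):
        """Numerically differentiating K recovers the smoothed PCF shape."""
        from sppa.models import ThomasParams, simulate_thomas
        pat = simulate_thomas(ThomasParams(1.0, 0.1, 4.0), transect_window,
                              seed=4)
        g = pcf(pat, r_max=1.0, n_grid=128)
        K = k_function(pat, r_max=1.0, n_grid=128)
        dK = np.gradient(K.values, K.r)
        with np.errstate(invalid="ignore", divide="ignore"):
            g_from_k = dK / (2 * np.pi * K.r)
        sel = (g.r > 0.1) & (g.r < 0.9)
        corr = np.corrcoef(g.values[sel], g_from_k[sel])[0, 1]
        assert corr > 0.95
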