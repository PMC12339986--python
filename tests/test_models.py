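"""Point-process simulators, fitters and model ranking."""

import numpy as np
import pytest

from sppa.geometry import ObservationWindow, nnd_summary
from sppa.models import (GibbsParams, ThomasParams, fit_gibbs,
                         fit_linked_thomas, fit_thomas, rank_models,
                         simulate_csr, simulate_gibbs, simulate_linked_thomas,
                         simulate_thomas, thomas_k_theoretical,
                         _min_contrast_thomas)


class TestSimulateCsr:
    def test_conditional_count_and_window(self, transect_window):
        pat = simulate_csr(transect_window, n=50, seed=1)
        assert pat.n == 50
        assert np.all(transect_window.contains(pat.x, pat.y))

    def test_poisson_count_mean(self, transect_window):
        counts = [simulate_csr(transect_window, intensity=2.5, seed=s).n
                  for s in range(400)]
        assert np.mean(counts) == pytest.approx(50, abs=2)

    def test_seed_determinism(self, transect_window):
        a = simulate_csr(transect_window, n=30, seed=9)
        b = simulate_csr(transect_window, n=30, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSimulateThomas:
    def test_expected_count(self, transect_window):
        counts = [simulate_thomas(ThomasParams(2.0, 0.05, 5.0),
                                  transect_window, seed=s).n
                  for s in range(300)]
        assert np.mean(counts) == pytest.approx(200, abs=10)

    def test_degenerate_sigma_collapses_clusters(self, transect_window):
        pat = simulate_thomas(ThomasParams(1.0, 1e-7, 5.0), transect_window,
                              seed=3)
        if pat.n >= 2:
            nnd = nnd_summary(pat).distances
            assert np.median(nnd) < 1e-6

    def test_seed_determinism(self, transect_window):
        p = ThomasParams(1.0, 0.1, 3.0)
        a = simulate_thomas(p, transect_window, seed=4)
        b = simulate_thomas(p, transect_window, seed=4)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSimulateGibbs:
    def test_hardcore_support_constraint(self, transect_window):
        pat = simulate_gibbs(GibbsParams(family="hardcore", hc_radius=0.25),
                             transect_window, n_target=50, seed=0,
                             n_sweeps=5000)
        assert nnd_summary(pat).min >= 0.25

    def test_infeasible_packing_raises(self):
        small = ObservationWindow.rectangle(0, 0, 1, 1)
        with pytest.raises(ValueError, match="pack"):
            simulate_gibbs(GibbsParams(family="hardcore", hc_radius=0.5),
                           small, n_target=50, seed=0)

    def test_softcore_inhibition_signature(self, transect_window):
        """Strong soft-core rarely produces pairs below half its scale."""
        hits = 0
        for s in range(30):
            pat = simulate_gibbs(
                GibbsParams(family="softcore", sc_sigma=0.3, sc_kappa=0.1),
                transect_window, n_target=40, seed=s, n_sweeps=4000)
            hits += nnd_summary(pat).min < 0.15
        assert hits / 30 < 0.05 + 0.1

    def test_burn_in_adequacy(self, transect_window):
        """Doubling the chain length barely moves the mean NND."""
        p = GibbsParams(family="softcore", sc_sigma=0.2, sc_kappa=0.5)
        m1 = np.mean([nnd_summary(simulate_gibbs(p, transect_window, 50,
                                                 seed=s, n_sweeps=10000)).mean
                      for s in range(8)])
        m2 = np.mean([nnd_summary(simulate_gibbs(p, transect_window, 50,
                                                 seed=100 + s,
                                                 n_sweeps=20000)).mean
                      for s in range(8)])
        assert abs(m1 - m2) / m1 < 0.05


class TestLinkedThomas:
    def test_zero_mu_drops_a_type(self, transect_window):
        pat = simulate_linked_thomas(ThomasParams(1.0, 0.1, 1.0),
                                     {"A": 3.0, "B": 0.0}, transect_window,
                                     seed=2)
        counts = pat.counts_by_mark()
        assert counts["B"] == 0 and counts["A"] > 0

    def test_cross_clustering_above_independence(self, transect_window):
        from sppa.summaries import pcf_multitype
        vals = []
        for s in range(10):
            pat = simulate_linked_thomas(ThomasParams(1.5, 0.1, 1.0),
                                         {"A": 2.0, "B": 2.0},
                                         transect_window, seed=s)
            c = pat.counts_by_mark()
            if min(c.values()) < 10:
                continue
            g = pcf_multitype(pat, "A", "B", r_max=1.0)
            idx = np.argmin(np.abs(g.r - 0.05))
            vals.append(g.values[idx])
        assert np.median(vals) > 2.0  # strongly cross-clustered at ~sigma/2


class TestFitThomas:
    def test_zero_contrast_fixed_point(self):
        r = np.linspace(0, 1, 256)
        kappa, sigma, c = _min_contrast_thomas(r, thomas_k_theoretical(r, 10, 0.05))
        assert kappa == pytest.approx(10, abs=1e-3)
        assert sigma == pytest.approx(0.05, abs=1e-4)
        assert c < 1e-12

    def test_parameter_recovery(self, transect_window):
        kerr, serr = [], []
        for s in range(20):
            pat = simulate_thomas(ThomasParams(1.5, 0.05, 2.0),
                                  transect_window, seed=s)
            if pat.n < 20:
                continue
            fit = fit_thomas(pat, r_max=1.0)
            kerr.append(abs(fit.params.kappa - 1.5) / 1.5)
            serr.append(abs(fit.params.sigma - 0.05) / 0.05)
        assert np.median(kerr) < 0.30
        assert np.median(serr) < 0.30

    def test_csr_input_flagged_no_cluster_evidence(self, transect_window):
        flagged = sum(fit_thomas(simulate_csr(transect_window, n=60, seed=s),
                                 r_max=1.0).flagged for s in range(10))
        assert flagged >= 8

    def test_mu_consistent_with_count(self, transect_window):
        pat = simulate_thomas(ThomasParams(1.5, 0.05, 2.0), transect_window,
                              seed=5)
        fit = fit_thomas(pat, r_max=1.0)
        expected_mu = pat.n / (fit.params.kappa * transect_window.area)
        assert fit.params.mu == pytest.approx(expected_mu)


class TestFitGibbs:
    def test_hardcore_radius_is_min_nnd(self, transect_window):
        pat = simulate_gibbs(GibbsParams(family="hardcore", hc_radius=0.2),
                             transect_window, n_target=50, seed=1,
                             n_sweeps=5000)
        fit = fit_gibbs(pat, "hardcore")
        assert fit.params.hc_radius == pytest.approx(nnd_summary(pat).min)

    def test_softcore_kappa_grid_bounds(self, transect_window):
        pat = simulate_gibbs(
            GibbsParams(family="softcore", sc_sigma=0.2, sc_kappa=0.5),
            transect_window, n_target=50, seed=3, n_sweeps=8000)
        fit = fit_gibbs(pat, "softcore")
        assert 0.1 <= fit.params.sc_kappa <= 0.9
        assert np.isfinite(fit.pseudo_aic)

    def test_csr_fitted_interaction_negligible(self, transect_window):
        """On CSR data the fitted soft-core barely inhibits at typical
        spacings (mean nearest-neighbour distance ~0.3 m at this density):
        h(0.15 m) = exp(-(sigma/0.15)^(2/kappa)) stays close to 1."""
        weak = 0
        for s in range(10):
            pat = simulate_csr(transect_window, n=60, seed=s)
            p = fit_gibbs(pat, "softcore").params
            h = np.exp(-(p.sc_sigma / 0.15) ** (2 / p.sc_kappa))
            weak += h > 0.6
        assert weak >= 8


class TestRankModels:
    class _Dummy:
        def __init__(self, family, **crit):
            self.family = family
            self.criterion = crit
            self.flagged = False

    def test_orders_within_family(self):
        a = self._Dummy("hetero_poisson", aic=100.0)
        b = self._Dummy("hetero_poisson", aic=105.0)
        out = rank_models([b, a], top_per_family=2)
        assert out[0] is a

    def test_families_never_interleaved_by_raw_criterion(self):
        poisson = self._Dummy("hetero_poisson", aic=500.0)
        thomas = self._Dummy("thomas", contrast=0.001)
        out = rank_models([poisson, thomas], top_per_family=1)
        assert {f.family for f in out} == {"hetero_poisson", "thomas"}

    def test_shortlist_size(self):
        fits = [self._Dummy("hetero_poisson", aic=float(i)) for i in range(4)]
        fits += [self._Dummy("thomas", contrast=float(i)) for i in range(1)]
        out = rank_models(fits, top_per_family=2)
        assert len(out) == min(2, 4) + min(2, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])
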