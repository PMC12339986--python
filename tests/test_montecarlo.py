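"""Quadrat test, envelopes, DCLF, segregation and Kendall correlation."""

import numpy as np
import pytest
from _oracles import kendall_concordance

from sppa.geometry import ObservationWindow, PointPattern
from sppa.models import simulate_csr
from sppa.montecarlo import (dclf_test, envelope, kendall_tau,
                             nn_segregation_test, quadrat_mc_test,
                             scaled_rank, _extract_excursions)
from sppa.summaries import l_function, pcf


class TestQuadrat:
    def test_chi2_arithmetic_extreme_case(self):
        """All 40 points in one of 4 equal quadrats: chi2 = 120 and the
        Monte-Carlo p is the smallest attainable."""
        win = ObservationWindow.rectangle(0, 0, 4, 4)
        rng = np.random.default_rng(0)
        pat = PointPattern(rng.uniform(0.01, 1.99, 40),
                           rng.uniform(0.01, 1.99, 40), win)
        res = quadrat_mc_test(pat, nx=2, ny=2, n_sim=199, seed=1)
        assert res.statistic_value == pytest.approx(120.0)
        assert res.p_value == pytest.approx(1 / 200)
        assert not res.extra["homogeneous"]

    def test_seed_determinism(self, csr60):
        a = quadrat_mc_test(csr60, n_sim=99, seed=7)
        b = quadrat_mc_test(csr60, n_sim=99, seed=7)
        assert a.p_value == b.p_value

    def test_power_against_strong_trend(self, transect_window):
        from sppa.intensity import IntensitySurface, _grid
        xc, yc, inside = _grid(transect_window, 0.1)
        XX, _ = np.meshgrid(xc, np.ones(len(yc)))
        surf = IntensitySurface(xc=xc, yc=yc,
                                values=np.where(inside, np.exp(XX), np.nan),
                                window=transect_window)
        from sppa.models import simulate_poisson_surface
        rejections = 0
        n_rep = 40
        for s in range(n_rep):
            pat = simulate_poisson_surface(surf, seed=s, n=60)
            rejections += quadrat_mc_test(pat, n_sim=99, seed=s).p_value <= 0.05
        assert rejections / n_rep > 0.9


class TestEnvelope:
    def test_rank_ordering_sanity(self, csr60):
        env = envelope(csr60, lambda p: pcf(p, r_max=1.0, n_grid=64),
                       model="csr", n_sim=39, seed=0)
        assert np.all(env.lo[1:] <= env.hi[1:])

    def test_excursion_extraction_exact(self):
        r = np.linspace(0, 1, 11)
        lo = np.zeros(11)
        hi = np.ones(11)
        obs = np.array([0.5, 1.5, 1.5, 0.5, -1, -1, 0.5, 0.5, 2.0, 0.5, 0.5])
        exc = _extract_excursions(r, obs, lo, hi)
        assert (r[1], r[2], "above") in exc
        assert (r[8], r[8], "above") in exc
        assert (r[4], r[5], "below") in exc
        # re-checking pointwise membership reproduces the intervals
        outside = (obs > hi) | (obs < lo)
        covered = np.zeros(11, bool)
        for a, b, _ in exc:
            covered |= (r >= a) & (r <= b)
        np.testing.assert_array_equal(outside, covered)

    def test_nan_in_observed_ignored(self):
        r = np.linspace(0, 1, 5)
        obs = np.array([np.nan, 0.5, 0.5, 0.5, 0.5])
        exc = _extract_excursions(r, obs, np.zeros(5), np.ones(5))
        assert exc == []

    def test_rank_rescaling_preserves_level(self):
        assert scaled_rank(999) == 49
        assert scaled_rank(199) == 9
        assert scaled_rank(99) == 4
        assert scaled_rank(19) >= 1

    def test_seed_determinism(self, csr60):
        kw = dict(model="csr", n_sim=19, seed=3)
        e1 = envelope(csr60, lambda p: pcf(p, r_max=1.0, n_grid=64), **kw)
        e2 = envelope(csr60, lambda p: pcf(p, r_max=1.0, n_grid=64), **kw)
        np.testing.assert_array_equal(e1.lo, e2.lo)
        assert e1.excursions == e2.excursions


class TestDclf:
    def test_identical_model_gives_p_one(self, csr60):
        """A 'model' that replays the observed pattern gives u = 0 and
        p_d = 1: zero deviation is a perfect fit."""
        class Replay:
            family = "replay"

            def simulate(self, seed, n=None):
                return csr60

        res = dclf_test(csr60, model=Replay(), r_max=1.0, n_sim=19, seed=0)
        assert res.statistic_value == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == 1.0

    def test_clustered_vs_csr_rejected(self, transect_window):
        from sppa.models import ThomasParams, simulate_thomas
        rej = 0
        n_rep = 20
        for s in range(n_rep):
            pat = simulate_thomas(ThomasParams(1.5, 0.05, 2.0),
                                  transect_window, seed=s)
            if pat.n < 20:
                n_rep -= 1
                continue
            res = dclf_test(pat, model="csr", r_max=1.0, n_sim=99, seed=s)
            rej += res.p_value <= 0.05
        assert rej / n_rep >= 0.9

    def test_seed_determinism(self, csr60):
        a = dclf_test(csr60, model="csr", r_max=1.0, n_sim=39, seed=5)
        b = dclf_test(csr60, model="csr", r_max=1.0, n_sim=39, seed=5)
        assert a.p_value == b.p_value


class TestSegregation:
    def test_overall_dof_is_two_for_two_types(self, marked_pattern):
        overall, per_type = nn_segregation_test(marked_pattern, n_sim=99,
                                                seed=0)
        assert overall.dof == 2
        assert set(per_type) == {"Pennatuloidea", "Cerianthidae"}
        assert all(t.dof == 1 for t in per_type.values())

    def test_disjoint_halves_detected(self, transect_window):
        rng = np.random.default_rng(2)
        x = np.r_[rng.uniform(0, 4.5, 30), rng.uniform(5.5, 10, 30)]
        y = rng.uniform(0, 2, 60)
        pat = PointPattern(x, y, transect_window,
                           marks=["A"] * 30 + ["B"] * 30)
        overall, _ = nn_segregation_test(pat, n_sim=199, seed=0)
        assert overall.p_value <= 0.01

    def test_needs_two_types(self, csr60, transect_window):
        with pytest.raises(ValueError):
            nn_segregation_test(csr60)
        pat = PointPattern([1, 2, 3], [1, 1, 1], transect_window,
                           marks=["A", "A", "B"])
        with pytest.raises(ValueError, match="at least 5"):
            nn_segregation_test(pat)


class TestKendall:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x * 2 + 1).statistic_value == pytest.approx(1.0)
        assert kendall_tau(x, -x).statistic_value == pytest.approx(-1.0)

    def test_matches_concordance_count_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            res = kendall_tau(x, y)
            assert res.statistic_value == pytest.approx(
                kendall_concordance(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2, 3], [1, 2])
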