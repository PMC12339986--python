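"""Classification, driver mapping rules, and the transect pipeline."""

import json

import numpy as np
import pytest

from sppa.config import RunConfig
from sppa.inference import (AnalysisReport, PatternClassification,
                            bivariate_driver, classify_pattern,
                            run_transect_analysis, univariate_driver)
from sppa.models import simulate_csr
from sppa.montecarlo import EnvelopeResult, TestResult
from sppa.summaries import FunctionEstimate

FAST = RunConfig(n_sim=49, n_grid_pcf=128, n_grid_l=96, gibbs_sweeps=4000)


def _env(excursions, n=64):
    r = np.linspace(0, 1, n)
    obs = np.ones(n)
    lo = np.full(n, 0.5)
    hi = np.full(n, 1.5)
    for a, b, d in excursions:
        sel = (r >= a) & (r <= b)
        obs[sel] = 2.0 if d == "above" else 0.1
    est = FunctionEstimate(r=r, values=obs, variant="pcf")
    from sppa.montecarlo import _extract_excursions
    return EnvelopeResult(statistic=est, lo=lo, hi=hi, n_sim=999, rank=49,
                          model="csr",
                          excursions=_extract_excursions(r, obs, lo, hi))


def _test(p, name="t"):
    return TestResult(name=name, statistic_value=1.0, p_value=p)


class _Fit:
    def __init__(self, family, covariate_spec=None, flagged=False):
        self.family = family
        self.covariate_spec = covariate_spec
        self.flagged = flagged
        self.criterion = {"aic": 0.0}

    def to_dict(self):
        return {"family": self.family}


class TestClassification:
    def test_empty_excursions_is_csr(self):
        cls = classify_pattern(_env([]), _test(0.5), _test(0.5))
        assert cls.summary_label == "csr"
        assert not cls.significant_departure

    def test_single_above_excursion_is_clustered(self):
        cls = classify_pattern(_env([(0.3, 0.6, "above")]), _test(0.5),
                               _test(0.01))
        assert cls.summary_label == "clustered"
        assert cls.significant_departure

    def test_both_directions_is_mixed(self):
        cls = classify_pattern(_env([(0.0, 0.4, "above"),
                                     (0.55, 0.65, "below")]),
                               _test(0.5), _test(0.01))
        assert cls.summary_label == "mixed"

    def test_inhomogeneity_alone_is_a_departure(self):
        cls = classify_pattern(_env([]), _test(0.01), _test(0.8))
        assert cls.summary_label == "csr"
        assert cls.significant_departure  # CSR = *homogeneous* Poisson


class TestUnivariateDriver:
    def test_csr_maps_to_no_departure(self):
        cls = classify_pattern(_env([]), _test(0.5), _test(0.5))
        v = univariate_driver(cls, [])
        assert v.driver == "no_departure_from_csr"

    @pytest.mark.parametrize("family,driver", [
        ("hetero_poisson", "habitat_association"),
        ("thomas", "reproductive_dispersal"),
        ("thomas_inhom", "reproductive_dispersal_with_habitat"),
        ("softcore", "competition"),
        ("hardcore", "competition"),
    ])
    def test_family_mapping(self, family, driver):
        cls = classify_pattern(_env([(0.3, 0.6, "above")]), _test(0.5),
                               _test(0.01))
        scored = [(_Fit(family), _test(0.9)), (_Fit("thomas" if family
                  != "thomas" else "hetero_poisson"), _test(0.2))]
        assert univariate_driver(cls, scored).driver == driver

    def test_exact_tie_is_indeterminate(self):
        cls = classify_pattern(_env([(0.3, 0.6, "above")]), _test(0.5),
                               _test(0.01))
        scored = [(_Fit("hetero_poisson"), _test(0.7)),
                  (_Fit("thomas"), _test(0.7))]
        assert univariate_driver(cls, scored).driver == "indeterminate"

    def test_all_flagged_is_indeterminate(self):
        cls = classify_pattern(_env([(0.3, 0.6, "above")]), _test(0.5),
                               _test(0.01))
        scored = [(_Fit("thomas", flagged=True), _test(0.0))]
        assert univariate_driver(cls, scored).driver == "indeterminate"


class TestBivariateDriver:
    def _clustered(self):
        return classify_pattern(_env([(0.0, 0.3, "above")]), _test(0.5),
                                _test(0.01), mode="bivariate")

    def test_joint_density_model_means_mutual_habitat(self):
        scored = [(_Fit("hetero_poisson", ("surface", "joint")), _test(0.9)),
                  (_Fit("hetero_poisson", ("surface", "A")), _test(0.2))]
        v = bivariate_driver(self._clustered(), scored, {})
        assert v.driver == "mutual_habitat_association"

    def test_single_taxon_density_model_means_facilitation(self):
        scored = [(_Fit("hetero_poisson", ("surface", "B")), _test(0.9)),
                  (_Fit("hetero_poisson", ("surface", "joint")), _test(0.2))]
        v = bivariate_driver(self._clustered(), scored, {})
        assert v.driver == "facilitation"
        assert any("B" in n for n in v.evidence_notes)

    def test_linked_thomas_means_facilitation(self):
        scored = [(_Fit("linked_thomas"), _test(0.9)),
                  (_Fit("hetero_poisson", ("surface", "joint")), _test(0.2))]
        assert bivariate_driver(self._clustered(), scored, {}).driver == \
            "facilitation"

    def test_near_tie_is_indeterminate(self):
        scored = [(_Fit("hetero_poisson", ("surface", "joint")), _test(0.72)),
                  (_Fit("linked_thomas"), _test(0.70))]
        v = bivariate_driver(self._clustered(), scored, {}, tie_band=0.05)
        assert v.driver == "indeterminate"

    def test_overdispersion_only_bivariate_means_competition(self):
        bi = classify_pattern(_env([(0.0, 0.3, "below")]), _test(0.5),
                              _test(0.01), mode="bivariate")
        uni = {"A": classify_pattern(_env([]), _test(0.5), _test(0.5)),
               "B": classify_pattern(_env([]), _test(0.5), _test(0.5))}
        assert bivariate_driver(bi, [], uni).driver == "competition"

    def test_shared_overdispersion_means_habitat(self):
        bi = classify_pattern(_env([(0.0, 0.3, "below")]), _test(0.5),
                              _test(0.01), mode="bivariate")
        uni = {"A": classify_pattern(_env([(0.1, 0.25, "below")]),
                                     _test(0.5), _test(0.01)),
               "B": classify_pattern(_env([]), _test(0.5), _test(0.5))}
        assert bivariate_driver(bi, [], uni).driver == \
            "mutual_habitat_association"


class TestPipeline:
    def test_small_pattern_excluded_with_reason(self, transect_window):
        pat = simulate_csr(transect_window, n=29, seed=0)
        rep = run_transect_analysis(pat, FAST, seed=1)
        assert rep.status.startswith("excluded")
        assert "minimum of 30 points" in rep.status

    def test_csr_report_structure_and_verdict(self, csr60):
        rep = run_transect_analysis(csr60, FAST, seed=2, transect_id="t9")
        sec = rep.univariate["all"]
        assert sec["driver"] == "no_departure_from_csr"
        assert rep.transect_id == "t9"
        # the ladder never fits models on a CSR classification
        assert "shortlist" not in sec

    def test_reports_are_deterministic(self, csr60):
        r1 = run_transect_analysis(csr60, FAST, seed=3)
        r2 = run_transect_analysis(csr60, FAST, seed=3)
        assert json.dumps(r1.to_dict(), default=str) == \
            json.dumps(r2.to_dict(), default=str)

    def test_habitat_scenario_recovered(self):
        from sppa.synthetic import ScenarioSpec, generate_scenario
        pat, _ = generate_scenario(ScenarioSpec(driver="habitat_association",
                                                seed=11))
        rep = run_transect_analysis(pat, FAST, seed=4)
        assert rep.univariate["Pennatuloidea"]["driver"] == \
            "habitat_association"

    def test_config_echoed_into_report(self, csr60):
        rep = run_transect_analysis(csr60, FAST, seed=5)
        assert rep.config["n_sim"] == 49
        assert rep.config["min_points"] == 30
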