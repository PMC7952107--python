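"""Scenario experiments, calibration search, and provider impact reports."""

import numpy as np
import pytest

from edflow.benchmark import ProviderRecord
from edflow.distributions import ArrivalProfile
from edflow.ed_model import ResourceConfig
from edflow.scenarios import (
    ScenarioConfig,
    calibrate_resources,
    provider_impact_report,
    run_experiment,
    standard_scenarios,
)

from conftest import flat_profile


def small_profile(scale=0.25):
    """Scaled-down diurnal load for fast experiment tests."""
    from edflow.distributions import default_arrival_profile

    base = default_arrival_profile()
    return ArrivalProfile(
        hourly_rates=tuple(r * scale for r in base.hourly_rates),
        esi4_fraction=base.esi4_fraction,
    )


@pytest.fixture(scope="module")
def small_setup(request):
    cfg = request.getfixturevalue("shipped_config")
    res = ResourceConfig(n_rooms=4, n_nurses=1, n_providers=1, n_residents=1,
                         resident_fraction=0.5)
    return cfg.pathway, res, small_profile()


class TestExperiment:
    def test_identical_paired_scenarios_give_zero_difference(self, small_setup):
        pathway, res, profile = small_setup
        kw = dict(n_reps=2, horizon=15, warmup=2, master_seed=3, paired_streams=True)
        scen = [
            ScenarioConfig("a", 0.2, 0.1, **kw),
            ScenarioConfig("b", 0.2, 0.1, **kw),
        ]
        result = run_experiment(scen, res, pathway, profile)
        for c in result.comparisons[("a", "b")]:
            assert c.difference == pytest.approx(0.0, abs=1e-9)

    def test_outputs_invariant_to_scenario_ordering(self, small_setup):
        pathway, res, profile = small_setup
        kw = dict(n_reps=2, horizon=12, warmup=2, master_seed=5)
        a = ScenarioConfig("current", 0.3, 0.2, **kw)
        b = ScenarioConfig("abc", 0.1, 0.05, **kw)
        r1 = run_experiment([a, b], res, pathway, profile)
        r2 = run_experiment([b, a], res, pathway, profile)
        assert r1.summaries["current"] == r2.summaries["current"]
        assert r1.summaries["abc"] == r2.summaries["abc"]

    def test_los_monotone_along_testing_ladder_with_crn(self, small_setup):
        pathway, res, profile = small_setup
        providers = [
            ProviderRecord(f"P{i}", 100, t, 50, max(0, t // 3))
            for i, t in enumerate([5, 10, 20, 35, 60])
        ]
        scen = standard_scenarios(
            providers=providers, n_reps=2, horizon=15, warmup=2, master_seed=11,
            paired_streams=True, include_ladder=True,
        )
        result = run_experiment(scen, res, pathway, profile)
        ladder = ["abc", "current", "p90_provider", "max_provider", "all_tested"]
        los4 = [np.mean([r.mean_los_esi4 for r in result.summaries[lab]])
                for lab in ladder]
        assert los4 == sorted(los4)

    def test_patient_hours_and_annual_counts_reported(self, small_setup):
        pathway, res, profile = small_setup
        kw = dict(n_reps=2, horizon=10, warmup=1, master_seed=2)
        scen = [ScenarioConfig("current", 0.4, 0.2, **kw),
                ScenarioConfig("abc", 0.1, 0.05, **kw)]
        result = run_experiment(scen, res, pathway, profile)
        hours = result.patient_hours[("current", "abc")]
        assert set(hours) == {4, 5}
        assert result.annual_patients["current"][4] > 0

    def test_degenerate_experiments_rejected(self, small_setup):
        pathway, res, profile = small_setup
        kw = dict(n_reps=2, horizon=5, master_seed=0)
        with pytest.raises(ValueError):
            run_experiment([ScenarioConfig("only", 0.1, 0.1, **kw)], res, pathway, profile)
        with pytest.raises(ValueError):
            run_experiment(
                [ScenarioConfig("x", 0.1, 0.1, **kw), ScenarioConfig("x", 0.2, 0.1, **kw)],
                res, pathway, profile,
            )
        with pytest.raises(ValueError):
            ScenarioConfig("x", 0.1, 0.1, n_reps=1)
        with pytest.raises(ValueError):
            standard_scenarios(include_ladder=True)


class TestCalibration:
    def test_recovers_known_configuration_from_its_own_surface(self, small_setup):
        """Targets simulated from a known config; the search space contains it;
        the best fit reproduces the surface within Monte-Carlo error."""
        pathway, _, profile = small_setup
        truth = ResourceConfig(n_rooms=4, n_nurses=1, n_providers=1)
        from edflow.ed_model import run_replication
        from edflow.inference import summarize

        acc = {"los4": 0.0, "los5": 0.0, "wait4": 0.0, "wait5": 0.0}
        for seed in (51, 52):
            s = summarize(run_replication(pathway, truth, profile, horizon=32,
                                          warmup=2, seed=seed))
            for esi in (4, 5):
                acc[f"los{esi}"] += s.mean("los", esi) / 2
                acc[f"wait{esi}"] += s.mean("wait", esi) / 2
        space = {"n_rooms": [3, 4, 6], "n_nurses": [1, 2], "n_providers": [1, 2]}
        best, report = calibrate_resources(
            acc, space, pathway, profile, master_seed=9, n_reps=2, horizon=30,
        )
        # contract: the recovered configuration's surface matches the
        # generating surface within Monte-Carlo error (configurations with
        # indistinguishable surfaces are interchangeable)
        assert report["converged"]
        assert all(v < 0.10 for v in report["relative_miss"].values())
        assert best.n_rooms in space["n_rooms"]

    def test_single_point_search_space_returns_it_scored(self, small_setup):
        pathway, _, profile = small_setup
        targets = {"los4": 60.0, "los5": 55.0, "wait4": 20.0, "wait5": 20.0}
        space = {"n_rooms": [5], "n_nurses": [2], "n_providers": [1]}
        best, report = calibrate_resources(targets, space, pathway, profile,
                                           master_seed=1, n_reps=1, horizon=10)
        assert (best.n_rooms, best.n_nurses, best.n_providers) == (5, 2, 1)
        assert report["n_evaluated"] == 1
        assert "score" in report

    def test_infeasible_targets_flag_failure(self, small_setup):
        pathway, _, profile = small_setup
        targets = {"los4": 1.0, "los5": 1.0, "wait4": 1.0, "wait5": 1.0}
        space = {"n_rooms": [4], "n_nurses": [1], "n_providers": [1]}
        _, report = calibrate_resources(targets, space, pathway, profile,
                                        master_seed=1, n_reps=1, horizon=10)
        assert not report["converged"]
        assert "failure" in report

    def test_bad_target_keys_rejected(self, small_setup):
        pathway, _, profile = small_setup
        with pytest.raises(ValueError):
            calibrate_resources({"los4": 100.0}, {}, pathway, profile)


class TestProviderImpact:
    providers = [
        ProviderRecord("A", 100, 10, 0, 0),
        ProviderRecord("B", 200, 50, 0, 0),
        ProviderRecord("C", 100, 4, 0, 0),
        ProviderRecord("D", 100, 40, 0, 0),
    ]
    benchmark = {4: 0.04}
    system_diff = {4: 20.0}

    def _report(self, pid):
        return provider_impact_report(pid, self.providers, self.benchmark,
                                      self.system_diff, esi_levels=(4,))

    def test_provider_at_benchmark_predicts_zero_change(self):
        r = self._report("C")
        assert r["esi"][4]["predicted_system_los_change_min"] == pytest.approx(0.0)

    def test_attribution_matches_hand_arithmetic(self):
        # population: 104/500 tested = 0.208; excess over benchmark 0.168
        # A: rate 0.10, share 0.2 -> 20 * 0.2 * (0.06/0.168)
        r = self._report("A")
        assert r["esi"][4]["predicted_system_los_change_min"] == pytest.approx(
            20.0 * 0.2 * (0.06 / 0.168)
        )
        assert r["esi"][4]["population_rate"] == pytest.approx(0.208)

    def test_attributions_sum_to_full_system_difference(self):
        total = sum(
            self._report(p.provider_id)["esi"][4]["predicted_system_los_change_min"]
            for p in self.providers
        )
        assert total == pytest.approx(20.0)

    def test_rank_and_share_reported(self):
        r = self._report("D")
        assert r["esi"][4]["percentile_rank"] == pytest.approx(100.0)
        assert r["esi"][4]["visit_share"] == pytest.approx(0.2)

    def test_unknown_provider_rejected(self):
        with pytest.raises(KeyError):
            self._report("nobody")
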