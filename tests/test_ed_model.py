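"""Discrete-event engine: pathway logic, queueing, conservation, accounting."""

import math

import numpy as np
import pandas as pd
import pytest

from edflow.distributions import analytic_mean, nhpp_arrivals
from edflow.ed_model import (
    PathwayConfig,
    ResourceConfig,
    _spawn_streams,
    read_visit_log,
    run_replication,
    utilization,
    write_visit_log,
)

from conftest import constant_pathway, flat_profile


class TestPathwayTrace:
    def test_hand_traced_single_pathway(self, ample_resources):
        """screening 3 + vitals 2 + transfer 10 -> wait 15; +eval 15 +discharge 10
        -> LOS 40; bed cleaning happens after disposition and never extends LOS."""
        pw = constant_pathway(
            nurse_screening=3, vitals=2, transfer_to_room=10,
            attending_eval=15, nurse_discharge=10, bed_cleaning=45,
        )
        log = run_replication(pw, ample_resources, flat_profile(1.0), horizon=5, seed=9)
        df = log.records
        assert len(df) > 50
        assert np.allclose(df["wait"], 15.0)
        assert np.allclose(df["los"], 40.0)

    def test_zero_duration_pathway_gives_zero_los(self, ample_resources):
        log = run_replication(
            constant_pathway(), ample_resources, flat_profile(2.0), horizon=2, seed=1
        )
        assert np.allclose(log.records["los"], 0.0)
        assert np.allclose(log.records["wait"], 0.0)

    def test_untested_skip_testing_and_tested_stay_longer(self, ample_resources):
        pw = constant_pathway(
            attending_eval=10, testing_treatment_esi4=60, testing_treatment_esi5=60,
            attending_reassessment=5, p_test_esi4=0.5, p_test_esi5=0.5,
        )
        df = run_replication(pw, ample_resources, flat_profile(2.0), horizon=10, seed=2).records
        assert np.allclose(df.loc[~df.tested, "los"], 10.0)
        assert np.allclose(df.loc[df.tested, "los"], 75.0)

    def test_resident_path_adds_review_stage(self, ample_resources):
        pw = constant_pathway(resident_eval=12, attending_resident_review=4)
        res = ResourceConfig(10_000, 10_000, 10_000, n_residents=10_000,
                             resident_fraction=1.0)
        df = run_replication(pw, res, flat_profile(2.0), horizon=5, seed=3).records
        assert np.allclose(df["los"], 16.0)
        assert np.allclose(df["wait"], 0.0)  # wait ends at first clinician contact

    def test_unknown_variant_rejected(self, ample_resources):
        with pytest.raises(ValueError, match="pathway_variant"):
            run_replication(constant_pathway(), ample_resources, flat_profile(1.0),
                            horizon=1, seed=0, pathway_variant="beds_first")

    def test_vitals_in_room_variant_orders_vitals_after_entry(self, ample_resources):
        pw = constant_pathway(nurse_screening=3, vitals=2, transfer_to_room=10)
        df = run_replication(pw, ample_resources, flat_profile(1.0), horizon=3, seed=4,
                             pathway_variant="vitals_in_room").records
        assert (df["room_entry"] <= df["vitals_end"]).all()
        assert np.allclose(df["vitals_end"] - df["room_entry"], 12.0)


class TestContracts:
    def test_identical_seeds_bitwise_identical_logs(self, shipped_config):
        cfg = shipped_config
        kw = dict(horizon=12, warmup=2, seed=99)
        a = run_replication(cfg.pathway, cfg.resources, cfg.profile, **kw)
        b = run_replication(cfg.pathway, cfg.resources, cfg.profile, **kw)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_every_non_warmup_arrival_logged_once_to_disposition(self, shipped_config):
        cfg = shipped_config
        log = run_replication(cfg.pathway, cfg.resources, cfg.profile,
                              horizon=20, warmup=3, seed=5)
        df = log.records
        # reproduce the arrival stream: same named-stream spawning scheme
        times, _ = nhpp_arrivals(cfg.profile, 20, _spawn_streams(5, ("arrivals",))["arrivals"])
        expected = int((times >= 3 * 1440.0).sum())
        assert len(df) == expected
        assert df["patient_id"].is_unique
        assert df["disposition"].notna().all()  # run drained past horizon

    def test_timestamps_monotone_under_contention(self, shipped_config):
        cfg = shipped_config
        df = run_replication(cfg.pathway, cfg.resources, cfg.profile,
                             horizon=15, warmup=2, seed=8).records
        order = ["arrival", "screening_start", "screening_end", "vitals_end",
                 "room_entry", "provider_start", "disposition"]
        for earlier, later in zip(order, order[1:]):
            assert (df[later] >= df[earlier] - 1e-9).all(), (earlier, later)
        assert np.allclose(df["los"], df["disposition"] - df["arrival"])
        assert np.allclose(df["wait"], df["provider_start"] - df["arrival"])
        assert (df["wait"] <= df["los"] + 1e-9).all()
        assert (df["wait"] >= 0).all()

    def test_zero_resources_rejected(self):
        with pytest.raises(ValueError):
            ResourceConfig(n_rooms=0, n_nurses=1, n_providers=1)
        with pytest.raises(ValueError):
            ResourceConfig(n_rooms=1, n_nurses=1, n_providers=1,
                           n_residents=0, resident_fraction=0.5)

    def test_warmup_exceeding_horizon_rejected(self, ample_resources):
        with pytest.raises(ValueError):
            run_replication(constant_pathway(), ample_resources, flat_profile(1.0),
                            horizon=2, warmup=3, seed=0)

    def test_missing_pathway_spec_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PathwayConfig({}, 0.1, 0.1)


class TestQueueingTheory:
    def test_infinite_resources_wait_equals_pre_provider_service(self, shipped_config,
                                                                 ample_resources):
        """Without contention, wait = screening + vitals + transfer on average."""
        cfg = shipped_config
        log = run_replication(cfg.pathway, ample_resources, cfg.profile,
                              horizon=40, warmup=2, seed=6)
        df = log.records
        expected = sum(
            analytic_mean(cfg.pathway.specs[n])
            for n in ("nurse_screening", "vitals", "transfer_to_room")
        )
        se = df["wait"].std(ddof=1) / math.sqrt(len(df))
        assert abs(df["wait"].mean() - expected) < 4 * se

    def test_mm1_time_in_system_matches_closed_form(self):
        """Single provider, Poisson arrivals, exponential service: W = 1/(mu-lambda).

        lambda = 6/h, mean service 6 min (mu = 10/h), rho = 0.6 -> W = 15 min.
        """
        pw = constant_pathway()
        pw.specs["attending_eval"] = type(pw.specs["attending_eval"])("exponential", 6.0)
        res = ResourceConfig(n_rooms=100_000, n_nurses=100_000, n_providers=1)
        log = run_replication(pw, res, flat_profile(6.0), horizon=750, warmup=20, seed=17)
        df = log.records
        assert len(df) > 100_000
        w_expected = 1.0 / (10.0 - 6.0) * 60.0  # minutes
        assert df["los"].mean() == pytest.approx(w_expected, rel=0.05)

    def test_mean_los_nondecreasing_in_testing_rate_with_crn(self, shipped_config):
        cfg = shipped_config
        means = []
        for p4, p5 in [(0.0, 0.0), (0.225, 0.119), (0.6, 0.4), (1.0, 1.0)]:
            df = run_replication(cfg.pathway.with_rates(p4, p5), cfg.resources,
                                 cfg.profile, horizon=35, warmup=5, seed=31).records
            means.append(df["los"].mean())
        assert means == sorted(means)


class TestUtilization:
    def test_single_patient_room_occupancy_fraction(self, ample_resources):
        """One visit occupying a room 60 min over a 1-day horizon -> 60/1440."""
        pw = constant_pathway(transfer_to_room=30, attending_eval=20, nurse_discharge=10)
        seed = next(
            s for s in range(100)
            if len(run_replication(pw, ample_resources, flat_profile(1 / 24), horizon=1,
                                   seed=s).records) == 1
        )
        log = run_replication(pw, ample_resources, flat_profile(1 / 24), horizon=1, seed=seed)
        u = utilization(log, ample_resources, horizon=1)
        assert u["rooms"] * ample_resources.n_rooms == pytest.approx(60 / 1440)

    def test_zero_arrivals_zero_fractions(self, ample_resources):
        log = run_replication(constant_pathway(), ample_resources, flat_profile(0.0),
                              horizon=1, seed=0)
        u = utilization(log, ample_resources, horizon=1)
        assert all(v == 0.0 for v in u.values())

    def test_saturated_system_approaches_full_occupancy(self):
        pw = constant_pathway(attending_eval=30)
        res = ResourceConfig(n_rooms=1, n_nurses=1, n_providers=1)
        log = run_replication(pw, res, flat_profile(4.0), horizon=2, seed=1)
        u = utilization(log, res, horizon=2)
        assert u["rooms"] > 0.95

    def test_empty_log_rejected(self, ample_resources):
        from edflow.ed_model import VisitLog
        with pytest.raises(ValueError):
            utilization(VisitLog(records=pd.DataFrame()), ample_resources, 1)


class TestVisitLogIO:
    def test_csv_roundtrip_to_millis(self, shipped_config, tmp_path):
        cfg = shipped_config
        log = run_replication(cfg.pathway, cfg.resources, cfg.profile,
                              horizon=3, seed=12)
        path = tmp_path / "log.csv"
        write_visit_log(log, path)
        back = read_visit_log(path)
        for col in ("los", "wait", "arrival"):
            assert np.allclose(back.records[col], log.records[col].round(3))
        assert back.records["esi"].tolist() == log.records["esi"].tolist()
        assert back.records["tested"].tolist() == log.records["tested"].tolist()

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"patient_id": [1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_visit_log(p)
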