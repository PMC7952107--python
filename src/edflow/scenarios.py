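"""Experiment layer: testing-rate scenarios, calibration, provider reports.

A scenario fixes the per-ESI testing proportions; an experiment runs each
scenario for ``n_reps`` independent replications of a simulated year and
compares arms with pooled-t intervals, mirroring the published design
(5 iterations of 1 year; current rates 22.5%/11.9% vs the achievable
benchmark 13.5%/4.2%, plus 90th-percentile, maximum-provider and
100%-testing what-ifs).

Replication seeding: each (scenario, rep) gets its own integer seed derived
from the master seed, so arms are independent by default; with
``paired_streams`` the rep seeds are shared across scenarios (common
random numbers), which pins arrivals and service draws patient-by-patient
and turns the testing Bernoulli into a nested u < p rule.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np

from .benchmark import ProviderRecord, provider_percentile_rate
from .distributions import ArrivalProfile
from .ed_model import PathwayConfig, ResourceConfig, run_replication
from .inference import (
    ComparisonResult,
    ReplicationSummary,
    compare_summaries,
    summarize,
    total_patient_hours,
)

__all__ = [
    "ScenarioConfig",
    "ExperimentResult",
    "run_scenario",
    "run_experiment",
    "calibrate_resources",
    "provider_impact_report",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One experimental arm: a label plus per-ESI testing proportions."""

    label: str
    p_test_esi4: float
    p_test_esi5: float
    n_reps: int = 5
    horizon: float = 365.0  # recorded days per replication
    warmup: float = 7.0  # discarded initialisation days, simulated in addition
    master_seed: int = 0
    paired_streams: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need n_reps >= 2 for interval estimation")
        for p in (self.p_test_esi4, self.p_test_esi5):
            if not 0.0 <= p <= 1.0:
                raise ValueError("testing proportions must lie in [0, 1]")


@dataclass
class ExperimentResult:
    summaries: dict  # label -> list[ReplicationSummary]
    comparisons: dict  # (label_a, label_b) -> list[ComparisonResult]
    patient_hours: dict  # (label_a, label_b) -> {esi: hours}
    annual_patients: dict  # label -> {esi: mean patients per replication}


def _rep_seeds(master_seed: int, label: str, n_reps: int, paired: bool):
    """Derived integer seeds below 2**31; label-keyed so that scenario
    ordering never matters, and paired streams share seeds across labels."""
    key = [] if paired else [zlib.crc32(label.encode("utf8"))]
    return [
        int(
            np.random.SeedSequence([master_seed % (2**31)] + key + [rep])
            .generate_state(1, np.uint32)[0]
            % (2**31)
        )
        for rep in range(n_reps)
    ]


def run_scenario(
    scenario: ScenarioConfig,
    resources: ResourceConfig,
    pathway: PathwayConfig,
    profile: ArrivalProfile,
    pathway_variant: str = "vitals_before_room",
) -> list[ReplicationSummary]:
    """n_reps independent year-long replications of one testing scenario."""
    pw = pathway.with_rates(scenario.p_test_esi4, scenario.p_test_esi5)
    seeds = _rep_seeds(
        scenario.master_seed, scenario.label, scenario.n_reps, scenario.paired_streams
    )
    out = []
    for rep, seed in enumerate(seeds):
        log = run_replication(
            pw,
            resources,
            profile,
            horizon=scenario.horizon + scenario.warmup,
            warmup=scenario.warmup,
            seed=seed,
            pathway_variant=pathway_variant,
        )
        out.append(summarize(log, rep_id=rep))
    return out


def run_experiment(
    scenarios: list[ScenarioConfig],
    resources: ResourceConfig,
    pathway: PathwayConfig,
    profile: ArrivalProfile,
    pathway_variant: str = "vitals_before_room",
) -> ExperimentResult:
    """Run all scenarios and compare every ordered pair (earlier - later).

    Differences are reported as (arm a - arm b) for a listed before b, so
    listing the current scenario first gives positive differences when the
    alternative shortens stays.  Patient-hours use each pair's arm-a mean
    annual patient counts.
    """
    if len(scenarios) < 2:
        raise ValueError("an experiment needs at least 2 scenarios")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    summaries = {}
    for sc in scenarios:
        summaries[sc.label] = run_scenario(
            sc, resources, pathway, profile, pathway_variant=pathway_variant
        )
    comparisons, hours, annual = {}, {}, {}
    for sc in scenarios:
        reps = summaries[sc.label]
        annual[sc.label] = {
            4: float(np.mean([r.n_esi4 for r in reps])),
            5: float(np.mean([r.n_esi5 for r in reps])),
        }
    for a, b in itertools.combinations(scenarios, 2):
        comps = compare_summaries(summaries[a.label], summaries[b.label])
        comparisons[(a.label, b.label)] = comps
        hours[(a.label, b.label)] = {
            c.esi: total_patient_hours(int(round(annual[a.label][c.esi])), c.difference)
            for c in comps
            if c.metric == "los"
        }
    return ExperimentResult(
        summaries=summaries,
        comparisons=comparisons,
        patient_hours=hours,
        annual_patients=annual,
    )


def standard_scenarios(
    providers: list[ProviderRecord] | None = None,
    current: tuple[float, float] = (0.225, 0.119),
    benchmark: tuple[float, float] = (0.135, 0.042),
    n_reps: int = 5,
    horizon: float = 365.0,
    warmup: float = 7.0,
    master_seed: int = 0,
    paired_streams: bool = False,
    include_ladder: bool = False,
) -> list[ScenarioConfig]:
    """The published scenario set: current vs ABC, optionally the full ladder.

    With a provider table the high-testing arms take their rates from the
    90th-percentile and maximum provider; the 100%-testing arm is fixed.
    """
    kw = dict(
        n_reps=n_reps,
        horizon=horizon,
        warmup=warmup,
        master_seed=master_seed,
        paired_streams=paired_streams,
    )
    out = [
        ScenarioConfig("current", *current, **kw),
        ScenarioConfig("abc", *benchmark, **kw),
    ]
    if include_ladder:
        if providers is None:
            raise ValueError("the high-testing ladder needs a provider table")
        p90 = tuple(provider_percentile_rate(providers, esi, 90.0) for esi in (4, 5))
        pmax = tuple(provider_percentile_rate(providers, esi, 100.0) for esi in (4, 5))
        out += [
            ScenarioConfig("p90_provider", *p90, **kw),
            ScenarioConfig("max_provider", *pmax, **kw),
            ScenarioConfig("all_tested", 1.0, 1.0, **kw),
        ]
    return out


def calibrate_resources(
    targets: dict,
    search_space: dict,
    pathway: PathwayConfig,
    profile: ArrivalProfile,
    base: ResourceConfig | None = None,
    master_seed: int = 0,
    n_reps: int = 2,
    horizon: float = 90.0,
    warmup: float = 7.0,
    pathway_variant: str = "vitals_before_room",
    failure_tolerance: float = 0.25,
) -> tuple[ResourceConfig, dict]:
    """Grid search over resource counts against a mean LOS/wait surface.

    ``targets``: {"los4": .., "los5": .., "wait4": .., "wait5": ..} minutes;
    ``search_space``: {"n_rooms": iterable, "n_nurses": iterable,
    "n_providers": iterable, optionally "n_residents", "resident_fraction"}.
    Score is the sum of squared relative errors over the four targets;
    deterministic given ``master_seed``.  If the best configuration misses
    any target by more than ``failure_tolerance`` (relative), the report
    flags calibration failure.
    """
    required = {"los4", "los5", "wait4", "wait5"}
    if set(targets) != required:
        raise ValueError(f"targets must have keys {sorted(required)}")
    base = base or ResourceConfig(n_rooms=12, n_nurses=2, n_providers=2)
    axes = {
        "n_rooms": list(search_space.get("n_rooms", [base.n_rooms])),
        "n_nurses": list(search_space.get("n_nurses", [base.n_nurses])),
        "n_providers": list(search_space.get("n_providers", [base.n_providers])),
        "n_residents": list(search_space.get("n_residents", [base.n_residents])),
        "resident_fraction": list(
            search_space.get("resident_fraction", [base.resident_fraction])
        ),
    }
    seeds = [int(s.generate_state(1, np.uint32)[0] % (2**31))
             for s in np.random.SeedSequence(master_seed).spawn(n_reps)]
    trials = []
    for combo in itertools.product(*axes.values()):
        kw = dict(zip(axes.keys(), combo))
        if kw["n_residents"] == 0 and kw["resident_fraction"] > 0:
            continue  # invalid corner of the grid
        res = ResourceConfig(**kw)
        achieved = {"los4": 0.0, "los5": 0.0, "wait4": 0.0, "wait5": 0.0}
        for seed in seeds:
            log = run_replication(
                pathway, res, profile,
                horizon=horizon + warmup, warmup=warmup, seed=seed,
                pathway_variant=pathway_variant,
            )
            s = summarize(log)
            for esi in (4, 5):
                achieved[f"los{esi}"] += s.mean("los", esi) / n_reps
                achieved[f"wait{esi}"] += s.mean("wait", esi) / n_reps
        score = sum(((achieved[k] - targets[k]) / targets[k]) ** 2 for k in targets)
        trials.append((score, kw, achieved))
    trials.sort(key=lambda t: (t[0], sorted(t[1].items())))
    best_score, best_kw, best_achieved = trials[0]
    rel_miss = {k: abs(best_achieved[k] - targets[k]) / targets[k] for k in targets}
    report = {
        "score": best_score,
        "achieved": best_achieved,
        "targets": dict(targets),
        "relative_miss": rel_miss,
        "converged": all(v <= failure_tolerance for v in rel_miss.values()),
        "n_evaluated": len(trials),
    }
    if not report["converged"]:
        report["failure"] = (
            "no configuration within "
            f"{failure_tolerance:.0%} of all targets; best misses {rel_miss}"
        )
    return ResourceConfig(**best_kw), report


def provider_impact_report(
    provider_id: str,
    providers: list[ProviderRecord],
    benchmark: dict,
    system_difference: dict,
    esi_levels: tuple = (4, 5),
) -> dict:
    """Individualised feedback: a provider's rates, rank, and system impact.

    ``benchmark``: {esi: benchmark testing rate}; ``system_difference``:
    {esi: full current-vs-benchmark mean LOS difference, minutes}.  The
    predicted system LOS change if this provider's panel alone moved to the
    benchmark uses a linear attribution: the full difference scaled by the
    provider's visit share and by the provider's own excess testing over
    the benchmark relative to the population excess.  Visit-weighted across
    providers these contributions sum to the full system difference.
    """
    table = {p.provider_id: p for p in providers}
    if provider_id not in table:
        raise KeyError(f"unknown provider id {provider_id!r}")
    me = table[provider_id]
    out = {"provider_id": provider_id, "esi": {}}
    for esi in esi_levels:
        pool = [p for p in providers if p.visits(esi) > 0]
        total_visits = sum(p.visits(esi) for p in pool)
        pop_rate = sum(p.tested(esi) for p in pool) / total_visits
        rates = sorted(p.rate(esi) for p in pool)
        my_rate = me.rate(esi)
        rank = 1 + sum(r < my_rate for r in rates)
        share = me.visits(esi) / total_visits
        pop_excess = pop_rate - benchmark[esi]
        my_excess = my_rate - benchmark[esi]
        attr = 0.0
        if pop_excess > 0:
            attr = system_difference[esi] * share * (my_excess / pop_excess)
        out["esi"][esi] = {
            "rate": my_rate,
            "population_rate": pop_rate,
            "benchmark_rate": benchmark[esi],
            "percentile_rank": 100.0 * rank / len(rates),
            "visit_share": share,
            "predicted_system_los_change_min": attr,
        }
    return out
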