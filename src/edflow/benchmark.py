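"""Achievable Benchmark of Care (ABC) for diagnostic-testing rates.

The ABC is a pared-mean benchmark: providers are ranked by a shrunken
performance estimate, the top performers are selected until they cover a
minimum share of all patients (10% by convention), and the benchmark is
the plain visit-weighted rate among the selected providers.

Diagnostic testing in low-acuity visits is *overuse*, so the desirable
event is a visit WITHOUT a test; the benchmark testing rate reported is
the complement of the selected providers' no-test rate.  Ranking uses the
adjusted performance fraction

    APF = (x + 1) / (d + 2)

(x desirable events among d visits), a Bayesian shrinkage that keeps
small-denominator providers from dominating the top ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProviderRecord",
    "BenchmarkResult",
    "adjusted_performance_fraction",
    "compute_abc",
    "provider_percentile_rate",
    "read_provider_table",
    "write_provider_table",
]


@dataclass(frozen=True)
class ProviderRecord:
    """Per-provider visit and test counts for each ESI level."""

    provider_id: str
    n_visits_esi4: int = 0
    n_tested_esi4: int = 0
    n_visits_esi5: int = 0
    n_tested_esi5: int = 0

    def __post_init__(self) -> None:
        for esi in (4, 5):
            v, t = self.visits(esi), self.tested(esi)
            if v < 0 or t < 0 or t > v:
                raise ValueError(
                    f"provider {self.provider_id}: need 0 <= tested <= visits for ESI {esi}"
                )

    def visits(self, esi: int) -> int:
        return getattr(self, f"n_visits_esi{esi}")

    def tested(self, esi: int) -> int:
        return getattr(self, f"n_tested_esi{esi}")

    def rate(self, esi: int) -> float:
        v = self.visits(esi)
        return self.tested(esi) / v if v else float("nan")


@dataclass
class BenchmarkResult:
    esi: int
    benchmark_rate: float
    selected_providers: list
    apf_by_provider: dict
    coverage: float
    min_coverage: float

    def to_dict(self) -> dict:
        return {
            "esi": self.esi,
            "benchmark_rate": self.benchmark_rate,
            "selected_providers": list(self.selected_providers),
            "apf_by_provider": dict(self.apf_by_provider),
            "coverage": self.coverage,
            "min_coverage": self.min_coverage,
        }


def adjusted_performance_fraction(x_desirable: int, d_visits: int) -> float:
    """Shrunken performance fraction (x + 1) / (d + 2)."""
    if d_visits < 0 or x_desirable < 0:
        raise ValueError("counts must be nonnegative")
    if x_desirable > d_visits:
        raise ValueError("desirable events cannot exceed visits")
    return (x_desirable + 1) / (d_visits + 2)


def compute_abc(
    providers: list[ProviderRecord],
    esi: int,
    min_coverage: float = 0.10,
    min_visits: int = 0,
) -> BenchmarkResult:
    """Pared-mean achievable benchmark testing rate for one ESI level.

    Providers are ranked by APF of the no-test fraction (descending, ties
    broken by provider id ascending) and selected from the top until the
    selected group covers at least ``min_coverage`` of all visits.  The
    benchmark is the selected group's visit-weighted testing rate.
    ``min_visits`` optionally excludes very-low-volume providers.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must lie in (0, 1]")
    pool = [p for p in providers if p.visits(esi) > 0 and p.visits(esi) >= min_visits]
    if not pool:
        raise ValueError(f"no providers with visits for ESI {esi}")
    total_visits = sum(p.visits(esi) for p in pool)
    apf = {
        p.provider_id: adjusted_performance_fraction(
            p.visits(esi) - p.tested(esi), p.visits(esi)
        )
        for p in pool
    }
    ranked = sorted(pool, key=lambda p: (-apf[p.provider_id], p.provider_id))
    selected, cum = [], 0
    for p in ranked:
        selected.append(p)
        cum += p.visits(esi)
        if cum >= min_coverage * total_visits:
            break
    sel_visits = sum(p.visits(esi) for p in selected)
    sel_no_test = sum(p.visits(esi) - p.tested(esi) for p in selected)
    return BenchmarkResult(
        esi=esi,
        benchmark_rate=1.0 - sel_no_test / sel_visits,
        selected_providers=[p.provider_id for p in selected],
        apf_by_provider=apf,
        coverage=sel_visits / total_visits,
        min_coverage=min_coverage,
    )


def provider_percentile_rate(
    providers: list[ProviderRecord], esi: int, percentile: float
) -> float:
    """Testing rate of the provider at the given percentile (nearest rank).

    Providers are the units (unweighted by visits); percentile 100 is the
    highest-testing provider.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    rates = sorted(p.rate(esi) for p in providers if p.visits(esi) > 0)
    if not rates:
        raise ValueError(f"no providers with visits for ESI {esi}")
    if percentile == 0.0:
        return rates[0]
    k = int(np.ceil(percentile / 100.0 * len(rates)))  # nearest-rank
    return rates[k - 1]


def write_provider_table(providers: list[ProviderRecord], path) -> None:
    """Long-format CSV: provider_id, esi, n_visits, n_tested."""
    rows = []
    for p in providers:
        for esi in (4, 5):
            rows.append(
                {
                    "provider_id": p.provider_id,
                    "esi": esi,
                    "n_visits": p.visits(esi),
                    "n_tested": p.tested(esi),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_provider_table(path) -> list[ProviderRecord]:
    df = pd.read_csv(path, dtype={"provider_id": str})
    out = []
    for pid, grp in df.groupby("provider_id", sort=True):
        kw = {"provider_id": pid}
        for _, row in grp.iterrows():
            kw[f"n_visits_esi{int(row.esi)}"] = int(row.n_visits)
            kw[f"n_tested_esi{int(row.esi)}"] = int(row.n_tested)
        out.append(ProviderRecord(**kw))
    return out
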