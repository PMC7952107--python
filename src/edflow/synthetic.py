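"""Synthetic stand-ins for the institutional administrative extracts.

The real study drew three inputs from an EMR: a provider-level testing
table, annual low-acuity visit volumes, and monthly administrative LOS/wait
summaries.  None are deposited, so this module generates statistically
faithful substitutes:

* provider testing rates with a ~10-fold p90/p10 spread around the local
  means (22.5% of ESI-4 and 11.9% of ESI-5 visits tested),
* visit volumes matching the annual census (35,838 ESI-4, 9,124 ESI-5),
* twelve monthly mean LOS/wait summaries with the dispersion of the
  published fiscal-year administrative data.

Provider rates are drawn log-normally and then affinely calibrated in log
space so the realised p90/p10 ratio and the realised visit-weighted mean
hit their targets exactly; visit volumes are allocated by a symmetric
Dirichlet.  Both choices are synthetic conventions — the real per-provider
distributions are unpublished.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import ProviderRecord

__all__ = ["SyntheticCohortSpec", "gen_provider_table", "gen_admin_monthly"]

# Published fiscal-year administrative summary surface (minutes).
ADMIN_DEFAULTS = {
    "los": {4: (169.8, 21.4), 5: (136.4, 27.8)},
    "wait": {4: (76.4, 22.0), 5: (73.6, 25.1)},
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic administrative cohort."""

    n_providers: int = 30
    mean_rate_esi4: float = 0.225
    mean_rate_esi5: float = 0.119
    spread_factor: float = 10.0  # target p90/p10 ratio of provider rates
    annual_visits_esi4: int = 35_838
    annual_visits_esi5: int = 9_124
    dirichlet_conc: float = 5.0  # visit-share concentration across providers
    admin_means: dict = field(default_factory=lambda: ADMIN_DEFAULTS)
    n_months: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_providers < 2:
            raise ValueError("need at least 2 providers")
        for r in (self.mean_rate_esi4, self.mean_rate_esi5):
            if not 0.0 < r < 1.0:
                raise ValueError("mean testing rates must lie in (0, 1)")
        if self.spread_factor < 1.0:
            raise ValueError("spread_factor must be >= 1")
        if self.annual_visits_esi4 <= 0 or self.annual_visits_esi5 <= 0:
            raise ValueError("annual visit totals must be positive")


def _allocate_visits(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer visit counts summing exactly to ``total`` (largest remainder)."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _calibrated_rates(
    z: np.ndarray, weights: np.ndarray, mean_rate: float, spread: float
) -> np.ndarray:
    """Map standard-normal draws to rates with exact spread and weighted mean.

    Rates are ``exp(a + b z)``: ``b`` pins the empirical p90/p10 ratio to
    ``spread`` and ``a`` pins the visit-weighted mean to ``mean_rate``.
    """
    if spread == 1.0:
        return np.full(z.size, mean_rate)
    q10, q90 = np.percentile(z, [10.0, 90.0])
    if q90 <= q10:  # pragma: no cover - degenerate tiny samples
        raise ValueError("cannot calibrate spread: degenerate draws")
    b = np.log(spread) / (q90 - q10)

    cap = 0.995  # rates are proportions; the clip keeps the right tail < 1

    def weighted_mean(a: float) -> float:
        return float(np.sum(weights * np.minimum(np.exp(a + b * z), cap)))

    # weighted mean is monotone increasing in a; bisect to pin it exactly
    lo, hi = np.log(mean_rate) - b * z.max() - 10.0, np.log(cap)
    if weighted_mean(hi) < mean_rate:
        raise ValueError(f"infeasible spec: mean rate {mean_rate} with spread {spread}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if weighted_mean(mid) < mean_rate:
            lo = mid
        else:
            hi = mid
    return np.minimum(np.exp(0.5 * (lo + hi) + b * z), cap)


def gen_provider_table(spec: SyntheticCohortSpec) -> list[ProviderRecord]:
    """Synthetic provider testing table with the study's rate structure."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.n_providers
    shares = rng.dirichlet(np.full(n, spec.dirichlet_conc))
    visits4 = _allocate_visits(spec.annual_visits_esi4, shares)
    visits5 = _allocate_visits(spec.annual_visits_esi5, shares)
    z = rng.standard_normal(n)
    w4 = visits4 / visits4.sum()
    w5 = visits5 / visits5.sum()
    rates4 = _calibrated_rates(z, w4, spec.mean_rate_esi4, spec.spread_factor)
    # the same provider ordering drives both ESI levels: a high tester is
    # a high tester for both acuities
    rates5 = _calibrated_rates(z, w5, spec.mean_rate_esi5, spec.spread_factor)
    tested4 = rng.binomial(visits4, rates4)
    tested5 = rng.binomial(visits5, rates5)
    width = len(str(n))
    return [
        ProviderRecord(
            provider_id=f"P{i + 1:0{width}d}",
            n_visits_esi4=int(visits4[i]),
            n_tested_esi4=int(tested4[i]),
            n_visits_esi5=int(visits5[i]),
            n_tested_esi5=int(tested5[i]),
        )
        for i in range(n)
    ]


def gen_admin_monthly(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Monthly administrative mean LOS/wait per ESI (normal month-to-month).

    Columns: month, esi, mean_los, mean_wait.  Consumable as the n-month
    comparison arm of a pooled-t validation.
    """
    if spec.n_months < 2:
        raise ValueError("need at least 2 months")
    for metric in ("los", "wait"):
        for esi in (4, 5):
            if spec.admin_means[metric][esi][1] < 0:
                raise ValueError("admin month-to-month SDs must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    rows = []
    for esi in (4, 5):
        mu_l, sd_l = spec.admin_means["los"][esi]
        mu_w, sd_w = spec.admin_means["wait"][esi]
        los = rng.normal(mu_l, sd_l, spec.n_months)
        wait = rng.normal(mu_w, sd_w, spec.n_months)
        for m in range(spec.n_months):
            rows.append(
                {
                    "month": m + 1,
                    "esi": esi,
                    "mean_los": los[m],
                    "mean_wait": wait[m],
                }
            )
    return pd.DataFrame(rows)
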