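"""Outcome summaries and replication-based interval estimation.

Replication experiments produce a handful of per-replication means (here
5 one-year iterations per arm), and arm comparisons are reported as a
difference of means with a 95% confidence interval.  The interval uses the
classical pooled-variance two-sample t:

    d = mean_a - mean_b
    s_p^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2)
    CI = d +/- t_{n_a+n_b-2, (1+level)/2} * s_p * sqrt(1/n_a + 1/n_b)

which reproduces every published validation and experiment interval from
the printed means and SDs (model arms n = 5; the administrative arm is the
12 monthly summaries of the fiscal year).  Display rounding is
half-away-from-zero to one decimal; internal arithmetic is unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicationSummary",
    "ComparisonResult",
    "summarize",
    "pooled_t_ci",
    "total_patient_hours",
    "clinical_impact_flag",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for minutes)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class ReplicationSummary:
    """Per-ESI patient counts and mean outcomes for one replication."""

    rep_id: int
    n_esi4: int
    n_esi5: int
    mean_los_esi4: float | None
    mean_los_esi5: float | None
    mean_wait_esi4: float | None
    mean_wait_esi5: float | None

    def mean(self, metric: str, esi: int) -> float | None:
        return getattr(self, f"mean_{metric}_esi{esi}")

    def n(self, esi: int) -> int:
        return getattr(self, f"n_esi{esi}")


@dataclass(frozen=True)
class ComparisonResult:
    """Difference of arm means (a - b) with its confidence interval."""

    metric: str  # "los" | "wait"
    esi: int  # 4 | 5
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    difference: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def rounded(self) -> tuple[float, float, float]:
        return (
            round_half_away(self.difference),
            round_half_away(self.ci_low),
            round_half_away(self.ci_high),
        )


def summarize(log, rep_id: int = 0) -> ReplicationSummary:
    """Per-ESI arithmetic means of LOS and wait for one visit log.

    Accepts a :class:`~edflow.ed_model.VisitLog` or its records DataFrame.
    An ESI stratum with no patients reports ``n = 0`` and ``None`` means.
    """
    df = getattr(log, "records", log)
    if not isinstance(df, pd.DataFrame):
        raise TypeError("expected a VisitLog or DataFrame of visit records")
    required = {"esi", "los", "wait"}
    if not df.empty and not required.issubset(df.columns):
        raise ValueError(f"visit log missing columns: {sorted(required - set(df.columns))}")
    if not df.empty:
        bad = df[df["los"].isna() | df["wait"].isna() | (df["los"] < 0) | (df["wait"] < 0) | (df["wait"] > df["los"])]
        if len(bad):
            raise ValueError(f"malformed visit records at rows {bad.index[:5].tolist()}")
    vals = {}
    for esi in (4, 5):
        sub = df[df["esi"] == esi] if not df.empty else df
        n = len(sub)
        vals[f"n_esi{esi}"] = n
        vals[f"mean_los_esi{esi}"] = float(sub["los"].mean()) if n else None
        vals[f"mean_wait_esi{esi}"] = float(sub["wait"].mean()) if n else None
    return ReplicationSummary(rep_id=rep_id, **vals)


def pooled_t_ci(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    level: float = 0.95,
    metric: str = "los",
    esi: int = 4,
) -> ComparisonResult:
    """Pooled-variance two-sample t interval for a difference of means."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each arm needs at least 2 replications")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = math.sqrt(sp2) * math.sqrt(1.0 / n_a + 1.0 / n_b)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
    diff = mean_a - mean_b
    return ComparisonResult(
        metric=metric,
        esi=esi,
        mean_a=mean_a,
        sd_a=sd_a,
        n_a=n_a,
        mean_b=mean_b,
        sd_b=sd_b,
        n_b=n_b,
        difference=diff,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        level=level,
    )


def compare_summaries(
    summaries_a: list[ReplicationSummary],
    summaries_b: list[ReplicationSummary],
    level: float = 0.95,
) -> list[ComparisonResult]:
    """All four (metric, ESI) comparisons between two replication sets."""
    out = []
    for metric in ("los", "wait"):
        for esi in (4, 5):
            va = [s.mean(metric, esi) for s in summaries_a]
            vb = [s.mean(metric, esi) for s in summaries_b]
            if any(v is None for v in va + vb):
                raise ValueError(f"missing {metric} means for ESI {esi}")
            out.append(
                pooled_t_ci(
                    float(np.mean(va)),
                    float(np.std(va, ddof=1)),
                    len(va),
                    float(np.mean(vb)),
                    float(np.std(vb, ddof=1)),
                    len(vb),
                    level=level,
                    metric=metric,
                    esi=esi,
                )
            )
    return out


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabular mirror of the published comparison layout."""
    return pd.DataFrame(
        [
            {
                "esi": r.esi,
                "metric": r.metric,
                "mean_a": r.mean_a,
                "sd_a": r.sd_a,
                "mean_b": r.mean_b,
                "sd_b": r.sd_b,
                "difference": r.difference,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in results
        ]
    )


def total_patient_hours(n_patients: int, per_patient_difference_minutes: float) -> int:
    """Annual patient-hours implied by a per-patient LOS change.

    ``n * diff / 60`` rounded to the nearest whole hour, e.g. 9,124 patients
    at 10.9 min each is 1,658 hours.
    """
    if n_patients < 0:
        raise ValueError("patient count must be nonnegative")
    return int(round_half_away(n_patients * per_patient_difference_minutes / 60.0, 0))


def clinical_impact_flag(difference_minutes: float, threshold_minutes: float = 15.0) -> bool:
    """True when an LOS reduction reaches the a-priori clinical threshold.

    The 15-minute default is roughly 10% of the current mean low-acuity
    LOS; the boundary is inclusive.
    """
    return difference_minutes >= threshold_minutes
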