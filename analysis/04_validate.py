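"""Validate the calibrated model against administrative data.

Mirrors the published validation: five one-year replications at current
testing rates vs the twelve monthly administrative summaries, compared
per ESI with pooled-variance t intervals (model n = 5, admin n = 12).  A
well-calibrated model shows no interval excluding zero.  Uses the
synthetic admin months from 01_make_fixtures.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from edflow.config import default_config
from edflow.inference import comparisons_to_frame, pooled_t_ci
from edflow.scenarios import ScenarioConfig, run_scenario

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "results" / "fixtures"


def main(seed: int = 0) -> None:
    cfg = default_config()
    admin = pd.read_csv(FIXTURES / "admin_monthly.csv")
    sc = ScenarioConfig("current", cfg.pathway.p_test_esi4, cfg.pathway.p_test_esi5,
                        master_seed=seed)
    reps = run_scenario(sc, cfg.resources, cfg.pathway, cfg.profile,
                        pathway_variant=cfg.pathway_variant)
    results = []
    for metric, col in (("los", "mean_los"), ("wait", "mean_wait")):
        for esi in (4, 5):
            model_vals = [r.mean(metric, esi) for r in reps]
            admin_vals = admin.loc[admin.esi == esi, col].to_numpy()
            c = pooled_t_ci(
                float(np.mean(model_vals)), float(np.std(model_vals, ddof=1)),
                len(model_vals),
                float(np.mean(admin_vals)), float(np.std(admin_vals, ddof=1)),
                len(admin_vals), metric=metric, esi=esi,
            )
            results.append(c)
            d, lo, hi = c.rounded()
            verdict = "consistent" if lo <= 0 <= hi else "DISCREPANT"
            print(f"ESI {esi} {metric}: model {c.mean_a:.1f} ({c.sd_a:.1f}) vs "
                  f"admin {c.mean_b:.1f} ({c.sd_b:.1f}) -> diff {d} ({lo}, {hi}) "
                  f"[{verdict}]")
    out = ROOT / "results"
    out.mkdir(parents=True, exist_ok=True)
    comparisons_to_frame(results).to_csv(out / "validation_table.csv", index=False)
    print(f"wrote {out / 'validation_table.csv'}")


if __name__ == "__main__":
    main()
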