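"""Generate the synthetic administrative dataset the pipeline consumes.

The real study drew its inputs from an institutional EMR: a provider-level
diagnostic-testing table, annual low-acuity visit volumes, and monthly
administrative LOS/wait summaries.  This driver writes synthetic stand-ins
with the documented statistical structure (~10-fold provider variation in
testing rates around means of 22.5%/11.9%, the 44,962-visit annual census,
and fiscal-year monthly summaries with the published dispersion) under
results/fixtures/.
"""

import sys
from pathlib import Path

import numpy as np

from edflow.benchmark import write_provider_table
from edflow.synthetic import SyntheticCohortSpec, gen_admin_monthly, gen_provider_table

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticCohortSpec(seed=seed)
    providers = gen_provider_table(spec)
    write_provider_table(providers, OUT / "provider_table.csv")
    admin = gen_admin_monthly(spec)
    admin.to_csv(OUT / "admin_monthly.csv", index=False)

    rates4 = np.array([p.rate(4) for p in providers])
    w4 = np.array([p.visits(4) for p in providers], dtype=float)
    print(f"wrote {len(providers)} providers to {OUT / 'provider_table.csv'}")
    print(f"  ESI4 visit-weighted testing rate: {np.sum(w4 * rates4) / w4.sum():.3f}")
    print(f"  ESI4 provider p90/p10 spread:     "
          f"{np.percentile(rates4, 90) / np.percentile(rates4, 10):.1f}-fold")
    print(f"wrote {spec.n_months} admin months to {OUT / 'admin_monthly.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
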