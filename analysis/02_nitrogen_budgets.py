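#!/usr/bin/env python
"""Nitrogen budgets of the simulated cultures: end-stage composition,
conversion ratios, and the NO2--N2O production association.

Reads results/cultures.csv (runs 01 first if missing); writes
results/budgets.csv.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from n2oiso.errors import DegenerateInputError, UndefinedRatioError
from n2oiso.io_tables import read_timeseries_table
from n2oiso.nitrogen_budget import (
    conversion_ratio,
    end_stage_composition,
    production_association,
    yield_estimates,
)

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"


def main() -> None:
    cultures = RESULTS / "cultures.csv"
    if not cultures.exists():
        subprocess.run([sys.executable, str(HERE / "01_simulate_cultures.py")], check=True)
    rows = []
    for ts in read_timeseries_table(cultures):
        comp = end_stage_composition(ts)
        row = {"bottle_id": ts.bottle_id, "substrate": ts.substrate}
        row.update({f"frac_{k}": round(v, 4) for k, v in comp.items()})
        for product in ("NH4", "N2O"):
            try:
                row[f"ratio_{product}"] = round(conversion_ratio(ts, product), 4)
            except UndefinedRatioError:
                row[f"ratio_{product}"] = float("nan")
        row.update({f"yhat_{k}": round(v, 4) for k, v in yield_estimates(ts).items()})
        if ts.substrate == "NO3":  # NO2 accumulation only exists in NO3-fed bottles
            try:
                fit = production_association(ts)
                row["assoc_r2"] = round(fit.r_squared, 3)
                row["assoc_p"] = fit.p_value
            except DegenerateInputError:
                row["assoc_r2"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "budgets.csv", index=False)
    print(df.to_string(index=False))
    no3 = df[df.substrate == "NO3"]
    print(
        f"\nNO3-fed bottles: NH4 end fraction {no3.frac_NH4.mean():.2f}, "
        f"N2O conversion {100 * no3.ratio_N2O.mean():.2f}% of consumed N, "
        f"NO2-N2O association R2 {no3.assoc_r2.mean():.2f}"
    )


if __name__ == "__main__":
    main()
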