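#!/usr/bin/env python
"""Partition the late-culture N2O of the two cNor-carrying strains between
the DNRA pathway (3-day SP endmember) and cNor-type NO reduction, closed
form plus Monte-Carlo uncertainty.

Writes results/partitioning.csv.
"""

from pathlib import Path

import pandas as pd

from n2oiso.datasets import CNOR_ENDMEMBER
from n2oiso.mixing import PointEndmember, mc_fraction

SEED = 20243
RESULTS = Path(__file__).resolve().parent.parent / "results"

# (strain, 3-day SP mean+-SD as the pure-DNRA endmember, 7-day mixed SP mean+-SD)
CASES = [
    ("Red69", PointEndmember("Red69-3d", 45.5, 0.7), 41.9, 0.9),
    ("Red111", PointEndmember("Red111-3d", 47.0, 0.3), 41.1, 1.4),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for i, (strain, em3, sp7, sp7_sd) in enumerate(CASES):
        res = mc_fraction(sp7, sp7_sd, em3, CNOR_ENDMEMBER, n_draws=100_000, seed=SEED + i)
        rows.append(
            {
                "strain": strain,
                "sp_7day": sp7,
                "sp_3day": em3.sp,
                "sp_cnor": CNOR_ENDMEMBER.sp,
                "f_dnra_closed_form": round(res.f_point, 4),
                "f_dnra_mc_mean": round(res.f_mean, 4),
                "f_dnra_mc_sd": round(res.f_sd, 4),
                "ci95_low": round(res.ci_low, 4),
                "ci95_high": round(res.ci_high, 4),
                "clipped_share": res.clipped_share,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "partitioning.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nThe DNRA pathway still accounts for ~89-93% of 7-day N2O in both strains;"
        "\nthe SP decline from day 3 to day 7 needs only a ~7-11% cNor contribution."
    )


if __name__ == "__main__":
    main()
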