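"""Bundled reference data: the Geobacteraceae N₂O isotopocule survey.

Strain-mean isotopocule signatures of N₂O produced by nine nitrate/nitrite-
ammonifying Geobacteraceae strains (genera Geomonas, Oryzomonas, Geobacter)
incubated on NO₃⁻ (8 mM) or NO₂⁻ (2 mM), sampled at 3 and 7 days, plus one
abiotic (acidified, bacteria-free) control.  δ¹⁵Nbulk and δ¹⁸O are
substrate-referenced (product minus substrate); parenthetical SDs from the
replicate incubations are carried in the ``*_sd`` columns.  Values are
published strain means; the underlying replicate-level raw table is not
redistributed here.

Also houses the shipped substrate isotope references, the cNor and DNRA point
endmembers used in SP mixing, and the published DNRA zone ranges.
"""

from __future__ import annotations

import io

import pandas as pd

from .iso_core import IsotopoculeMeasurement, SubstrateReference
from .mixing import PointEndmember

__all__ = [
    "load_isotopocule_survey",
    "survey_measurements",
    "substrate_sp_groups",
    "NITRATE_REFERENCE",
    "NITRITE_REFERENCE",
    "CNOR_ENDMEMBER",
    "DNRA_SP_RANGE",
    "MIXED_PROCESS_ROWS",
    "NITRITE_ONLY_STRAINS",
]

#: Substrate isotope references measured for the culture medium
#: (denitrifier method for NO₃⁻, azide method for NO₂⁻).
NITRATE_REFERENCE = SubstrateReference("NO3", d15n=2.4, d18o=17.9, d15n_sd=0.1, d18o_sd=0.3)
NITRITE_REFERENCE = SubstrateReference("NO2", d15n=-1.8, d18o=3.7, d15n_sd=0.3, d18o_sd=0.2)

#: SP of denitrifier-type N₂O from cNor-catalysed NO reduction.
CNOR_ENDMEMBER = PointEndmember("cNor", sp=-5.9, sp_sd=2.1)

#: Replicate-level SP range of DNRA-derived N₂O (mixed-process rows excluded).
DNRA_SP_RANGE = (43.0, 49.9)

#: (strain, substrate, day) rows whose SP reflects mixed DNRA + cNor
#: production rather than the pure DNRA signature.
MIXED_PROCESS_ROWS = [("Red69", "NO3", 7), ("Red111", "NO3", 7)]

#: Strains lacking nitrate reductase genes — nitrite-only ammonifiers with no
#: NO₃⁻ arm, excluded from substrate comparisons by default.
NITRITE_ONLY_STRAINS = ["DSM16622", "JCM30203"]

# substrate,strain,genus,day,d18o,d18o_sd,d15n_bulk,d15n_bulk_sd,sp,sp_sd,biotic
_SURVEY_CSV = """\
substrate,strain,genus,day,d18o,d18o_sd,d15n_bulk,d15n_bulk_sd,sp,sp_sd,biotic
NO3,Red32,Geomonas,3,16.2,0.1,-39.8,0.0,46.5,0.1,1
NO3,Red32,Geomonas,7,14.6,0.4,-27.5,1.2,45.4,1.4,1
NO3,Red69,Geomonas,3,26.4,4.1,-29.6,4.5,45.5,0.7,1
NO3,Red69,Geomonas,7,23.6,3.9,-28.2,4.9,41.9,0.9,1
NO3,Red111,Geomonas,3,15.2,1.2,-19.7,2.1,47.0,0.3,1
NO3,Red111,Geomonas,7,9.6,0.7,-23.0,3.4,41.1,1.4,1
NO3,Red330,Geomonas,3,18.6,4.1,-21.1,7.0,46.8,1.3,1
NO3,Red330,Geomonas,7,15.5,1.5,-18.0,7.2,46.5,0.1,1
NO3,Red88,Oryzomonas,3,23.4,0.8,-31.4,3.7,46.3,0.6,1
NO3,Red88,Oryzomonas,7,19.2,1.5,-22.4,5.4,46.4,0.3,1
NO2,Red32,Geomonas,3,27.8,0.2,-23.7,0.0,46.8,0.2,1
NO2,Red32,Geomonas,7,27.0,1.0,-21.3,0.1,46.1,1.0,1
NO2,Red69,Geomonas,3,28.8,0.1,-23.7,0.0,45.8,0.7,1
NO2,Red69,Geomonas,7,28.6,0.0,-23.5,0.3,46.0,0.1,1
NO2,Red111,Geomonas,3,27.5,0.3,-24.3,0.1,47.2,0.7,1
NO2,Red111,Geomonas,7,29.5,0.0,-23.9,0.1,46.3,0.2,1
NO2,Red330,Geomonas,3,28.5,0.4,-22.5,0.5,46.5,0.2,1
NO2,Red330,Geomonas,7,28.6,0.2,-21.6,0.5,46.4,0.2,1
NO2,Red88,Oryzomonas,3,28.8,0.4,-21.6,0.7,44.8,2.0,1
NO2,Red88,Oryzomonas,7,28.8,0.3,-21.0,0.1,44.4,2.0,1
NO2,DSM16622,Geomonas,3,28.6,0.6,-22.9,0.2,47.4,2.3,1
NO2,JCM30203,Geobacter,3,28.7,0.7,-23.0,0.0,46.7,0.7,1
NO2,Abiotic,,1,20.1,0.2,-28.8,0.4,20.0,1.2,0
"""


def load_isotopocule_survey() -> pd.DataFrame:
    """The bundled strain-mean survey as a tidy DataFrame (23 rows)."""
    df = pd.read_csv(io.StringIO(_SURVEY_CSV))
    df["biotic"] = df["biotic"].astype(bool)
    return df


def survey_measurements() -> list[IsotopoculeMeasurement]:
    """The survey as substrate-referenced :class:`IsotopoculeMeasurement` records."""
    out = []
    for _, row in load_isotopocule_survey().iterrows():
        out.append(
            IsotopoculeMeasurement(
                sample_id=f"{row.strain}-{row.substrate}-{int(row.day)}d",
                strain=row.strain,
                substrate="abiotic" if row.strain == "Abiotic" else row.substrate,
                day=float(row.day),
                replicate=1,
                d15n_bulk=float(row.d15n_bulk),
                d18o=float(row.d18o),
                sp=float(row.sp),
                referenced=True,
            )
        )
    return out


def substrate_sp_groups(include_nitrite_only: bool = False) -> dict[str, list[float]]:
    """SP values grouped by substrate for the nitrate-ammonifying strains.

    The two nitrite-only strains (DSM16622, JCM30203) have no NO₃⁻ arm and are
    excluded by default so the substrate comparison is paired over the same
    five strains; pass ``include_nitrite_only=True`` to keep them in the NO₂⁻
    group.  The abiotic control is always excluded.
    """
    df = load_isotopocule_survey()
    df = df[df["biotic"]]
    if not include_nitrite_only:
        df = df[~df["strain"].isin(NITRITE_ONLY_STRAINS)]
    return {sub: grp["sp"].tolist() for sub, grp in df.groupby("substrate")}
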