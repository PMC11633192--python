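"""Synthetic DNRA culture generator.

Produces the two data shapes the analysis consumes — per-bottle time courses
of biomass and N species, and replicate-level N₂O isotopocule tables — with
the statistical structure the pipeline assumes, so every stage is testable
without external data.

Kinetic model (the simplest form reproducing the observed dynamics: substrate
drawdown over days with transient NO₂⁻ accumulation):

* biomass B grows logistically, dB/dt = r·B·(1 − B/K);
* NO₃⁻ is consumed first-order scaled by biomass, dS/dt = −k_consume·B·S,
  quantitatively producing NO₂⁻;
* NO₂⁻ is further reduced at k_nitrite·B·[NO₂⁻]; the reduced flux is
  partitioned into NH₄⁺ (y_nh4), N₂O-N (y_n2o) and an unmeasured remainder,
  so the latent state conserves nitrogen exactly.

Isotopes: each replicate's SP is a value-level mixture of the two pathway
endmembers, f·SP_DNRA + (1−f)·SP_cNor, with endmember spread; δ¹⁵Nbulk and
δ¹⁸O are the substrate value plus a drawn net fractionation; instrument noise
is added last and δ¹⁵Nα/β are derived from the noisy bulk and SP so the
isotopocule identities hold exactly on every generated row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrationError
from .gas_partition import VesselGeometry
from .iso_core import SubstrateReference
from .mixing import PointEndmember
from .nitrogen_budget import CultureTimeSeries
from .datasets import CNOR_ENDMEMBER, NITRATE_REFERENCE, NITRITE_REFERENCE

__all__ = ["CultureConfig", "simulate_culture", "simulate_isotopes", "SP_NOISE_SD"]

#: Instrument SD for SP (‰), propagated from the stated α (0.2‰) and bulk
#: (0.1‰) precisions via δ¹⁵Nβ = 2δ¹⁵Nbulk − δ¹⁵Nα: √(0.2² + (2·0.1)²) ≈ 0.28.
SP_NOISE_SD = math.sqrt(0.2**2 + (2 * 0.1) ** 2)


@dataclass
class CultureConfig:
    """All tunables of the synthetic culture and isotope generators.

    Defaults describe a standard NO₃⁻ incubation: 8 mM substrate in 20 mL
    medium under 30 mL headspace, first-order consumption by logistically
    growing biomass, product yields y_nh4 = 0.65 and y_n2o = 0.01 of reduced
    NO₂⁻-N, and a pure-DNRA isotope mixture (f_dnra = 1) around
    SP_DNRA = 46.2 ± 1.5‰ vs SP_cNor = −5.9 ± 2.1‰.  Use
    :meth:`nitrite_default` for the 2 mM NO₂⁻ arm (y_n2o = 0.02).
    """

    substrate: str = "NO3"
    substrate_mM: float = 8.0
    geometry: VesselGeometry = field(default_factory=VesselGeometry)
    # kinetics (per-OD600 first-order rates)
    k_consume: float = 0.12  # 1/(OD·h), substrate → NO₂⁻
    k_nitrite: float = 0.07  # 1/(OD·h), NO₂⁻ → products
    growth_rate: float = 0.12  # 1/h
    od_max: float = 0.4
    od_initial: float = 0.02
    # product yields (fractions of reduced NO₂⁻-N)
    y_nh4: float = 0.65
    y_n2o: float = 0.01
    # isotope model
    f_dnra: float = 1.0
    f_schedule: Optional[Sequence[tuple[float, float]]] = None  # [(day, f), ...] step fn
    sp_dnra: PointEndmember = field(default_factory=lambda: PointEndmember("DNRA", 46.2, 1.5))
    sp_cnor: PointEndmember = field(default_factory=lambda: CNOR_ENDMEMBER)
    eps15n_mean: float = -24.6
    eps15n_sd: float = 6.0
    eps18o_mean: float = 23.6
    eps18o_sd: float = 6.3
    # instrument noise (‰)
    noise_alpha: float = 0.2
    noise_bulk: float = 0.1
    noise_d18o: float = 0.1
    noise_sp: float = SP_NOISE_SD
    # measurement noise for the culture series
    noise_enabled: bool = True
    noise_od: float = 0.005
    noise_conc_mM: float = 0.05
    noise_n2o_rel: float = 0.02
    # sampling
    n_replicates: int = 3
    sample_days: tuple[float, ...] = (3.0, 7.0)
    t_end_h: float = 168.0
    dt_h: float = 0.05
    sample_every_h: float = 12.0

    def __post_init__(self) -> None:
        if self.substrate not in {"NO3", "NO2"}:
            raise ConfigError(f"substrate must be NO3 or NO2, got {self.substrate!r}")
        if self.y_nh4 + self.y_n2o > 1.0 + 1e-12:
            raise ConfigError("y_nh4 + y_n2o must be <= 1")
        if min(self.k_consume, self.k_nitrite, self.growth_rate) < 0:
            raise ConfigError("rates must be >= 0")
        if not (0.0 <= self.f_dnra <= 1.0):
            raise ConfigError("f_dnra must lie in [0, 1]")
        if self.dt_h <= 0 or self.dt_h > 0.1:
            raise ConfigError("integration step must satisfy 0 < dt_h <= 0.1")

    @classmethod
    def nitrite_default(cls, **overrides) -> "CultureConfig":
        """The standard NO₂⁻ arm: 2 mM substrate, y_n2o = 0.02."""
        kw = dict(substrate="NO2", substrate_mM=2.0, y_n2o=0.02)
        kw.update(overrides)
        return cls(**kw)

    @property
    def substrate_reference(self) -> SubstrateReference:
        return NITRATE_REFERENCE if self.substrate == "NO3" else NITRITE_REFERENCE

    def f_at(self, day: float) -> float:
        """Pathway mixture at a given day (step schedule, else constant)."""
        f = self.f_dnra
        if self.f_schedule:
            for d, fv in sorted(self.f_schedule):
                if day >= d:
                    f = fv
        return f


def simulate_culture(cfg: CultureConfig, seed: int, bottle_id: str = "synthetic-1") -> CultureTimeSeries:
    """Forward-Euler integration of the culture model; deterministic per seed.

    Returns a :class:`CultureTimeSeries` sampled every ``cfg.sample_every_h``
    hours, with Gaussian measurement noise when ``cfg.noise_enabled`` (noisy
    concentrations are floored at zero).  The noise-free latent state —
    including the unmeasured-N pool — is attached as ``.latent``; nitrogen
    closure holds exactly there.
    """
    rng = np.random.default_rng(seed)
    v = cfg.geometry.v_liquid
    # state in µmol N per bottle
    no3 = cfg.substrate_mM * v if cfg.substrate == "NO3" else 0.0
    no2 = cfg.substrate_mM * v if cfg.substrate == "NO2" else 0.0
    nh4 = 0.0
    n2o_n = 0.0
    other = 0.0
    od = cfg.od_initial
    initial_n = no3 + no2

    n_steps = int(round(cfg.t_end_h / cfg.dt_h))
    sample_times = [round(i * cfg.sample_every_h, 9) for i in range(int(cfg.t_end_h / cfg.sample_every_h) + 1)]
    records = []
    t = 0.0
    next_sample = 0

    def record(time_h: float) -> None:
        records.append((time_h, od, no3 / v, no2 / v, nh4 / v, n2o_n / 2.0, other))

    record(0.0)
    next_sample = 1
    for step in range(1, n_steps + 1):
        d_no3 = cfg.k_consume * od * no3 * cfg.dt_h
        d_no2_out = cfg.k_nitrite * od * no2 * cfg.dt_h
        no3 -= d_no3
        no2 += d_no3 - d_no2_out
        nh4 += cfg.y_nh4 * d_no2_out
        n2o_n += cfg.y_n2o * d_no2_out
        other += (1.0 - cfg.y_nh4 - cfg.y_n2o) * d_no2_out
        od += cfg.growth_rate * od * (1.0 - od / cfg.od_max) * cfg.dt_h
        t = step * cfg.dt_h
        if min(no3, no2, nh4, n2o_n, other) < -1e-9:
            raise IntegrationError(
                f"state went negative at t={t:.2f} h; reduce dt_h (currently {cfg.dt_h} h)"
            )
        while next_sample < len(sample_times) and t >= sample_times[next_sample] - 1e-9:
            record(sample_times[next_sample])
            next_sample += 1

    latent = pd.DataFrame(
        records,
        columns=["time_h", "od600", "no3_mM", "no2_mM", "nh4_mM", "n2o_umol", "unmeasured_N"],
    )
    data = latent[["time_h", "od600", "no3_mM", "no2_mM", "nh4_mM", "n2o_umol"]].copy()
    if cfg.noise_enabled:
        n = len(data)
        data["od600"] += rng.normal(0.0, cfg.noise_od, n)
        for col in ("no3_mM", "no2_mM", "nh4_mM"):
            data[col] += rng.normal(0.0, cfg.noise_conc_mM, n)
        data["n2o_umol"] *= 1.0 + rng.normal(0.0, cfg.noise_n2o_rel, n)
        data[data.columns[1:]] = data[data.columns[1:]].clip(lower=0.0)
    return CultureTimeSeries(
        bottle_id=bottle_id,
        strain="synthetic",
        substrate=cfg.substrate,
        data=data,
        geometry=cfg.geometry,
        latent=latent,
    )


def simulate_isotopes(cfg: CultureConfig, seed: int, strain: str = "synthetic") -> pd.DataFrame:
    """Replicate-level raw-scale isotopocule table; deterministic per seed.

    One row per (sample day, replicate).  SP is the value-level pathway
    mixture plus instrument noise; δ¹⁵Nbulk/δ¹⁸O are substrate value + drawn
    net fractionation + instrument noise; δ¹⁵Nα/β are derived from the final
    bulk and SP, so every row passes isotopocule consistency validation
    exactly.  Values are on the raw calibrated scale (``referenced`` False);
    subtract the substrate reference to compare with zone libraries.
    """
    rng = np.random.default_rng(seed)
    ref = cfg.substrate_reference
    rows = []
    for day in cfg.sample_days:
        f = cfg.f_at(day)
        for rep in range(1, cfg.n_replicates + 1):
            sp_d = rng.normal(cfg.sp_dnra.sp, cfg.sp_dnra.sp_sd)
            sp_c = rng.normal(cfg.sp_cnor.sp, cfg.sp_cnor.sp_sd)
            sp = f * sp_d + (1.0 - f) * sp_c + rng.normal(0.0, cfg.noise_sp)
            bulk = ref.d15n + rng.normal(cfg.eps15n_mean, cfg.eps15n_sd) + rng.normal(0.0, cfg.noise_bulk)
            d18o = ref.d18o + rng.normal(cfg.eps18o_mean, cfg.eps18o_sd) + rng.normal(0.0, cfg.noise_d18o)
            rows.append(
                {
                    "sample_id": f"{strain}-{cfg.substrate}-{day:g}d-r{rep}",
                    "strain": strain,
                    "substrate": cfg.substrate,
                    "day": day,
                    "replicate": rep,
                    "d15N_alpha": bulk + sp / 2.0,
                    "d15N_bulk": bulk,
                    "d18O": d18o,
                    "SP": sp,
                }
            )
    return pd.DataFrame(rows)
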