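"""Per-bottle nitrogen accounting for DNRA culture time courses.

Converts concentration time series to absolute µmol-N pools, computes
substrate-to-product conversion ratios, end-stage nitrogen composition with
closure, and the linear association between N₂O production and transient NO₂⁻
accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError, UndefinedRatioError, ValidationError
from .gas_partition import VesselGeometry

__all__ = [
    "CultureTimeSeries",
    "amounts_as_n",
    "conversion_ratio",
    "end_stage_composition",
    "production_association",
    "yield_estimates",
    "AssociationFit",
]

#: Concentration columns (mM) and the N₂O column (µmol/bottle) expected in a series.
SERIES_COLUMNS = ["time_h", "od600", "no3_mM", "no2_mM", "nh4_mM", "n2o_umol"]

_SPECIES = {"NO3": "no3_mM", "NO2": "no2_mM", "NH4": "nh4_mM"}


@dataclass
class CultureTimeSeries:
    """Time course of biomass and N species for one culture bottle.

    ``data`` holds one row per sampling time with columns ``time_h`` (h),
    ``od600``, ``no3_mM``/``no2_mM``/``nh4_mM`` (mM) and ``n2o_umol``
    (total µmol N₂O per bottle, already partition-corrected).  ``latent``
    optionally carries the simulator's noise-free state including the
    unmeasured-N pool.
    """

    bottle_id: str
    strain: str
    substrate: str  # "NO3" or "NO2"
    data: pd.DataFrame
    geometry: Optional[VesselGeometry] = None
    latent: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.substrate not in {"NO3", "NO2"}:
            raise ValidationError(f"substrate must be NO3 or NO2, got {self.substrate!r}")
        missing = [c for c in SERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"bottle {self.bottle_id!r}: missing columns {missing}")
        t = self.data["time_h"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValidationError(f"bottle {self.bottle_id!r}: time not strictly increasing")
        vals = self.data[SERIES_COLUMNS[1:]].to_numpy(float)
        if np.any(vals < 0):
            raise ValidationError(f"bottle {self.bottle_id!r}: negative concentration/amount")

    @property
    def initial_substrate_mM(self) -> float:
        col = _SPECIES[self.substrate]
        return float(self.data[col].iloc[0])


def amounts_as_n(ts: CultureTimeSeries) -> pd.DataFrame:
    """Absolute µmol N per species per sampling time.

    mM × v_liquid (mL) = µmol for the ionic species; each µmol N₂O carries
    2 µmol N.
    """
    if ts.geometry is None:
        raise ConfigError(f"bottle {ts.bottle_id!r}: geometry required to convert mM to µmol")
    v = ts.geometry.v_liquid
    out = pd.DataFrame({"time_h": ts.data["time_h"].to_numpy(float)})
    out["no3_N"] = ts.data["no3_mM"].to_numpy(float) * v
    out["no2_N"] = ts.data["no2_mM"].to_numpy(float) * v
    out["nh4_N"] = ts.data["nh4_mM"].to_numpy(float) * v
    out["n2o_N"] = ts.data["n2o_umol"].to_numpy(float) * 2.0
    return out


def _n_column(species: str) -> str:
    cols = {"NO3": "no3_N", "NO2": "no2_N", "NH4": "nh4_N", "N2O": "n2o_N"}
    try:
        return cols[species]
    except KeyError:
        raise ValidationError(f"unknown species {species!r}; expected one of {sorted(cols)}") from None


def conversion_ratio(
    ts: CultureTimeSeries, product: str, t_end: Optional[float] = None
) -> float:
    """Product-N produced per substrate-N consumed over [t0, t_end].

    ``product`` is one of NO2, NH4, N2O (N2O counted as 2 N).  Raises
    :class:`~n2oiso.errors.UndefinedRatioError` if no substrate was consumed
    over the interval — the ratio is undefined, not zero.
    """
    amounts = amounts_as_n(ts)
    if t_end is None:
        t_end = float(amounts["time_h"].iloc[-1])
    window = amounts[amounts["time_h"] <= t_end]
    if len(window) < 2:
        raise UndefinedRatioError(f"bottle {ts.bottle_id!r}: interval [t0, {t_end}] has < 2 points")
    scol = _n_column(ts.substrate)
    consumed = float(window[scol].iloc[0] - window[scol].iloc[-1])
    if consumed <= 0:
        raise UndefinedRatioError(
            f"bottle {ts.bottle_id!r}: no {ts.substrate} consumed by t={t_end} h"
        )
    pcol = _n_column(product)
    produced = float(window[pcol].iloc[-1] - window[pcol].iloc[0])
    return produced / consumed


def end_stage_composition(
    ts: CultureTimeSeries, t_end: Optional[float] = None
) -> dict[str, float]:
    """Nitrogen pools at the end of the run as fractions of initial substrate-N.

    Returns fractions for NO3, NO2, NH4, N2O-N and the unrecovered remainder;
    the five sum to 1 exactly.  Unrecovered may be negative if the measured
    pools over-close the budget — it is reported as-is, never clipped.  The
    final reaction stage defaults to the last sampling time; pass ``t_end`` to
    override.
    """
    amounts = amounts_as_n(ts)
    initial = ts.initial_substrate_mM * ts.geometry.v_liquid  # type: ignore[union-attr]
    if initial <= 0:
        raise ValidationError(f"bottle {ts.bottle_id!r}: initial substrate-N is zero")
    window = amounts if t_end is None else amounts[amounts["time_h"] <= t_end]
    last = window.iloc[-1]
    frac = {
        "NO3": float(last["no3_N"]) / initial,
        "NO2": float(last["no2_N"]) / initial,
        "NH4": float(last["nh4_N"]) / initial,
        "N2O-N": float(last["n2o_N"]) / initial,
    }
    frac["unrecovered"] = 1.0 - sum(frac.values())
    return frac


def yield_estimates(ts: CultureTimeSeries, t_end: Optional[float] = None) -> dict[str, float]:
    """Estimate the product yields of the NO₂⁻-reduction branch point.

    NH₄⁺ and N₂O arise from onward NO₂⁻ reduction, so the natural yield
    estimator normalises product-N by *reduced NO₂⁻-N* — substrate-N consumed
    minus the net NO₂⁻ still accumulated — rather than by consumed
    substrate-N (which :func:`conversion_ratio` uses and which understates
    the branch yields while NO₂⁻ remains).  For NO₂⁻-fed cultures the two
    denominators coincide.
    """
    amounts = amounts_as_n(ts)
    if t_end is None:
        t_end = float(amounts["time_h"].iloc[-1])
    window = amounts[amounts["time_h"] <= t_end]
    scol = _n_column(ts.substrate)
    consumed = float(window[scol].iloc[0] - window[scol].iloc[-1])
    d_no2 = float(window["no2_N"].iloc[-1] - window["no2_N"].iloc[0]) if ts.substrate == "NO3" else 0.0
    reduced = consumed - d_no2
    if reduced <= 0:
        raise UndefinedRatioError(f"bottle {ts.bottle_id!r}: no NO2-N reduced by t={t_end} h")
    return {
        "y_nh4": float(window["nh4_N"].iloc[-1] - window["nh4_N"].iloc[0]) / reduced,
        "y_n2o": float(window["n2o_N"].iloc[-1] - window["n2o_N"].iloc[0]) / reduced,
        "reduced_share": reduced / consumed if consumed > 0 else float("nan"),
    }


@dataclass(frozen=True)
class AssociationFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def production_association(
    ts: CultureTimeSeries,
    x: str = "NO2",
    y: str = "N2O",
    x_mode: str = "cummax",
    phase: str = "accumulation",
) -> AssociationFit:
    """OLS of cumulative ``y``-N production on ``x``-N accumulation.

    ``x_mode='cummax'`` (default) defines NO₂⁻ accumulation as the
    max-to-date net increase above the initial level; ``x_mode='level'`` uses
    the instantaneous net change instead.  ``phase='accumulation'`` (default)
    fits over the accumulation phase only — sampling times up to and
    including the accumulation peak — since that is where the claimed
    coupling operates (once accumulation stops, the regressor carries no new
    information while the product keeps integrating); ``phase='full'`` fits
    every time point.  The p-value is the two-sided test of zero slope.
    """
    amounts = amounts_as_n(ts)
    if len(amounts) < 3:
        raise ValidationError(f"bottle {ts.bottle_id!r}: need >= 3 time points")
    xv = amounts[_n_column(x)].to_numpy(float)
    xv = xv - xv[0]
    if x_mode == "cummax":
        xv = np.maximum.accumulate(xv)
    elif x_mode != "level":
        raise ValidationError(f"unknown x_mode {x_mode!r}")
    yv = amounts[_n_column(y)].to_numpy(float)
    yv = yv - yv[0]
    if np.ptp(xv) == 0:
        raise DegenerateInputError(
            f"bottle {ts.bottle_id!r}: {x} accumulation is constant; fit is degenerate"
        )
    if phase == "accumulation":
        peak = int(np.argmax(np.maximum.accumulate(xv)))
        if peak >= 2:  # need >= 3 points to fit the phase alone
            xv, yv = xv[: peak + 1], yv[: peak + 1]
    elif phase != "full":
        raise ValidationError(f"unknown phase {phase!r}")
    fit = stats.linregress(xv, yv)
    return AssociationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(xv),
    )
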