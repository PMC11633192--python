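"""Dual-isotope source-zone classification and N₂O-reduction back-projection.

N₂O production pathways occupy characteristic regions ("zones") in
(SP, δ¹⁵Nbulk, δ¹⁸O) space — bacterial/fungal/chemical denitrification,
nitrification, nitrifier denitrification, and the nitrate-ammonification (DNRA)
zone established from pure-culture Geobacteraceae measurements
(SP 43.0–49.9‰, δ¹⁵Nbulk −39.9 to −5.8‰, δ¹⁸O 14.1–30.5‰, substrate-
referenced δ axes).  Partial consumption of N₂O by N₂O reductase moves the
residual gas along a characteristic "reduction vector" with slopes
ε(SP)/ε(δ¹⁵N) = 0.96 and ε(δ¹⁸O)/ε(δ¹⁵N) = 2.21; back-projecting an
observation along this line tests whether an apparent signature could be a
reduced remnant of another source zone.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Sequence

from .errors import ValidationError
from .iso_core import IsotopoculeMeasurement

__all__ = [
    "EndmemberZone",
    "ReductionVector",
    "classify",
    "apply_reduction",
    "reachable_zones",
    "load_zone_library",
    "default_zone_library",
]

Range = tuple[float, float]


@dataclass(frozen=True)
class EndmemberZone:
    """A source process's region in isotopocule space.

    Each axis range is optional; a zone constrains only the axes it defines.
    Membership uses closed intervals — boundary points match.
    """

    name: str
    sp_range: Optional[Range] = None
    d15n_range: Optional[Range] = None
    d18o_range: Optional[Range] = None
    source: str = ""

    def __post_init__(self) -> None:
        for label, rng in (("sp", self.sp_range), ("d15n", self.d15n_range), ("d18o", self.d18o_range)):
            if rng is not None and rng[0] > rng[1]:
                raise ValidationError(f"zone {self.name!r}: {label} range has low > high")

    def axes(self) -> dict[str, Optional[Range]]:
        return {"sp": self.sp_range, "d15n_bulk": self.d15n_range, "d18o": self.d18o_range}


@dataclass(frozen=True)
class ReductionVector:
    """Slopes of the residual-N₂O trajectory under N₂O reductase consumption.

    δ¹⁵Nbulk parameterises the line: a shift Δ in δ¹⁵N moves SP by
    ``slope_sp_d15n``·Δ and δ¹⁸O by ``slope_d18o_d15n``·Δ.  The independently
    reported ε(SP)/ε(δ¹⁸O) = 0.45 is carried for reference; it is slightly
    inconsistent with 0.96/2.21 ≈ 0.434 (rounding in the source values), and
    the δ¹⁵N-parameterised pair is what :func:`apply_reduction` uses so the
    three axes stay mutually consistent.
    """

    slope_sp_d15n: float = 0.96
    slope_d18o_d15n: float = 2.21
    slope_sp_d18o: float = 0.45

    def __post_init__(self) -> None:
        for s in (self.slope_sp_d15n, self.slope_d18o_d15n, self.slope_sp_d18o):
            if not (s == s and abs(s) not in (0.0, float("inf"))):
                raise ValidationError("reduction-vector slopes must be finite and nonzero")


def classify(
    meas: IsotopoculeMeasurement, library: Sequence[EndmemberZone]
) -> set[str]:
    """Names of zones containing the measurement.

    A zone matches iff every axis range it defines contains the corresponding
    coordinate.  A zone constraining an axis the measurement lacks is counted
    as a non-match with a warning (the point cannot be shown to lie inside).
    δ axes are meaningful only for substrate-referenced records; SP is
    frame-free.
    """
    matches: set[str] = set()
    coords = {"sp": meas.sp, "d15n_bulk": meas.d15n_bulk, "d18o": meas.d18o}
    for zone in library:
        ok = True
        for axis, rng in zone.axes().items():
            if rng is None:
                continue
            v = coords[axis]
            if v is None:
                warnings.warn(
                    f"zone {zone.name!r} constrains {axis} but sample "
                    f"{meas.sample_id!r} lacks it; treating as non-match",
                    stacklevel=2,
                )
                ok = False
                break
            if not (rng[0] <= v <= rng[1]):
                ok = False
                break
        if ok:
            matches.add(zone.name)
    return matches


def apply_reduction(
    point: IsotopoculeMeasurement,
    delta_d15n: float,
    vector: ReductionVector = ReductionVector(),
) -> IsotopoculeMeasurement:
    """Shift a point along the N₂O-reduction line by Δδ¹⁵N = ``delta_d15n``.

    δ¹⁵Nbulk moves by Δ, SP by slope_sp_d15n·Δ, δ¹⁸O by slope_d18o_d15n·Δ.
    δ¹⁵Nα/β, when present, are recomputed from the shifted bulk and SP so the
    isotopocule identities keep holding.  Composition is additive:
    apply(Δ₁)∘apply(Δ₂) = apply(Δ₁+Δ₂).
    """
    if point.d15n_bulk is None:
        raise ValidationError(f"sample {point.sample_id!r}: d15n_bulk required for reduction shift")
    bulk = point.d15n_bulk + delta_d15n
    sp = None if point.sp is None else point.sp + vector.slope_sp_d15n * delta_d15n
    d18o = None if point.d18o is None else point.d18o + vector.slope_d18o_d15n * delta_d15n
    alpha = beta = None
    if point.d15n_alpha is not None and sp is not None:
        alpha, beta = bulk + sp / 2.0, bulk - sp / 2.0
    return replace(point, d15n_bulk=bulk, sp=sp, d18o=d18o, d15n_alpha=alpha, d15n_beta=beta)


def reachable_zones(
    point: IsotopoculeMeasurement,
    vector: ReductionVector,
    zone_library: Sequence[EndmemberZone],
    delta_range: Range,
) -> dict[str, Optional[Range]]:
    """Feasible back-projection interval per zone, or ``None`` if unreachable.

    For each zone, solves the interval of Δ ≥ 0 (within ``delta_range``) such
    that the back-projected source point — the observation shifted by −Δ along
    the reduction line — lies inside the zone: the intersection of the per-axis
    interval constraints.  ``delta_range = (0, 0)`` reduces to plain
    :func:`classify` membership.
    """
    lo0, hi0 = delta_range
    if not (lo0 <= hi0) or not all(map(_finite, delta_range)):
        raise ValidationError("delta_range must be finite with low <= high")
    coords = {"sp": point.sp, "d15n_bulk": point.d15n_bulk, "d18o": point.d18o}
    slopes = {"d15n_bulk": 1.0, "sp": vector.slope_sp_d15n, "d18o": vector.slope_d18o_d15n}
    out: dict[str, Optional[Range]] = {}
    for zone in zone_library:
        lo, hi = lo0, hi0
        feasible = True
        for axis, rng in zone.axes().items():
            if rng is None:
                continue
            v = coords[axis]
            if v is None:
                warnings.warn(
                    f"zone {zone.name!r} constrains {axis} but sample "
                    f"{point.sample_id!r} lacks it; zone unreachable",
                    stacklevel=2,
                )
                feasible = False
                break
            m = slopes[axis]
            # rng[0] <= v - m*delta <= rng[1]; m > 0 for all shipped slopes
            a, b = (v - rng[1]) / m, (v - rng[0]) / m
            if m < 0:
                a, b = b, a
            lo, hi = max(lo, a), min(hi, b)
            if lo > hi:
                feasible = False
                break
        out[zone.name] = (lo, hi) if feasible else None
    return out


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def _zone_from_dict(name: str, spec: dict) -> EndmemberZone:
    def rng(key: str) -> Optional[Range]:
        v = spec.get(key)
        return None if v is None else (float(v[0]), float(v[1]))

    return EndmemberZone(
        name=name,
        sp_range=rng("sp"),
        d15n_range=rng("d15n_bulk"),
        d18o_range=rng("d18o"),
        source=spec.get("source", ""),
    )


def load_zone_library(path) -> list[EndmemberZone]:
    """Read a declarative TOML zone library (one ``[zones.NAME]`` table per zone,
    keys ``sp``/``d15n_bulk``/``d18o`` = [low, high], optional ``source``)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    zones = doc.get("zones", {})
    if not zones:
        raise ValidationError(f"{path}: no [zones.*] tables found")
    return [_zone_from_dict(name, spec) for name, spec in zones.items()]


def default_zone_library() -> list[EndmemberZone]:
    """The zone library shipped with the package (``data/zones.toml``)."""
    ref = resources.files("n2oiso.data").joinpath("zones.toml")
    with resources.as_file(ref) as path:
        return load_zone_library(path)
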