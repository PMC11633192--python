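"""Isotopocule calculus for N₂O.

The linear N₂O molecule (β-N–α-N–O) carries two distinguishable ¹⁵N positions.
Four δ quantities describe them:

* ``d15n_alpha`` — δ¹⁵N of the central (α) nitrogen, ‰ vs air-N₂
* ``d15n_beta``  — δ¹⁵N of the terminal (β) nitrogen, ‰ vs air-N₂
* ``d15n_bulk``  — average of the two, (δ¹⁵Nα + δ¹⁵Nβ)/2
* ``sp``         — site preference, δ¹⁵Nα − δ¹⁵Nβ

Any two of the four determine the other two; this module completes partial
records, validates over-determined ones, and re-expresses δ¹⁵N/δ¹⁸O relative
to the substrate (NO₃⁻ or NO₂⁻) from which the N₂O was produced.  All δ values
are stored as plain numbers on the per-mil scale (46.5 means 46.5‰); every
formula used here is linear in per-mil, so no ratio-space conversion is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import InconsistencyError, InsufficientDataError, StateError, ValidationError

__all__ = [
    "IsotopoculeMeasurement",
    "SubstrateReference",
    "complete_isotopocule",
    "substrate_reference",
    "unreference",
    "CONSISTENCY_TOL",
]

#: Tolerance (‰) for declaring an over-determined record inconsistent: one
#: decimal beyond the 0.1‰ reporting precision of the isotope tables.
CONSISTENCY_TOL = 0.01

_SUBSTRATES = {"NO3", "NO2", "NO_donor", "abiotic"}


@dataclass
class IsotopoculeMeasurement:
    """One N₂O isotopocule observation with sample metadata.

    Missing isotope fields are ``None``; ``referenced`` records whether the
    δ¹⁵N/δ¹⁸O values are raw calibrated-scale or product-minus-substrate
    differences.  Site preference is invariant under that change of frame.
    """

    sample_id: str
    strain: str = ""
    substrate: str = "NO3"
    day: float = 1.0
    replicate: int = 1
    d15n_alpha: Optional[float] = None
    d15n_beta: Optional[float] = None
    d15n_bulk: Optional[float] = None
    d18o: Optional[float] = None
    sp: Optional[float] = None
    referenced: bool = False

    def __post_init__(self) -> None:
        if self.substrate not in _SUBSTRATES:
            raise ValidationError(
                f"unknown substrate {self.substrate!r}; expected one of {sorted(_SUBSTRATES)}"
            )
        if not self.day > 0:
            raise ValidationError(f"incubation day must be > 0, got {self.day}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def n15_fields(self) -> dict:
        return {
            "d15n_alpha": self.d15n_alpha,
            "d15n_beta": self.d15n_beta,
            "d15n_bulk": self.d15n_bulk,
            "sp": self.sp,
        }


@dataclass(frozen=True)
class SubstrateReference:
    """Isotopic composition of the culture substrate (NO₃⁻ or NO₂⁻).

    Shipped defaults (see :mod:`n2oiso.datasets`): NO₃⁻ δ¹⁵N 2.4±0.1‰,
    δ¹⁸O 17.9±0.3‰; NO₂⁻ δ¹⁵N −1.8±0.3‰, δ¹⁸O 3.7±0.2‰.
    """

    species: str
    d15n: float
    d18o: float
    d15n_sd: float = 0.0
    d18o_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in {"NO3", "NO2"}:
            raise ValidationError(f"substrate reference species must be NO3 or NO2, got {self.species!r}")
        if self.d15n_sd < 0 or self.d18o_sd < 0:
            raise ValidationError("reference SDs must be >= 0")


def _solve_alpha_beta(fields: dict) -> tuple[float, float]:
    """Solve (α, β) from any sufficient pair of the four ¹⁵N quantities."""
    a, b = fields["d15n_alpha"], fields["d15n_beta"]
    bulk, sp = fields["d15n_bulk"], fields["sp"]
    if a is not None and b is not None:
        return a, b
    if a is not None and bulk is not None:
        return a, 2.0 * bulk - a
    if b is not None and bulk is not None:
        return 2.0 * bulk - b, b
    if a is not None and sp is not None:
        return a, a - sp
    if b is not None and sp is not None:
        return b + sp, b
    if bulk is not None and sp is not None:
        return bulk + sp / 2.0, bulk - sp / 2.0
    raise InsufficientDataError(
        "need at least two of {d15n_alpha, d15n_beta, d15n_bulk, sp} to complete a record"
    )


def complete_isotopocule(
    meas: IsotopoculeMeasurement, tol: float = CONSISTENCY_TOL
) -> IsotopoculeMeasurement:
    """Fill all four ¹⁵N quantities from any mutually sufficient subset.

    Uses SP = δ¹⁵Nα − δ¹⁵Nβ and δ¹⁵Nbulk = (δ¹⁵Nα + δ¹⁵Nβ)/2 (equivalently
    δ¹⁵Nβ = 2δ¹⁵Nbulk − δ¹⁵Nα).  If the record is over-determined and any
    supplied value disagrees with the completion by more than ``tol`` (‰),
    an :class:`~n2oiso.errors.InconsistencyError` carrying the worst residual
    is raised.

    Raises
    ------
    InsufficientDataError
        Fewer than two independent quantities present (SP alone, bulk alone...).
    InconsistencyError
        Over-determined input disagrees beyond ``tol``.
    """
    fields = meas.n15_fields
    alpha, beta = _solve_alpha_beta(fields)
    completed = {
        "d15n_alpha": alpha,
        "d15n_beta": beta,
        "d15n_bulk": (alpha + beta) / 2.0,
        "sp": alpha - beta,
    }
    residual = max(
        (abs(completed[k] - v) for k, v in fields.items() if v is not None),
        default=0.0,
    )
    if residual > tol:
        raise InconsistencyError(
            f"record {meas.sample_id!r} over-determined and inconsistent: "
            f"worst residual {residual:.4g}‰ exceeds tolerance {tol}‰",
            residual=residual,
        )
    return replace(meas, **completed)


def substrate_reference(
    meas: IsotopoculeMeasurement, ref: SubstrateReference
) -> IsotopoculeMeasurement:
    """Express δ¹⁵N and δ¹⁸O as product-minus-substrate differences.

    Every ¹⁵N position shifts by the same −δ¹⁵N_substrate, so δ¹⁵Nα, δ¹⁵Nβ and
    δ¹⁵Nbulk all move while SP — a difference of two ¹⁵N positions — is exactly
    invariant.  δ¹⁸O shifts by −δ¹⁸O_substrate.

    Raises
    ------
    StateError
        The record is already substrate-referenced.
    """
    if meas.referenced:
        raise StateError(f"record {meas.sample_id!r} is already substrate-referenced")
    sub = lambda v, r: None if v is None else v - r
    return replace(
        meas,
        d15n_alpha=sub(meas.d15n_alpha, ref.d15n),
        d15n_beta=sub(meas.d15n_beta, ref.d15n),
        d15n_bulk=sub(meas.d15n_bulk, ref.d15n),
        d18o=sub(meas.d18o, ref.d18o),
        referenced=True,
    )


def unreference(meas: IsotopoculeMeasurement, ref: SubstrateReference) -> IsotopoculeMeasurement:
    """Exact inverse of :func:`substrate_reference`."""
    if not meas.referenced:
        raise StateError(f"record {meas.sample_id!r} is not substrate-referenced")
    add = lambda v, r: None if v is None else v + r
    return replace(
        meas,
        d15n_alpha=add(meas.d15n_alpha, ref.d15n),
        d15n_beta=add(meas.d15n_beta, ref.d15n),
        d15n_bulk=add(meas.d15n_bulk, ref.d15n),
        d18o=add(meas.d18o, ref.d18o),
        referenced=False,
    )
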