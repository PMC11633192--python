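"""Two-endmember isotope mass balance on site preference, with Monte Carlo.

When two processes co-produce N₂O, the observed site preference is the
production-weighted mean of the endmember SPs:

    SP_mix = f·SP_a + (1 − f)·SP_b

Solving for f partitions the mixture; here the canonical use is attributing
late-culture N₂O between the high-SP nitrate-ammonification (DNRA) pathway and
low-SP denitrifier-type NO reduction by cNor (−5.9 ± 2.1‰).  Uncertainty in
all three SP values is propagated by seeded Monte Carlo with independent
Gaussian draws (reported ± values are read as 1 SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, EstimationError, ValidationError

__all__ = ["PointEndmember", "MixingResult", "solve_fraction", "predict_mixture", "predict_multi", "mc_fraction"]

_DEGENERATE_TOL = 1e-6


@dataclass(frozen=True)
class PointEndmember:
    """A source pathway's characteristic SP value (‰) with 1-SD uncertainty."""

    name: str
    sp: float
    sp_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sp_sd < 0:
            raise ValidationError(f"endmember {self.name!r}: sp_sd must be >= 0")


@dataclass(frozen=True)
class MixingResult:
    """Endmember-fraction estimate with Monte-Carlo uncertainty.

    ``f_point`` is the closed-form solution at the stated means; the MC fields
    summarise the draw distribution.  ``clipped_share`` is the share of draws
    falling outside [0, 1]; draws are *retained* in the statistics (silent
    truncation would bias f near the boundaries), the share is reported so the
    caller can judge boundary effects.  ``n_degenerate`` counts rejected and
    resampled draws with near-equal endmembers.
    """

    f_point: float
    f_mean: float
    f_sd: float
    ci_low: float
    ci_high: float
    n_draws: int
    seed: int
    clipped_share: float
    n_degenerate: int = 0


def solve_fraction(sp_mix: float, a: PointEndmember, b: PointEndmember) -> float:
    """Closed-form fraction of endmember ``a`` in the mixture.

    f_a = (SP_mix − SP_b) / (SP_a − SP_b).  The value is returned unclipped:
    results outside [0, 1] signal that the observation is not bracketed by the
    endmembers (extrapolation), which callers should inspect rather than hide.
    """
    denom = a.sp - b.sp
    if abs(denom) < _DEGENERATE_TOL:
        raise DegenerateInputError(
            f"endmembers {a.name!r} and {b.name!r} have equal SP ({a.sp}‰); fraction undefined"
        )
    return (sp_mix - b.sp) / denom


def predict_mixture(f: float, a: PointEndmember, b: PointEndmember) -> float:
    """Forward mixture SP: f·SP_a + (1 − f)·SP_b.  Exact inverse of
    :func:`solve_fraction`; f outside [0, 1] extrapolates."""
    return f * a.sp + (1.0 - f) * b.sp


def predict_multi(fractions: Sequence[float], endmembers: Sequence[PointEndmember]) -> float:
    """Forward k-endmember mixture SP, Σ f_i·SP_i with Σ f_i = 1.

    Only the forward direction generalises: inverting k > 2 endmembers from a
    single SP axis is under-determined, and :func:`solve_fraction` refuses it
    by accepting exactly two endmembers.
    """
    if len(fractions) != len(endmembers):
        raise ValidationError("fractions and endmembers must have equal length")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {sum(fractions)}")
    return float(sum(f * e.sp for f, e in zip(fractions, endmembers)))


def mc_fraction(
    sp_mix: float,
    sp_mix_sd: float,
    a: PointEndmember,
    b: PointEndmember,
    n_draws: int = 100_000,
    seed: int = 0,
) -> MixingResult:
    """Monte-Carlo propagation of SP uncertainty through :func:`solve_fraction`.

    Independent normal draws for SP_mix, SP_a and SP_b; per-draw closed-form f;
    mean, SD and the 2.5–97.5 percentile interval of the draws.  Draws whose
    endmember difference falls below 1e-6‰ are rejected and resampled (count
    reported as ``n_degenerate``).  Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    if sp_mix_sd < 0:
        raise ValidationError("sp_mix_sd must be >= 0")
    f_point = solve_fraction(sp_mix, a, b)
    if sp_mix_sd == 0.0 and a.sp_sd == 0.0 and b.sp_sd == 0.0:
        # degenerate-noise limit: every draw equals the closed form exactly
        return MixingResult(
            f_point=f_point, f_mean=f_point, f_sd=0.0, ci_low=f_point, ci_high=f_point,
            n_draws=n_draws, seed=seed,
            clipped_share=0.0 if 0.0 <= f_point <= 1.0 else 1.0,
        )

    rng = np.random.default_rng(seed)
    f_draws = np.empty(n_draws)
    filled = 0
    n_degenerate = 0
    attempts = 0
    while filled < n_draws:
        attempts += 1
        if attempts > 1000:
            raise EstimationError("all Monte-Carlo draws degenerate; endmember SDs overlap completely")
        need = n_draws - filled
        mix = rng.normal(sp_mix, sp_mix_sd, need)
        sa = rng.normal(a.sp, a.sp_sd, need)
        sb = rng.normal(b.sp, b.sp_sd, need)
        ok = np.abs(sa - sb) >= _DEGENERATE_TOL
        n_degenerate += int(need - ok.sum())
        k = int(ok.sum())
        f_draws[filled : filled + k] = (mix[ok] - sb[ok]) / (sa[ok] - sb[ok])
        filled += k

    lo, hi = np.percentile(f_draws, [2.5, 97.5])
    return MixingResult(
        f_point=f_point,
        f_mean=float(f_draws.mean()),
        f_sd=float(f_draws.std(ddof=1)) if n_draws > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=n_draws,
        seed=seed,
        clipped_share=float(np.mean((f_draws < 0.0) | (f_draws > 1.0))),
        n_degenerate=n_degenerate,
    )
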