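"""Group summaries and nonparametric comparisons of isotopocule values.

Median SP (or δ¹⁵Nbulk, δ¹⁸O) by substrate, genus, strain or day, with the
rank tests conventional for small isotope data sets: Mann–Whitney U for two
groups and Kruskal–Wallis H for three or more.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupMedian",
    "group_medians",
    "round_half_away",
    "mann_whitney",
    "kruskal_wallis",
    "MannWhitneyResult",
    "KruskalWallisResult",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (so 46.35 → 46.4, −46.35 → −46.4).

    Python's built-in ``round`` is banker's rounding; isotope tables are
    conventionally reported with half-away-from-zero at one decimal.  The
    value is first snapped at ``decimals + 8`` digits so a binary-float
    representation error (46.349999…994 for the median of 46.3 and 46.4)
    cannot flip a genuine half tie downward.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(round(x, decimals + 8))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupMedian:
    raw: float
    reported: float  # half-away-from-zero at one decimal
    n: int


def group_medians(groups: Mapping[str, Sequence[float]]) -> dict[str, GroupMedian]:
    """Median per group: raw value plus the one-decimal reported value.

    Standard median (mean of the central pair for even n).
    """
    out: dict[str, GroupMedian] = {}
    for label, values in groups.items():
        if len(values) == 0:
            raise ValidationError(f"group {label!r} is empty")
        raw = float(np.median(np.asarray(values, dtype=float)))
        out[label] = GroupMedian(raw=raw, reported=round_half_away(raw, 1), n=len(values))
    return out


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_two_sided: float
    method: str  # "exact", "asymptotic", or "permutation"


def _has_ties(a: Sequence[float], b: Sequence[float]) -> bool:
    pooled = list(a) + list(b)
    return len(set(pooled)) < len(pooled)


def _u_statistic(ranks: np.ndarray, idx_a: Sequence[int], n_a: int, n_b: int) -> float:
    r_a = float(ranks[list(idx_a)].sum())
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney(a: Sequence[float], b: Sequence[float], method: str = "auto") -> MannWhitneyResult:
    """Mann–Whitney U test, two-sided.

    ``method='auto'`` uses the exact U distribution when min(n_a, n_b) ≤ 8 and
    there are no ties, and the normal approximation with tie correction (and
    continuity correction, matching R's ``wilcox.test`` default) otherwise.
    ``method='permutation'`` enumerates all C(n, n_a) label assignments with
    midranks, which also handles ties exactly for small samples.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        raise ValidationError("both groups must be nonempty")
    if method == "auto":
        method = "exact" if (min(len(a), len(b)) <= 8 and not _has_ties(a, b)) else "asymptotic"
    if method in {"exact", "asymptotic"}:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
        return MannWhitneyResult(u=float(res.statistic), p_two_sided=float(res.pvalue), method=method)
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")

    n_a, n_b = len(a), len(b)
    pooled = np.asarray(a + b)
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = _u_statistic(ranks, range(n_a), n_a, n_b)
    mu = n_a * n_b / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        u = _u_statistic(ranks, idx, n_a, n_b)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return MannWhitneyResult(u=u_obs, p_two_sided=count / total, method="permutation")


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    p: float
    df: int


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal–Wallis H with tie correction; chi-square p on k − 1 df.

    Requires ≥ 3 groups — for two groups use :func:`mann_whitney`.  All values
    identical across groups gives H = 0 (no rank variation), p = 1.
    """
    if len(groups) < 3:
        raise ValidationError("kruskal_wallis needs >= 3 groups; use mann_whitney for two")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValidationError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(h=0.0, p=1.0, df=len(groups) - 1)
    h, p = stats.kruskal(*arrays)
    return KruskalWallisResult(h=float(h), p=float(p), df=len(groups) - 1)
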