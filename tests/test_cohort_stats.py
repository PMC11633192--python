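"""Medians and nonparametric tests, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from n2oiso.cohort_stats import (
    group_medians,
    kruskal_wallis,
    mann_whitney,
    round_half_away,
)
from n2oiso.datasets import substrate_sp_groups
from n2oiso.errors import ValidationError


# ---------------------------------------------------------------- oracles

def brute_force_mw_p(a, b):
    """Two-sided permutation p for the Mann-Whitney U over all labelings."""
    pooled = list(a) + list(b)
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    mu = n_a * len(b) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    assignments = list(itertools.combinations(range(len(pooled)), n_a))
    count = sum(1 for idx in assignments if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12)
    return count / len(assignments)


def brute_force_kw_p(groups):
    """Permutation null of the Kruskal-Wallis H over all group assignments."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    h_obs = sps.kruskal(*groups).statistic
    count = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        start = 0
        regrouped = []
        for s in sizes:
            regrouped.append(pooled[list(perm[start : start + s])])
            start += s
        h = sps.kruskal(*regrouped).statistic
        if h >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------- medians

def test_substrate_medians_of_nitrate_ammonifying_strains():
    """The five dual-substrate strains give SP medians 46.2 (NO2) and 46.4 (NO3)."""
    groups = substrate_sp_groups()
    assert {k: len(v) for k, v in groups.items()} == {"NO2": 10, "NO3": 10}
    med = group_medians(groups)
    assert med["NO2"].reported == 46.2
    assert med["NO3"].raw == pytest.approx(46.35)
    assert med["NO3"].reported == 46.4  # half-away-from-zero at one decimal


def test_single_value_median_and_empty_group():
    med = group_medians({"g": [41.9]})
    assert med["g"].raw == med["g"].reported == 41.9
    with pytest.raises(ValidationError):
        group_medians({"g": []})


@pytest.mark.parametrize(
    "x, expected", [(46.35, 46.4), (-46.35, -46.4), (46.34, 46.3), (0.05, 0.1), (-0.05, -0.1)]
)
def test_round_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


def test_medians_invariant_under_group_permutation():
    g = {"a": [3.0, 1.0, 2.0], "b": [5.0, 4.0]}
    g2 = {"b": [4.0, 5.0], "a": [1.0, 2.0, 3.0]}
    assert group_medians(g) == group_medians(g2)


# ------------------------------------------------------------ mann-whitney

def test_mw_exact_small_case():
    res = mann_whitney([1, 2], [3, 4])
    assert res.method == "exact"
    assert res.u == 0.0
    assert res.p_two_sided == pytest.approx(2 / 6)


def test_mw_identical_multisets_permutation_p_is_one():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="permutation")
    assert res.p_two_sided == 1.0


@pytest.mark.parametrize(
    "a, b",
    [
        ([1, 2], [3, 4]),
        ([1.5, 2.5, 9.0], [0.5, 3.5]),
        ([1, 1, 2], [2, 3, 3]),  # ties -> midranks
        ([5, 6, 7, 8], [1, 2, 3]),
        ([0.1, 0.2, 0.3, 0.4, 0.5], [0.15, 0.25, 0.35, 0.45, 0.55]),
    ],
)
def test_mw_permutation_matches_brute_force(a, b):
    res = mann_whitney(a, b, method="permutation")
    assert res.p_two_sided == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)


def test_mw_exact_matches_brute_force_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(5):
        a = list(rng.permutation(20)[:4].astype(float))
        b = list(set(rng.permutation(40)[:5].astype(float)) - set(a))[:4]
        res = mann_whitney(a, b)  # auto -> exact (no ties, small n)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(brute_force_mw_p(a, b), abs=1e-9)


def test_mw_substrate_sp_groups_not_significant():
    """NO2- vs NO3-derived SP values are statistically indistinguishable."""
    groups = substrate_sp_groups()
    res = mann_whitney(groups["NO2"], groups["NO3"])
    assert res.p_two_sided > 0.05


def test_mw_empty_group_rejected():
    with pytest.raises(ValidationError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------- kruskal-wallis

def test_kw_identical_constants_give_zero():
    res = kruskal_wallis([[5.0, 5.0], [5.0], [5.0, 5.0]])
    assert res.h == 0.0 and res.p == 1.0


def test_kw_hand_rank_oracle():
    """{1,2},{3,4},{5,6}: H = 12/42 * (9+49+121)/2 - 21 = 32/7."""
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.h == pytest.approx(32 / 7, abs=1e-12)
    assert res.df == 2


def test_kw_needs_three_groups():
    with pytest.raises(ValidationError, match="mann_whitney"):
        kruskal_wallis([[1, 2], [3, 4]])


def test_kw_chi_square_p_close_to_permutation_null():
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    res = kruskal_wallis(groups)
    assert res.p == pytest.approx(brute_force_kw_p(groups), abs=0.1)
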