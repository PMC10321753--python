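"""Unit and property tests for the rank-statistics kernel.

Expected values come from hand computation, brute-force enumeration, or
independent library implementations (scipy.stats, statsmodels, lifelines)
used strictly as cross-checks.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nrscreen as nr
from nrscreen.exceptions import DegenerateStatisticsWarning

finite_floats = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


# ---------------------------------------------------------------- ranks

@pytest.mark.parametrize(
    "values, expected",
    [
        ([10, 20, 30], [1, 2, 3]),
        ([5, 5, 10], [1.5, 1.5, 3]),
        ([7, 7, 7, 7], [2.5, 2.5, 2.5, 2.5]),
        ([3, 1, 2], [3, 1, 2]),
        ([2, 1, 2, 1], [3.5, 1.5, 3.5, 1.5]),
    ],
)
def test_average_ranks_examples(values, expected):
    assert nr.average_ranks(values) == pytest.approx(expected)


def test_average_ranks_rejects_bad_input():
    with pytest.raises(ValueError):
        nr.average_ranks([])
    with pytest.raises(ValueError):
        nr.average_ranks([1.0, np.nan])


@settings(derandomize=True, max_examples=100)
@given(st.lists(finite_floats, min_size=1, max_size=40))
def test_rank_sum_invariant(values):
    n = len(values)
    assert nr.average_ranks(values).sum() == pytest.approx(n * (n + 1) / 2)


@pytest.mark.parametrize(
    "values, expected",
    [
        ([10, 20, 30, 40], [0.25, 0.50, 0.75, 1.00]),
        ([5, 5, 10], [0.5, 0.5, 1.0]),
    ],
)
def test_rank_percentile_examples(values, expected):
    assert nr.rank_percentile(values) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(finite_floats, min_size=2, max_size=30),
    st.sampled_from(["exp", "cube_shift", "affine"]),
)
def test_rank_percentile_monotone_invariance(values, transform):
    """Percentiles depend only on the ordering, so any strictly increasing
    map leaves them bit-identical (ties map to ties)."""
    from hypothesis import assume

    x = np.asarray(values)
    if transform == "exp":
        y = np.exp(x / (1 + np.abs(x).max()))  # rescale to avoid overflow
    elif transform == "cube_shift":
        y = x**3 + 2.0
    else:
        y = 3.5 * x + 1.0
    # float rounding can merge close values, breaking strict monotonicity of
    # the map itself; only ordering-faithful transforms are in scope
    assume(np.array_equal(np.sign(np.subtract.outer(x, x)),
                          np.sign(np.subtract.outer(y, y))))
    assert np.array_equal(nr.rank_percentile(x), nr.rank_percentile(y))


# ------------------------------------------------------------- spearman

def test_spearman_perfect_discordance():
    rho, _ = nr.spearman([1, 2, 3], [3, 2, 1])
    assert rho == pytest.approx(-1.0)


def test_spearman_derived_example():
    # Sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
    rho, _ = nr.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert rho == pytest.approx(0.8)


def test_spearman_exact_permutation_small():
    _, p = nr.spearman([1, 2, 3], [3, 2, 1], p_method="exact_permutation")
    assert p == pytest.approx(1 / 3)


def test_spearman_exact_cap_enforced():
    x = list(range(9))
    with pytest.raises(ValueError, match="cap"):
        nr.spearman(x, x[::-1], p_method="exact_permutation", exact_cap=8)


def test_spearman_rejects_constant_and_mismatch():
    with pytest.raises(ValueError):
        nr.spearman([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        nr.spearman([1, 2, 3], [1, 2])


def test_spearman_matches_scipy(rng):
    from scipy import stats

    for _ in range(25):
        n = int(rng.integers(5, 60))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n) + 0.5 * x
        rho, p = nr.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


# ------------------------------------------------------------- wilcoxon

def test_wilcoxon_exact_separated_groups():
    # 2 of the C(6,3)=20 assignments are as extreme as full separation
    _, p = nr.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_wilcoxon_identical_multisets():
    _, p = nr.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_wilcoxon_group_swap_symmetry(rng):
    a = rng.standard_normal(20)
    b = rng.standard_normal(25) + 0.4
    _, p_ab = nr.wilcoxon_rank_sum(a, b)
    _, p_ba = nr.wilcoxon_rank_sum(b, a)
    assert p_ab == pytest.approx(p_ba)


def test_wilcoxon_matches_scipy_large(rng):
    from scipy import stats

    a = rng.standard_normal(30)
    b = rng.standard_normal(40) + 0.5
    _, p = nr.wilcoxon_rank_sum(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_wilcoxon_rejects_empty():
    with pytest.raises(ValueError):
        nr.wilcoxon_rank_sum([], [1.0])


# ------------------------------------------------------------------ BH

def test_bh_examples():
    assert nr.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert nr.bh_adjust([0.5]) == pytest.approx([0.5])


def test_bh_never_decreases_and_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 50)))
        adj = nr.bh_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert adj == pytest.approx(ref, abs=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        nr.bh_adjust([0.2, 1.2])


# ------------------------------------------------------------------ KM

def test_km_no_censoring_equals_one_minus_ecdf():
    curve = nr.km_curve([1, 2, 3], [1, 1, 1])
    assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])


def test_km_hand_product_limit_with_censoring():
    # risk sets 3, 1 at event times 1 and 3; censor at 2
    curve = nr.km_curve([1, 2, 3], [1, 0, 1])
    assert curve.event_times == pytest.approx([1, 3])
    assert curve.survival == pytest.approx([2 / 3, 0.0])


def test_km_all_censored():
    curve = nr.km_curve([1, 2, 3], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.survival_at(10.0) == 1.0


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValueError):
        nr.km_curve([0.0, 1.0], [1, 1])


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = np.round(rng.exponential(2.0, size=80), 3) + 1e-3
    e = (rng.uniform(size=80) > 0.25).astype(int)
    curve = nr.km_curve(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for te, s in zip(curve.event_times, curve.survival):
        assert s == pytest.approx(
            float(kmf.survival_function_at_times(te).iloc[0]), abs=1e-10
        )


def test_km_median_and_restricted_mean():
    curve = nr.km_curve([1, 2, 3, 4], [1, 1, 1, 1])
    assert curve.median() == 2.0  # S(2) = 0.5
    # step integral on [0,4]: 1*1 + 0.75*1 + 0.5*1 + 0.25*1
    assert curve.restricted_mean(4.0) == pytest.approx(2.5)


# ------------------------------------------------------------- logrank

def test_logrank_identical_groups_null():
    t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    e = [1, 1, 1, 1, 1, 1]
    g = ["A", "A", "A", "B", "B", "B"]
    res = nr.logrank(t, e, g)
    assert res.chi2 == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_logrank_hand_computed_example():
    # group A events at {1,2}, B at {3,4}: O-E = 7/6, V = 17/36 -> chi2 = 49/17
    res = nr.logrank([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert res.chi2 == pytest.approx(49 / 17, rel=1e-12)
    assert res.direction == "A"


def test_logrank_label_swap_invariance(rng):
    t = rng.exponential(1.0, size=40) + 0.01
    e = (rng.uniform(size=40) > 0.2).astype(int)
    g = rng.integers(0, 2, size=40)
    r1 = nr.logrank(t, e, g)
    r2 = nr.logrank(t, e, 1 - g)
    assert r1.chi2 == pytest.approx(r2.chi2)
    assert r1.p == pytest.approx(r2.p)


def test_logrank_zero_variance_warns():
    # the only event time has every at-risk subject in one group
    with pytest.warns(DegenerateStatisticsWarning):
        res = nr.logrank([5.0, 1.0, 2.0], [1, 0, 0], ["A", "B", "B"])
    assert res.p == 1.0


def test_logrank_rejects_single_group():
    with pytest.raises(ValueError):
        nr.logrank([1, 2], [1, 1], ["A", "A"])


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test

    for _ in range(10):
        n = int(rng.integers(20, 60))
        t = np.round(rng.exponential(1.0, size=n), 2) + 0.01
        e = (rng.uniform(size=n) > 0.3).astype(int)
        g = rng.integers(0, 2, size=n)
        if e.sum() == 0 or len(set(g.tolist())) < 2:
            continue
        mine = nr.logrank(t, e, g)
        if mine.variance <= 0:
            continue
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert mine.chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.p_value, abs=1e-10)


def test_spearman_exact_agrees_with_bruteforce_small(rng):
    """Exact-permutation p equals plain-python full enumeration (with ties)."""
    for _ in range(20):
        n = int(rng.integers(3, 7))
        x = rng.integers(0, 4, size=n).astype(float)
        y = rng.integers(0, 4, size=n).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        rho, p = nr.spearman(x, y, p_method="exact_permutation")
        rx = nr.average_ranks(x) - nr.average_ranks(x).mean()
        ry = nr.average_ranks(y) - nr.average_ranks(y).mean()
        obs = abs(sum(a * b for a, b in zip(rx, ry)))
        hits = sum(
            1
            for perm in itertools.permutations(ry)
            if abs(sum(a * b for a, b in zip(rx, perm))) >= obs - 1e-12
        )
        assert p == hits / math.factorial(n)
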