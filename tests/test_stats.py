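"""Exact statistics verified against brute-force enumeration oracles."""

import math
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps

from subtype_suite.stats_core import (bh_fdr, fisher_exact_2x2, mann_whitney_u,
                                      one_sample_prop_test, perm_pvalue,
                                      perm_pvalues_welch, welch_t,
                                      wilcoxon_signed_rank)

# ---------------------------------------------------------------------------
# independent enumeration oracles


def fisher_oracle(table):
    """Sum hypergeometric probabilities <= P(observed), by full enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = sps.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def mwu_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
        return gt

    u_obs = u_of(range(n1))
    mu = n1 * (len(pooled) - n1) / 2
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        hits += abs(u_of(idx) - mu) >= dev_obs - 1e-9
    return hits / total


def signed_rank_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    dev_obs = abs(w_obs - mu)
    hits = total = 0
    for signs in product([1, -1], repeat=len(d)):
        w = ranks[np.array(signs) > 0].sum()
        total += 1
        hits += abs(w - mu) >= dev_obs - 1e-9
    return hits / total


def bh_oracle(p):
    """Literal step-up rule: q_i = min over j with p_(j) >= p_(i) of m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def perm_oracle(data, labels):
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == labels[0]).sum())
    idx_obs = tuple(np.flatnonzero(labels == labels[0]))
    t_obs = welch_t(data[list(idx_obs)], np.delete(data, list(idx_obs)))
    hits = total = 0
    for idx in combinations(range(data.size), n1):
        t = welch_t(data[list(idx)], np.delete(data, list(idx)))
        total += 1
        hits += abs(t) >= abs(t_obs) - 1e-12
    return hits / total


# ---------------------------------------------------------------------------
# worked examples


def test_fisher_worked_example():
    res = fisher_exact_2x2([[3, 1], [1, 3]])
    assert res.p_value == pytest.approx(34 / 70, abs=1e-12)


def test_fisher_symmetry_and_zero_margin():
    p1 = fisher_exact_2x2([[0, 5], [5, 0]]).p_value
    p2 = fisher_exact_2x2([[5, 0], [0, 5]]).p_value
    assert p1 == pytest.approx(p2)
    assert fisher_exact_2x2([[0, 0], [3, 4]]).p_value == pytest.approx(1.0)


def test_mann_whitney_worked_example():
    assert mann_whitney_u([1, 2], [3, 4]).p_value == pytest.approx(2 / 6)


def test_mann_whitney_identical_and_symmetric():
    x = [1.0, 2.0, 3.0]
    assert mann_whitney_u(x, x, mode="exact").p_value == pytest.approx(1.0)
    a, b = [1, 5, 9], [2, 3, 8]
    assert mann_whitney_u(a, b).p_value == pytest.approx(mann_whitney_u(b, a).p_value)


def test_signed_rank_worked_example():
    res = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
    assert res.p_value == pytest.approx(0.25)


def test_signed_rank_antisymmetry_and_n1():
    p_pos = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3]).p_value
    p_neg = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0]).p_value
    assert p_pos == pytest.approx(p_neg)
    assert wilcoxon_signed_rank([0], [2]).p_value == pytest.approx(1.0)


def test_signed_rank_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        wilcoxon_signed_rank([1, 2], [1, 2])


def test_proportions_worked_example():
    res = one_sample_prop_test(14, 16, 0.5)
    assert res.statistic == pytest.approx(7.5625)
    assert res.p_value == pytest.approx(0.0060, abs=5e-4)
    assert one_sample_prop_test(14, 16, 0.5, continuity=False).statistic == \
        pytest.approx(9.0)


def test_proportions_at_null_value():
    assert one_sample_prop_test(8, 16, 0.5).p_value == pytest.approx(1.0)


def test_perm_pvalue_worked_example():
    res = perm_pvalue(welch_t, [1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
    assert res.p_value == pytest.approx(2 / 20)
    assert res.method == "permutation (exhaustive)"


def test_perm_pvalue_identical_groups_and_seeded():
    res = perm_pvalue(welch_t, [1, 2, 1, 2], [0, 1, 0, 1])
    assert res.p_value == pytest.approx(1.0)
    big = np.arange(24.0)
    labels = np.repeat([0, 1], 12)
    p1 = perm_pvalue(welch_t, big, labels, n_perm=99, seed=5,
                     exhaustive_when_feasible=False).p_value
    p2 = perm_pvalue(welch_t, big, labels, n_perm=99, seed=5,
                     exhaustive_when_feasible=False).p_value
    assert p1 == p2


def test_bh_worked_examples():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]),
                               [0.04, 0.04, 0.04, 0.5])
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_fdr([0.7]), [0.7])


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_fdr([0.1, float("nan")])


# ---------------------------------------------------------------------------
# enumeration-oracle property tests (random small instances)


@pytest.mark.parametrize("case", range(40))
def test_fisher_matches_enumeration(case):
    rng = np.random.default_rng(1000 + case)
    table = rng.integers(0, 7, size=(2, 2))
    assert fisher_exact_2x2(table).p_value == pytest.approx(
        fisher_oracle(table), abs=1e-9)


@pytest.mark.parametrize("case", range(40))
def test_mann_whitney_matches_enumeration(case):
    rng = np.random.default_rng(2000 + case)
    n1, n2 = rng.integers(2, 6, size=2)
    pool = rng.permutation(20)[: n1 + n2].astype(float)  # distinct -> no ties
    x, y = pool[:n1], pool[n1:]
    assert mann_whitney_u(x, y, mode="exact").p_value == pytest.approx(
        mwu_oracle(x, y), abs=1e-9)


@pytest.mark.parametrize("case", range(40))
def test_signed_rank_matches_enumeration(case):
    rng = np.random.default_rng(3000 + case)
    n = int(rng.integers(2, 9))
    mags = rng.permutation(np.arange(1, 20))[:n].astype(float)  # distinct ranks
    diffs = mags * rng.choice([-1, 1], size=n)
    assert wilcoxon_signed_rank(np.zeros(n), diffs, mode="exact").p_value == \
        pytest.approx(signed_rank_oracle(diffs), abs=1e-9)


@pytest.mark.parametrize("case", range(40))
def test_bh_matches_step_up_oracle(case):
    rng = np.random.default_rng(4000 + case)
    p = rng.uniform(size=int(rng.integers(1, 12)))
    np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


@pytest.mark.parametrize("case", range(40))
def test_prop_test_matches_hand_formula(case):
    rng = np.random.default_rng(5000 + case)
    n = int(rng.integers(1, 50))
    x = int(rng.integers(0, n + 1))
    p0 = float(rng.uniform(0.1, 0.9))
    dev = max(abs(x - n * p0) - 0.5, 0.0)
    chi2 = dev**2 / (n * p0 * (1 - p0))
    res = one_sample_prop_test(x, n, p0)
    assert res.statistic == pytest.approx(chi2, abs=1e-12)
    assert res.p_value == pytest.approx(float(sps.chi2.sf(chi2, 1)), abs=1e-12)


@pytest.mark.parametrize("case", range(20))
def test_perm_pvalue_matches_enumeration(case):
    rng = np.random.default_rng(6000 + case)
    n1, n2 = rng.integers(2, 5, size=2)
    data = rng.normal(size=n1 + n2)
    labels = np.repeat([0, 1], [n1, n2])
    assert perm_pvalue(welch_t, data, labels).p_value == pytest.approx(
        perm_oracle(data, labels), abs=1e-12)


@pytest.mark.parametrize("case", range(10))
def test_vectorized_welch_permutation_equals_per_gene_route(case):
    rng = np.random.default_rng(7000 + case)
    values = rng.normal(size=(6, 8))
    labels = np.repeat([0, 1], 4)
    _, p_vec = perm_pvalues_welch(values, labels)
    for g in range(values.shape[0]):
        p_single = perm_pvalue(welch_t, values[g], labels).p_value
        assert p_vec[g] == pytest.approx(p_single, abs=1e-12)


# ---------------------------------------------------------------------------
# invariants


def test_bh_monotone_in_sorted_order_and_permutation_invariant():
    rng = np.random.default_rng(8)
    p = rng.uniform(size=25)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    perm = rng.permutation(25)
    np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])


@pytest.mark.parametrize("test_name", ["mwu", "signed_rank", "perm"])
def test_null_rejection_rate_calibrated(test_name):
    """Type-I error at alpha=0.05 within the binomial 99% CI under the null."""
    rng = np.random.default_rng(99)
    n_rep = 1000
    alpha = 0.05
    rejections = 0
    for _ in range(n_rep):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        if test_name == "mwu":
            p = mann_whitney_u(x, y).p_value
        elif test_name == "signed_rank":
            p = wilcoxon_signed_rank(x, y).p_value
        else:
            p = perm_pvalue(welch_t, np.concatenate([x, y[:2]]),
                            np.repeat([0, 1], [8, 2])).p_value
        rejections += p <= alpha
    lo, hi = sps.binom.interval(0.99, n_rep, alpha)
    # exact discrete tests are conservative; only the upper bound is strict
    assert rejections <= hi
    assert rejections >= lo - 25
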