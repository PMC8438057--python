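"""Small-sample statistical primitives shared by every pipeline stage.

Each test returns a :class:`TestResult` and is two-sided unless stated.
Exact modes are used automatically at small sample sizes where the exact
null is available (no ties), mirroring common statistical practice; the
asymptotic fallbacks use tie and continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXHAUSTIVE_LIMIT = 20_000  # permutation arrangements below this are enumerated


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str = "two-sided"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) or math.isnan(self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not self.method:
            raise ValueError("method string must be set")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities not exceeding that of
    the observed table (with a small relative tolerance in the comparison).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts in contingency table")
    if not np.array_equal(t, t.astype(int)):
        raise ValueError("non-integer counts in contingency table")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return TestResult(float(odds), float(min(p, 1.0)), "fisher-exact")


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``auto`` uses the exact null when n_x + n_y <= 20 and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group in Mann–Whitney test")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not has_ties) else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"mann-whitney-u ({mode})")


def wilcoxon_signed_rank(pre, post, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped (Wilcoxon's convention). ``auto`` uses
    exact enumeration of the 2^n sign assignments when n <= 15 (midranks
    for tied magnitudes), otherwise the normal approximation.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: all paired differences are zero")
    if mode == "auto":
        mode = "exact" if d.size <= 15 else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "exact":
        n = d.size
        mu = ranks.sum() / 2.0
        dev_obs = abs(w_plus - mu)
        # all 2^n sign assignments, vectorized over the bit patterns
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = bits @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= dev_obs - 1e-12))
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="approx")
        p = float(res.pvalue)
    return TestResult(w_plus, min(p, 1.0), f"wilcoxon-signed-rank ({mode})",
                      extras={"n_nonzero": int(d.size)})


def one_sample_prop_test(x: int, n: int, p0: float, continuity: bool = True) -> TestResult:
    """One-sample proportions chi-square test with optional continuity correction.

    chi2 = (|x - n p0| - 0.5)^2 / (n p0 (1 - p0)), the correction clipped at
    zero; p from the upper tail of chi-square with 1 df.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= x <= n):
        raise ValueError("x must lie in [0, n]")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    dev = abs(x - n * p0)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    chi2 = dev**2 / (n * p0 * (1 - p0))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), min(p, 1.0),
                      "one-sample-proportions"
                      + (" (continuity-corrected)" if continuity else ""))


def _group_indices(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"permutation test needs exactly 2 label values, got {uniq.size}")
    g1 = np.flatnonzero(labels == uniq[0])
    g2 = np.flatnonzero(labels == uniq[1])
    if g1.size == 0 or g2.size == 0:
        raise ValueError("empty group in permutation test")
    return g1, g2


def perm_pvalue(stat_fn, data, labels, n_perm: int = 999, seed: int | None = None,
                exhaustive_when_feasible: bool = True) -> TestResult:
    """Two-sided label-permutation p-value for a two-group statistic.

    ``stat_fn(x, y)`` returns a scalar. When the number of distinct label
    arrangements is at most 20,000 (and enumeration is enabled) the p-value
    is the exact fraction of arrangements with ``|T| >= |T_obs|``; otherwise
    it is the add-one estimate ``(1 + hits) / (1 + n_perm)`` over sampled
    permutations.
    """
    data = np.asarray(data, dtype=float)
    g1, g2 = _group_indices(labels)
    n, n1 = data.size, g1.size
    t_obs = float(stat_fn(data[g1], data[g2]))
    thresh = abs(t_obs) - 1e-12
    n_arrangements = math.comb(n, n1)
    if exhaustive_when_feasible and n_arrangements <= EXHAUSTIVE_LIMIT:
        hits = 0
        all_idx = frozenset(range(n))
        for comb in combinations(range(n), n1):
            idx1 = np.fromiter(comb, dtype=int)
            idx2 = np.fromiter(all_idx.difference(comb), dtype=int)
            if abs(float(stat_fn(data[idx1], data[idx2]))) >= thresh:
                hits += 1
        p = hits / n_arrangements
        return TestResult(t_obs, min(p, 1.0), "permutation (exhaustive)",
                          extras={"n_arrangements": n_arrangements})
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        if abs(float(stat_fn(data[perm[:n1]], data[perm[n1:]]))) >= thresh:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(t_obs, min(p, 1.0), "permutation (sampled)",
                      extras={"n_perm": n_perm})


def welch_t(x, y) -> float:
    """Unequal-variance two-sample t statistic (mean(x) - mean(y) direction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v1 = x.var(ddof=1) if x.size > 1 else 0.0
    v2 = y.var(ddof=1) if y.size > 1 else 0.0
    denom = math.sqrt(v1 / x.size + v2 / y.size)
    if denom == 0.0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def _welch_t_matrix(values: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """Row-wise Welch t over a features x samples matrix, vectorized."""
    x = values[:, idx1]
    y = values[:, idx2]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1) if idx1.size > 1 else np.zeros(values.shape[0])
    v2 = y.var(axis=1, ddof=1) if idx2.size > 1 else np.zeros(values.shape[0])
    denom = np.sqrt(v1 / idx1.size + v2 / idx2.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom == 0.0, 0.0, t)


def perm_pvalues_welch(values, labels, n_perm: int = 999, seed: int | None = None,
                       exhaustive_when_feasible: bool = True):
    """Row-wise Welch-t permutation p-values for a features x samples matrix.

    Shares perm_pvalue's conventions (exhaustive exact fraction below the
    enumeration limit, add-one estimator otherwise) but evaluates the
    statistic for all features per permutation at once.

    Returns ``(t_obs, p)`` arrays aligned to the rows of ``values``.
    """
    values = np.asarray(values, dtype=float)
    g1, g2 = _group_indices(labels)
    n, n1 = values.shape[1], g1.size
    order = np.concatenate([g1, g2])
    t_obs = _welch_t_matrix(values, g1, g2)
    thresh = np.abs(t_obs) - 1e-12
    n_arrangements = math.comb(n, n1)
    if exhaustive_when_feasible and n_arrangements <= EXHAUSTIVE_LIMIT:
        hits = np.zeros(values.shape[0], dtype=int)
        all_idx = frozenset(range(n))
        for comb in combinations(range(n), n1):
            idx1 = np.fromiter(comb, dtype=int)
            idx2 = np.fromiter(all_idx.difference(comb), dtype=int)
            t_perm = _welch_t_matrix(values, idx1, idx2)
            hits += np.abs(t_perm) >= thresh
        return t_obs, np.minimum(hits / n_arrangements, 1.0)
    rng = np.random.default_rng(seed)
    hits = np.zeros(values.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(order)
        t_perm = _welch_t_matrix(values, perm[:n1], perm[n1:])
        hits += np.abs(t_perm) >= thresh
    return t_obs, np.minimum((1 + hits) / (1 + n_perm), 1.0)
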