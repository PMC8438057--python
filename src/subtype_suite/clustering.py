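"""Variance filtering, resampling consensus clustering and k selection.

Subtype discovery follows the resampling consensus scheme: repeatedly
subsample the cohort, cluster each subsample by agglomerative clustering on
Pearson correlation distance (1 - r), and record how often each pair of
samples lands in the same cluster among the iterations that drew both. The
per-k consensus matrices yield the CDF-area curve A(k) and its relative
increments (the delta-area profile) used to choose the number of clusters;
the choice is reported, never silently enforced, because in practice it is
combined with clinical and biological information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io_core import AnalyteMatrix

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete")


def variance_filter(matrix: AnalyteMatrix, sd_threshold: float = 0.5) -> AnalyteMatrix:
    """Keep features whose across-sample SD (n-1 denominator) exceeds the threshold.

    Strict inequality: a feature at exactly the threshold is dropped.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    keep = sd > sd_threshold
    if not keep.any():
        raise ValueError("empty matrix: every feature filtered out")
    return AnalyteMatrix(matrix.data.loc[keep])


def pearson_distance_matrix(profiles: np.ndarray, ids=None) -> np.ndarray:
    """1 - Pearson r between rows; errors on any zero-variance row."""
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        i = int(np.argmax(sd == 0))
        name = ids[i] if ids is not None else f"row {i}"
        raise ValueError(f"constant profile (Pearson undefined): {name}")
    d = 1.0 - np.corrcoef(profiles)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hierarchical_cluster(profiles: np.ndarray, linkage: str = "average",
                         k: int | None = None, height: float | None = None,
                         ids=None):
    """Agglomerative clustering of row profiles under Pearson distance.

    Returns ``(labels, Z)`` where ``Z`` is the scipy linkage matrix. Exactly
    one of ``k`` or ``height`` selects the cut.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    d = pearson_distance_matrix(profiles, ids)
    Z = scipy_linkage(squareform(d, checks=False), method=linkage)
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = fcluster(Z, t=height, criterion="distance")
    return labels.astype(int), Z


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]          # per k: n x n matrix in [0, 1]
    assignments: dict[int, np.ndarray]        # per k: labels 1..k
    areas: dict[int, float]                   # A(k)
    delta_areas: dict[int, float]             # delta(k)
    stability: dict[int, np.ndarray]          # per k: mean within-cluster consensus
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class KSelection:
    selected_k: int
    no_structure: bool
    epsilon: float
    areas: dict[int, float]
    delta_areas: dict[int, float]
    min_stability: dict[int, float] = field(default_factory=dict)


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries (Monti's A(k))."""
    xs, counts = np.unique(values, return_counts=True)
    if xs.size == 1:
        return 0.0
    cdf = np.cumsum(counts) / values.size
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_cluster(matrix: AnalyteMatrix, k_range=range(2, 11),
                      iterations: int = 1000, subsample_frac: float = 0.8,
                      inner_linkage: str = "average",
                      final_linkage: str = "complete",
                      seed: int | None = None) -> ConsensusResult:
    """Resampling consensus clustering over a range of cluster counts.

    Per iteration a fraction of samples is drawn without replacement and
    clustered agglomeratively (Pearson distance); one linkage tree per
    iteration serves every k. consensus_k(i, j) = co-cluster count /
    co-sample count. The final per-k assignment cuts an agglomerative tree
    built on 1 - consensus.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = matrix.shape[1]
    if min(ks) < 2:
        raise ValueError("k must be at least 2")
    if n < max(ks) + 1:
        raise ValueError(f"need more than {max(ks)} samples for k up to {max(ks)}")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    profiles = matrix.values.T  # samples x features
    m = max(2, int(round(subsample_frac * n)))

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    n_used = 0
    for _ in range(iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        try:
            d = pearson_distance_matrix(profiles[idx])
        except ValueError as exc:
            logger.warning("iteration skipped: %s", exc)
            continue
        Z = scipy_linkage(squareform(d, checks=False), method=inner_linkage)
        co_sampled[np.ix_(idx, idx)] += 1
        any_k = False
        for k in ks:
            if m < k:
                logger.warning("subsample of %d too small for k=%d; skipped", m, k)
                continue
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
            any_k = True
        if any_k:
            n_used += 1
    if n_used == 0:
        raise ValueError("all consensus iterations were skipped")

    consensus, assignments, areas, stability = {}, {}, {}, {}
    never = co_sampled == 0
    if never[np.triu_indices(n, k=1)].any():
        logger.warning("some sample pairs were never co-sampled; consensus set to 0")
    for k in ks:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(never, 0.0, co_clustered[k] / np.maximum(co_sampled, 1))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        consensus[k] = c
        final_labels, _ = _cut_consensus(c, k, final_linkage)
        assignments[k] = final_labels
        areas[k] = _cdf_area(c[np.triu_indices(n, k=1)])
        stability[k] = _cluster_stability(c, final_labels, k)

    delta_areas = {}
    prev = None
    for k in ks:
        if prev is None:
            delta_areas[k] = areas[k]
        else:
            if areas[k] < areas[prev] - 1e-9:
                raise ValueError(
                    f"A(k) decreased from k={prev} ({areas[prev]:.6f}) to "
                    f"k={k} ({areas[k]:.6f}): consensus matrices are inconsistent"
                )
            delta_areas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k

    return ConsensusResult(ks, consensus, assignments, areas, delta_areas,
                           stability, list(matrix.sample_ids))


def _cut_consensus(consensus: np.ndarray, k: int, linkage: str):
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    Z = scipy_linkage(squareform(d, checks=False), method=linkage)
    return fcluster(Z, t=k, criterion="maxclust").astype(int), Z

def _cluster_stability(consensus: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    out = np.ones(k)
    for c in range(1, k + 1):
        members = np.flatnonzero(labels == c)
        if members.size > 1:
            sub = consensus[np.ix_(members, members)]
            out[c - 1] = sub[np.triu_indices(members.size, k=1)].mean()
    return out


def select_k(result: ConsensusResult, epsilon: float = 0.03,
             stability_floor: float = 0.8) -> KSelection:
    """Choose k from the delta-area profile combined with cluster stability.

    A cluster count (beyond the smallest evaluated) counts as evidence of
    structure when its relative CDF-area increment is >= epsilon (the first
    k's delta is A(k) itself) AND its least-stable cluster keeps a mean
    within-cluster consensus >= stability_floor; resampled noise inflates
    the raw area increments, so the delta profile alone cannot separate
    genuine structure from a null cohort. The largest such k is the elbow,
    a lower bound only: the area increment from resolving a cluster holding
    a few percent of samples is quadratically small in its size, so among
    k at or above the elbow the k with the highest minimum per-cluster
    stability (smallest k on ties) is selected. When no k qualifies the
    data carry no detectable structure beyond the smallest k: selection
    falls back to it with the ``no_structure`` flag. The full delta and
    stability profiles are part of the report so the caller can override
    the choice with external (e.g. clinical) information.
    """
    ks = result.k_range
    if len(ks) < 3:
        raise ValueError("need at least 3 k values to select k")
    min_stab = {k: float(result.stability[k].min()) for k in ks}
    qualifying = [k for k in ks[1:]
                  if result.delta_areas[k] >= epsilon
                  and min_stab[k] >= stability_floor]
    no_structure = not qualifying
    if no_structure:
        selected = ks[0]
    else:
        k_elbow = max(qualifying)
        candidates = [k for k in ks if k >= k_elbow]
        best = max(min_stab[k] for k in candidates)
        selected = min(k for k in candidates if min_stab[k] >= best - 1e-12)
    return KSelection(selected, no_structure, epsilon,
                      dict(result.areas), dict(result.delta_areas), min_stab)
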