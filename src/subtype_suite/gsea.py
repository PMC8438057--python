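"""Per-gene class comparison and gene-set enrichment analysis.

The enrichment statistic is the weighted Kolmogorov–Smirnov running sum:
walking down the ranked gene list, genes in the set increment the sum by
|score|^weight (normalized over the set's hits), genes outside decrement it
by 1/(N - N_hits); the enrichment score ES is the signed maximum deviation.
NES normalizes ES by the mean |null ES| of matching sign, and the FDR uses
the sign-matched ratio-of-tails over the pooled permutation null (the
convention of the reference GSEA tool). Phenotype permutation shuffles
sample labels and re-ranks genes by signal-to-noise; preranked permutation
shuffles gene identities, which is equivalent to drawing random same-size
gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import AnalyteMatrix, GeneSetCollection
from .stats_core import bh_fdr, perm_pvalues_welch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Class comparison


def class_comparison(matrix: AnalyteMatrix, labels, group_of_interest,
                     n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """One-vs-rest per-gene comparison with permutation p and BH q.

    Per gene: unequal-variance t statistic, label-permutation p-value,
    BH q, and log2 fold change = mean(group) - mean(rest). Genes constant
    across all samples are flagged with statistic 0 and p 1.
    """
    labels = np.asarray(labels)
    if labels.size != matrix.shape[1]:
        raise ValueError("labels must align with matrix samples")
    in_group = labels == group_of_interest
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("need at least 2 samples on each side")
    values = matrix.values
    flat = values.std(axis=1) == 0
    t, p = perm_pvalues_welch(values, in_group.astype(int), n_perm=n_perm, seed=seed)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    fc = values[:, in_group].mean(axis=1) - values[:, ~in_group].mean(axis=1)
    return pd.DataFrame({
        "statistic": t,
        "fold_change": np.where(flat, 0.0, fc),
        "p": p,
        "q": bh_fdr(p),
        "flagged": flat,
    }, index=matrix.feature_ids)


def summarize_log_ratios(log_ratios) -> np.ndarray:
    """Per-feature replicate summary score: mean / (SD + 1), SD with n-1."""
    x = np.asarray(log_ratios, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 replicates per feature")
    return x.mean(axis=1) / (x.std(axis=1, ddof=1) + 1.0)


# ---------------------------------------------------------------------------
# Enrichment score


def gsea_es(ranked_features, ranking_scores, gene_set, weight: float = 1.0):
    """Weighted KS enrichment score over a descending-ranked list.

    Returns ``(es, running_sum)``. ``ranked_features`` must already be
    sorted by descending score.
    """
    features = list(ranked_features)
    scores = np.asarray(ranking_scores, dtype=float)
    members = set(gene_set.members) if hasattr(gene_set, "members") else set(gene_set)
    hit = np.fromiter((f in members for f in features), dtype=bool, count=len(features))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    n = len(features)
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are zero: fall back to equal weights
        hit_w = hit.astype(float)
        total = float(n_hits)
    steps = hit_w / total
    if n_hits < n:
        steps = steps - (~hit) / (n - n_hits)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES from sorted hit positions only (O(hits)); equals gsea_es.

    The running sum is piecewise linear between hits, so its extremes occur
    at a hit position (candidate maxima) or just before one / at the list
    end (candidate minima).
    """
    h = positions.size
    if h == n:
        return 1.0
    total = weights.sum()
    if total == 0:
        weights = np.ones(h)
        total = float(h)
    cum_w = np.cumsum(weights) / total
    miss = 1.0 / (n - h)
    ranks = np.arange(1, h + 1)
    at_hit = cum_w - (positions + 1 - ranks) * miss       # just after each hit
    before_hit = np.concatenate(([0.0], cum_w[:-1])) - (positions + 1 - ranks) * miss
    hi = float(at_hit.max())
    lo = float(min(before_hit.min(), 0.0))
    return hi if hi >= -lo else lo


# ---------------------------------------------------------------------------
# Signal-to-noise ranking


def signal_to_noise(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """GSEA's signal-to-noise ratio with its SD floor (sigma >= max(0.2|mu|, 0.2 sigma-min))."""
    x = values[:, in_group]
    y = values[:, ~in_group]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    s1 = np.maximum(x.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(m1), 1e-8))
    s2 = np.maximum(y.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(m2), 1e-8))
    return (m1 - m2) / (s1 + s2)


# ---------------------------------------------------------------------------
# Full GSEA run


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: es, nes, p, fdr, size, leading_edge
    mode: str
    n_perm: int

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not np.all(np.sign(t["nes"].fillna(0)) * np.sign(t["es"]) >= 0):
            raise ValueError("NES sign disagrees with ES sign")


def _set_positions(order_inv: np.ndarray, set_idx: np.ndarray) -> np.ndarray:
    return np.sort(order_inv[set_idx])


def _leading_edge(features, scores, gene_set, weight):
    es, running = gsea_es(features, scores, gene_set, weight)
    members = gene_set.member_set
    if es >= 0:
        upto = int(np.argmax(np.abs(running)))
        return [f for f in features[: upto + 1] if f in members]
    frm = int(np.argmax(np.abs(running)))
    return [f for f in features[frm:] if f in members]


def gsea_run(data, gene_sets: GeneSetCollection, mode: str = "phenotype",
             labels=None, group_of_interest=None, n_perm: int = 1000,
             seed: int | None = None, weight: float = 1.0,
             min_size: int = 5, max_size: int = 500) -> EnrichmentResult:
    """Run GSEA in phenotype-permutation or preranked mode.

    ``data`` is an :class:`AnalyteMatrix` (phenotype mode) or a pandas
    Series of ranking scores indexed by feature (preranked mode).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    rng = np.random.default_rng(seed)

    if mode == "phenotype":
        if labels is None or group_of_interest is None:
            raise ValueError("phenotype mode needs labels and a group of interest")
        matrix: AnalyteMatrix = data
        features = np.array(matrix.feature_ids)
        values = matrix.values
        in_group = np.asarray(labels) == group_of_interest
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ValueError("need at least 2 samples on each side")
        score_obs = signal_to_noise(values, in_group)
        null_scores = np.empty((n_perm, values.shape[0]))
        idx = np.flatnonzero(in_group)
        n_samples = values.shape[1]
        for b in range(n_perm):
            perm_group = np.zeros(n_samples, dtype=bool)
            perm_group[rng.choice(n_samples, size=idx.size, replace=False)] = True
            null_scores[b] = signal_to_noise(values, perm_group)
    elif mode == "preranked":
        series = pd.Series(data).astype(float)
        features = np.array(series.index.astype(str))
        score_obs = series.to_numpy()
        null_scores = None  # preranked null permutes gene identities instead
    else:
        raise ValueError(f"unknown GSEA mode {mode!r}")

    n = features.size
    feat_index = {f: i for i, f in enumerate(features)}

    order_obs = np.argsort(-score_obs, kind="stable")
    inv_obs = np.empty(n, dtype=int)
    inv_obs[order_obs] = np.arange(n)
    sorted_obs = score_obs[order_obs]
    ranked_features = features[order_obs]

    kept_sets, set_indices = [], []
    for gs in gene_sets:
        idxs = np.array([feat_index[m] for m in gs.members if m in feat_index], dtype=int)
        if not (min_size <= idxs.size <= max_size):
            logger.info("gene set %s skipped (size %d outside [%d, %d])",
                        gs.name, idxs.size, min_size, max_size)
            continue
        kept_sets.append(gs)
        set_indices.append(idxs)
    if not kept_sets:
        logger.warning("no gene set within size bounds")
        return EnrichmentResult(pd.DataFrame(
            columns=["es", "nes", "p", "fdr", "size", "leading_edge"]), mode, n_perm)

    es_obs = np.empty(len(kept_sets))
    for s, idxs in enumerate(set_indices):
        pos = _set_positions(inv_obs, idxs)
        es_obs[s] = _es_from_positions(pos, np.abs(sorted_obs[pos]) ** weight, n)

    # null ES: sets x permutations
    es_null = np.empty((len(kept_sets), n_perm))
    if mode == "phenotype":
        for b in range(n_perm):
            sc = null_scores[b]
            order = np.argsort(-sc, kind="stable")
            inv = np.empty(n, dtype=int)
            inv[order] = np.arange(n)
            sorted_sc = sc[order]
            for s, idxs in enumerate(set_indices):
                pos = _set_positions(inv, idxs)
                es_null[s, b] = _es_from_positions(pos, np.abs(sorted_sc[pos]) ** weight, n)
    else:
        w_sorted = np.abs(sorted_obs) ** weight
        for b in range(n_perm):
            for s, idxs in enumerate(set_indices):
                pos = np.sort(rng.choice(n, size=idxs.size, replace=False))
                es_null[s, b] = _es_from_positions(pos, w_sorted[pos], n)

    nes_obs, nes_null, p_nom = _normalize_es(es_obs, es_null)
    fdr = _fdr_ratio_of_tails(nes_obs, nes_null)

    rows = []
    for s, gs in enumerate(kept_sets):
        le = _leading_edge(list(ranked_features), sorted_obs, gs, weight)
        rows.append({
            "es": es_obs[s], "nes": nes_obs[s], "p": p_nom[s], "fdr": fdr[s],
            "size": set_indices[s].size, "leading_edge": ",".join(le),
        })
    table = pd.DataFrame(rows, index=[gs.name for gs in kept_sets])
    return EnrichmentResult(table, mode, n_perm)


def _normalize_es(es_obs: np.ndarray, es_null: np.ndarray):
    """NES = ES / mean(|null ES| of matching sign); nominal p sign-matched."""
    n_sets, n_perm = es_null.shape
    nes_obs = np.zeros(n_sets)
    nes_null = np.zeros_like(es_null)
    p = np.ones(n_sets)
    for s in range(n_sets):
        null = es_null[s]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        with np.errstate(invalid="ignore"):
            nes_null[s] = np.where(null >= 0,
                                   null / pos_mean if np.isfinite(pos_mean) else 0.0,
                                   null / neg_mean if np.isfinite(neg_mean) else 0.0)
        nes_null[s] = np.nan_to_num(nes_null[s])
        e = es_obs[s]
        if e >= 0:
            denom = pos_mean
            same = null[null >= 0]
            hits = (same >= e - 1e-12).sum()
        else:
            denom = neg_mean
            same = null[null <= 0]
            hits = (same <= e + 1e-12).sum()
        p[s] = hits / same.size if same.size else 1.0
        nes_obs[s] = e / denom if np.isfinite(denom) and denom > 0 else 0.0
    return nes_obs, nes_null, p


def _fdr_ratio_of_tails(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """Sign-matched ratio-of-tails FDR over the pooled normalized null."""
    pooled = nes_null.ravel()
    fdr = np.ones_like(nes_obs)
    for s, nes in enumerate(nes_obs):
        if nes >= 0:
            null_tail = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            obs_tail = (nes_obs >= nes).sum() / max((nes_obs >= 0).sum(), 1)
        else:
            null_tail = (pooled <= nes).sum() / max((pooled <= 0).sum(), 1)
            obs_tail = (nes_obs <= nes).sum() / max((nes_obs <= 0).sum(), 1)
        fdr[s] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0
    return fdr


def enrichment_matrix(matrix: AnalyteMatrix, cluster_labels,
                      gene_sets: GeneSetCollection, fdr_cut: float = 0.05,
                      n_perm: int = 1000, seed: int | None = None,
                      **gsea_kwargs) -> pd.DataFrame:
    """One-vs-rest NES matrix across clusters, filtered at a per-set FDR.

    Rows are cluster contrasts, columns the gene sets that pass the FDR cut
    in at least one contrast (the subtype-vs-hallmark enrichment heatmap
    object). Empty when nothing passes.
    """
    cluster_labels = np.asarray(cluster_labels)
    uniq = np.unique(cluster_labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    nes_rows, fdr_rows = {}, {}
    for g, cluster in enumerate(uniq):
        res = gsea_run(matrix, gene_sets, mode="phenotype", labels=cluster_labels,
                       group_of_interest=cluster, n_perm=n_perm,
                       seed=None if seed is None else seed + g, **gsea_kwargs)
        nes_rows[str(cluster)] = res.table["nes"]
        fdr_rows[str(cluster)] = res.table["fdr"]
    nes = pd.DataFrame(nes_rows).T
    fdr = pd.DataFrame(fdr_rows).T
    keep = [c for c in nes.columns if (fdr[c] <= fdr_cut).any()]
    if not keep:
        logger.warning("no gene set passes FDR <= %g in any contrast", fdr_cut)
    return nes[keep]
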