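"""Projection of 96-channel mutation catalogs onto fixed mutational signatures.

The catalog V (channels x samples) is projected onto a fixed signature
matrix W (channels x signatures) by the multiplicative update for
nonnegative matrix factorization under generalized Kullback–Leibler
divergence, with W held fixed so only the activation matrix H is learned:

    H <- H * (W^T (V / (W H))) / (W^T 1)

With W fixed this objective is convex in H, so initialization affects only
the iteration count, and the cost is monotone non-increasing by the
standard majorization argument. Parsimonious signature-set selection scans
subset sizes, keeping the minimum-cost composition per size, and picks the
smallest size beyond which adding a signature no longer buys a large
relative cost drop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .stats_core import mann_whitney_u

logger = logging.getLogger(__name__)

EPS = 1e-12

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: canonical COSMIC order of the 96 trinucleotide channels:
#: substitution-major, then 5' base, then 3' base.
COSMIC_CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in BASES for three in BASES
)


@dataclass
class MutationCatalog:
    """96-channel substitution counts, channels x samples (V)."""

    counts: np.ndarray
    sample_ids: list[str]
    channels: tuple[str, ...] = COSMIC_CHANNELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.channels) != 96:
            raise ValueError("expected exactly 96 channels")
        if self.counts.shape != (96, len(self.sample_ids)):
            raise ValueError("catalog dimensions inconsistent")
        if (self.counts < 0).any():
            raise ValueError("negative mutation counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.channels),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationCatalog":
        if list(df.index) != list(COSMIC_CHANNELS):
            raise ValueError("catalog rows must be the 96 COSMIC channels in order")
        return cls(df.to_numpy(), list(df.columns.astype(str)))


@dataclass
class SignatureMatrix:
    """Fixed signature profiles, channels x signatures (W); columns sum to 1."""

    values: np.ndarray
    names: list[str]
    channels: tuple[str, ...] = COSMIC_CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channels), len(self.names)):
            raise ValueError("signature matrix dimensions inconsistent")
        if (self.values < 0).any():
            raise ValueError("negative signature weights")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1 (+/- 1e-6)")

    def subset(self, names) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.values[:, idx], list(names), self.channels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.channels), columns=self.names)


@dataclass
class ActivationResult:
    """Learned activations H (signatures x samples) with per-sample fractions."""

    h: np.ndarray
    fractions: np.ndarray            # columns sum to 1 where the sample has mutations
    signature_names: list[str]
    sample_ids: list[str]
    cost: float
    cost_trajectory: np.ndarray
    n_iter: int
    converged: bool
    zero_samples: list[str] = field(default_factory=list)


def kl_cost(v: np.ndarray, wh: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum V log(V/WH) - V + WH."""
    wh = np.maximum(wh, EPS)
    mask = v > 0
    term = np.where(mask, v * np.log(np.maximum(v, EPS) / wh), 0.0)
    return float((term - v + wh).sum())


def project_activations(catalog: MutationCatalog, signatures: SignatureMatrix,
                        tol: float = 1e-6, max_iter: int = 10_000,
                        seed: int | None = None) -> ActivationResult:
    """Fit H in V ~ W H with W fixed, by KL multiplicative updates.

    Stops when the relative cost change drops below ``tol``. The cost
    trajectory is returned so monotonicity can be certified. All-zero
    samples get a zero activation column and undefined (NaN) fractions,
    flagged in ``zero_samples``.
    """
    if tuple(catalog.channels) != tuple(signatures.channels):
        raise ValueError("catalog and signature channels differ")
    v = catalog.counts.astype(float)
    w = signatures.values
    s, n = w.shape[1], v.shape[1]
    rng = np.random.default_rng(seed)
    col_tot = v.sum(axis=0)
    h = rng.uniform(0.5, 1.5, size=(s, n)) * np.maximum(col_tot, 1.0) / s
    denom = w.sum(axis=0)[:, None]  # W^T 1
    costs = [kl_cost(v, w @ h)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wh = np.maximum(w @ h, EPS)
        h = h * (w.T @ (v / wh)) / np.maximum(denom, EPS)
        costs.append(kl_cost(v, w @ h))
        if abs(costs[-2] - costs[-1]) <= tol * max(abs(costs[-2]), EPS):
            converged = True
            break
    zero = col_tot == 0
    h[:, zero] = 0.0
    h_sums = h.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fractions = np.where(h_sums > 0, h / np.maximum(h_sums, EPS), np.nan)
    zero_samples = [catalog.sample_ids[i] for i in np.flatnonzero(zero)]
    if zero_samples:
        logger.warning("samples with zero mutations (fractions undefined): %s",
                       zero_samples)
    return ActivationResult(h, fractions, list(signatures.names),
                            list(catalog.sample_ids), costs[-1],
                            np.asarray(costs), it, converged, zero_samples)


@dataclass
class SignatureSelection:
    selected: tuple[str, ...]
    selected_size: int
    cost_curve: dict[int, float]            # size -> best cost
    best_subsets: dict[int, tuple[str, ...]]
    tol_drop: float


def select_signatures(catalog: MutationCatalog, signatures: SignatureMatrix,
                      max_size: int | None = None, tol_drop: float = 0.02,
                      seed: int | None = None,
                      exhaustive_limit: int = 10_000) -> SignatureSelection:
    """Parsimonious signature-subset selection over the fixed catalog.

    For each size the minimum-cost subset is found (exhaustively when the
    number of combinations allows, otherwise by greedy forward search from
    the previous best subset; ties broken lexicographically). The selected
    size is the smallest s whose relative cost drop to s+1 falls below
    ``tol_drop``; with ``tol_drop=0`` the scan degenerates to ``max_size``.
    """
    names = list(signatures.names)
    s_total = len(names)
    max_size = s_total if max_size is None else int(max_size)
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    max_size = min(max_size, s_total)

    def subset_cost(subset: tuple[str, ...]) -> float:
        res = project_activations(catalog, signatures.subset(list(subset)), seed=seed)
        return res.cost

    cost_curve: dict[int, float] = {}
    best_subsets: dict[int, tuple[str, ...]] = {}
    prev_best: tuple[str, ...] = ()
    for size in range(1, max_size + 1):
        if math.comb(s_total, size) <= exhaustive_limit:
            candidates = [tuple(c) for c in combinations(sorted(names), size)]
        else:
            remaining = [n for n in sorted(names) if n not in prev_best]
            candidates = [tuple(sorted(prev_best + (n,))) for n in remaining]
        costs = [(subset_cost(c), c) for c in candidates]
        best_cost, best = min(costs, key=lambda t: (t[0], t[1]))
        cost_curve[size] = best_cost
        best_subsets[size] = best
        prev_best = best

    selected_size = max_size
    for size in range(1, max_size):
        drop = (cost_curve[size] - cost_curve[size + 1]) / max(cost_curve[size], EPS)
        if drop < tol_drop:
            selected_size = size
            break
    return SignatureSelection(best_subsets[selected_size], selected_size,
                              cost_curve, best_subsets, tol_drop)


def activation_group_compare(activations: ActivationResult, group_labels,
                             group_a, group_b) -> pd.DataFrame:
    """Per-signature Mann–Whitney comparison of activation fractions.

    Groups with fewer than 2 usable samples are skipped with a log message.
    Also reports per-group medians and a median-centered activation value is
    available via :func:`median_centered_fractions`.
    """
    labels = np.asarray(group_labels)
    frac = activations.fractions
    rows = []
    for i, sig in enumerate(activations.signature_names):
        vals = frac[i]
        ok = ~np.isnan(vals)
        a = vals[ok & (labels == group_a)]
        b = vals[ok & (labels == group_b)]
        if a.size < 2 or b.size < 2:
            logger.warning("signature %s skipped: group with < 2 samples", sig)
            continue
        test = mann_whitney_u(a, b)
        rows.append({
            "signature": sig,
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "statistic": test.statistic, "p": test.p_value, "method": test.method,
        })
    return pd.DataFrame(rows).set_index("signature") if rows else pd.DataFrame(
        columns=["median_a", "median_b", "statistic", "p", "method"])


def median_centered_fractions(activations: ActivationResult) -> pd.DataFrame:
    """Per-signature median-centered activation fractions (heatmap convention)."""
    df = pd.DataFrame(activations.fractions, index=activations.signature_names,
                      columns=activations.sample_ids)
    return df.sub(df.median(axis=1), axis=0)
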