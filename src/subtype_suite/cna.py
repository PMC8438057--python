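"""Copy-number aberration scoring and del(13q) architecture calls.

Segments are rasterized onto a uniform marker grid after the segment
filters (at least five markers and |log2 ratio| strictly above 0.2). Per
marker and direction the G-score is aberration amplitude x frequency
across samples; significance comes from a permutation null that circularly
shifts each sample's whole-genome marker vector, preserving its aberration
burden and segment-length structure while randomizing location. Peaks are
maximal runs of markers with BH q below the threshold (0.25 by default).

del(13q) architecture: a 13q loss is type II when it overlaps the RB1
locus, type I otherwise; a long distal break (LDB) extends strictly beyond
the 54.7 Mb boundary; biallelic loss is called from deep amplitude
(log2 <= -0.9 by default). Gene coordinates come from an annotation config
and are never hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_core import SegmentTable, normalize_chrom
from .stats_core import (TestResult, bh_fdr, fisher_exact_2x2,
                         one_sample_prop_test, wilcoxon_signed_rank)

logger = logging.getLogger(__name__)

DEFAULT_LDB_BOUNDARY_BP = 54_700_000  # distal edge of most of cytoband 13q21.1 (hg18)


@dataclass
class GenomeConfig:
    """Chromosome lengths plus the annotation intervals the CNA calls need."""

    build: str = "hg18"
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    rb1_interval: tuple[int, int] | None = None  # on chr13, 0-based half-open
    ldb_boundary_bp: int = DEFAULT_LDB_BOUNDARY_BP
    chrom13: str = "13"

    def __post_init__(self) -> None:
        self.chrom_lengths = {normalize_chrom(c): int(l)
                              for c, l in self.chrom_lengths.items()}
        if not self.chrom_lengths:
            raise ValueError("genome config needs chromosome lengths")

    @classmethod
    def from_yaml(cls, path) -> "GenomeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rb1 = raw.get("rb1_interval")
        return cls(build=raw.get("build", "hg18"),
                   chrom_lengths=raw["chrom_lengths"],
                   rb1_interval=tuple(rb1) if rb1 else None,
                   ldb_boundary_bp=int(raw.get("ldb_boundary_bp", DEFAULT_LDB_BOUNDARY_BP)),
                   chrom13=normalize_chrom(raw.get("chrom13", "13")))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "build": self.build,
                "chrom_lengths": self.chrom_lengths,
                "rb1_interval": list(self.rb1_interval) if self.rb1_interval else None,
                "ldb_boundary_bp": self.ldb_boundary_bp,
                "chrom13": self.chrom13,
            }, fh, sort_keys=True)


@dataclass
class MarkerMatrix:
    markers: pd.DataFrame        # columns chrom, pos, sorted
    values: np.ndarray           # samples x markers, signed log2, 0 = no aberration
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError("marker matrix dimensions inconsistent")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite marker values")

    def subset(self, sample_ids) -> "MarkerMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MarkerMatrix(self.markers, self.values[idx], list(sample_ids))


def marker_grid(genome: GenomeConfig, spacing: int = 1_000_000) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        for i in range(length // spacing):
            rows.append((chrom, int((i + 0.5) * spacing)))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def segments_to_markers(segments: SegmentTable, genome: GenomeConfig,
                        spacing: int = 1_000_000, min_markers: int = 5,
                        amp_threshold: float = 0.2, cap: float = 2.0,
                        sample_ids=None) -> MarkerMatrix:
    """Rasterize filtered segments onto a uniform marker grid.

    Segments failing the marker-count filter or with |log2| <= amp_threshold
    (strict exceedance required) are ignored; surviving amplitudes are
    clipped to +/-cap and painted onto every grid marker they cover.
    ``sample_ids`` fixes the cohort (samples without segments get an
    all-zero row); by default only samples present in the table appear.
    """
    grid = marker_grid(genome, spacing)
    sample_ids = list(sample_ids) if sample_ids is not None else segments.sample_ids
    values = np.zeros((len(sample_ids), len(grid)))
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    # marker lookup per chromosome
    chrom_offsets = {}
    for chrom in genome.chrom_lengths:
        idx = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
        chrom_offsets[chrom] = (idx[0], idx.size) if idx.size else (0, 0)
    for row in segments.data.itertuples(index=False):
        if row.sample not in sample_index:
            continue
        chrom = row.chrom
        if chrom not in genome.chrom_lengths:
            raise ValueError(f"segment on unknown chromosome {chrom!r}")
        if row.end > genome.chrom_lengths[chrom]:
            raise ValueError(
                f"segment {row.sample} chr{chrom}:{row.start}-{row.end} "
                f"extends beyond chromosome end {genome.chrom_lengths[chrom]}"
            )
        if row.n_markers < min_markers or abs(row.seg_mean) <= amp_threshold:
            continue
        off, n_m = chrom_offsets[chrom]
        if n_m == 0:
            continue
        # markers at (i + 0.5) * spacing covered by [start, end)
        first = int(np.ceil(row.start / spacing - 0.5))
        last = int(np.ceil(row.end / spacing - 0.5))  # exclusive
        first, last = max(first, 0), min(last, n_m)
        if first < last:
            values[sample_index[row.sample], off + first: off + last] = \
                float(np.clip(row.seg_mean, -cap, cap))
    return MarkerMatrix(grid, values, sample_ids)


def gscore_profile(markers: MarkerMatrix, sample_subset=None) -> dict[str, np.ndarray]:
    """Per-marker G-scores: mean aberrant amplitude x frequency, by direction."""
    mm = markers if sample_subset is None else markers.subset(sample_subset)
    if mm.values.shape[0] == 0:
        raise ValueError("empty sample subset")
    n = mm.values.shape[0]
    return {
        "gain": np.clip(mm.values, 0, None).sum(axis=0) / n,
        "loss": np.clip(-mm.values, 0, None).sum(axis=0) / n,
    }


@dataclass
class GScoreTrack:
    markers: pd.DataFrame
    g: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    q: dict[str, np.ndarray]
    peaks: pd.DataFrame  # direction, chrom, start, end, peak_pos, max_g, min_q
    q_threshold: float

    def to_bed_like(self) -> pd.DataFrame:
        rows = []
        for direction in ("gain", "loss"):
            for m, (chrom, pos) in enumerate(zip(self.markers["chrom"], self.markers["pos"])):
                rows.append((chrom, pos, direction, self.g[direction][m],
                             self.q[direction][m]))
        return pd.DataFrame(rows, columns=["chrom", "pos", "direction", "g", "q"])


def gistic_lite(markers: MarkerMatrix, sample_subset=None, n_perm: int = 1000,
                q_threshold: float = 0.25, seed: int | None = None) -> GScoreTrack:
    """Permutation significance for G-scores with per-sample circular shifts.

    Each permutation circularly shifts every sample's whole-genome marker
    vector by an independent uniform offset; per-marker p-values count
    permutations with G >= observed, BH-corrected per direction. Peaks are
    maximal same-chromosome runs of markers at q <= q_threshold.
    """
    mm = markers if sample_subset is None else markers.subset(sample_subset)
    n, m = mm.values.shape
    if n < 5:
        raise ValueError("need at least 5 samples for the permutation null")
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if n_perm < 100:
        logger.warning("n_perm=%d is low for q-value estimation", n_perm)
    rng = np.random.default_rng(seed)
    obs = gscore_profile(mm)
    hits = {"gain": np.zeros(m, dtype=int), "loss": np.zeros(m, dtype=int)}
    cols = np.arange(m)
    rows = np.arange(n)[:, None]
    for _ in range(n_perm):
        offsets = rng.integers(0, m, size=n)
        shifted = mm.values[rows, (cols[None, :] - offsets[:, None]) % m]
        g_gain = np.clip(shifted, 0, None).sum(axis=0) / n
        g_loss = np.clip(-shifted, 0, None).sum(axis=0) / n
        hits["gain"] += g_gain >= obs["gain"] - 1e-12
        hits["loss"] += g_loss >= obs["loss"] - 1e-12
    p = {d: (1 + hits[d]) / (1 + n_perm) for d in hits}
    q = {d: bh_fdr(p[d]) for d in p}
    peaks = _call_peaks(mm.markers, obs, q, q_threshold)
    return GScoreTrack(mm.markers, obs, p, q, peaks, q_threshold)


def _call_peaks(grid: pd.DataFrame, g, q, q_threshold: float) -> pd.DataFrame:
    chroms = grid["chrom"].to_numpy()
    pos = grid["pos"].to_numpy()
    n = len(grid)
    rows = []
    for direction in ("gain", "loss"):
        sig = q[direction] <= q_threshold
        i = 0
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and sig[j + 1] and chroms[j + 1] == chroms[i]:
                j += 1
            run = slice(i, j + 1)
            gm = g[direction][run]
            peak = i + int(np.argmax(gm))
            rows.append({
                "direction": direction, "chrom": chroms[i],
                "start": int(pos[i]), "end": int(pos[j]),
                "peak_pos": int(pos[peak]), "max_g": float(gm.max()),
                "min_q": float(q[direction][run].min()),
                "n_markers": j - i + 1,
            })
            i = j + 1
    return pd.DataFrame(rows, columns=["direction", "chrom", "start", "end",
                                       "peak_pos", "max_g", "min_q", "n_markers"])


# ---------------------------------------------------------------------------
# del(13q) architecture


@dataclass
class Del13qCall:
    sample_id: str
    status: str                  # none | typeI | typeII
    ldb: bool
    biallelic: bool
    distal_boundary: int | None  # bp end of the most distal qualifying loss

    def __post_init__(self) -> None:
        if self.status not in ("none", "typeI", "typeII"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "none" and (self.ldb or self.biallelic):
            raise ValueError("ldb/biallelic flags require a deletion call")


def classify_del13q(sample_segments: pd.DataFrame, genome: GenomeConfig,
                    biallelic_log2: float = -0.9, min_markers: int = 5,
                    amp_threshold: float = 0.2,
                    sample_id: str = "") -> Del13qCall:
    """Classify one sample's 13q deletion architecture.

    Qualifying losses are chr13 segments passing the standard segment
    filters with log2 < -amp_threshold. Type II = any loss overlapping the
    RB1 interval, type I otherwise; LDB = most distal loss boundary strictly
    beyond the configured 54.7 Mb cutoff; biallelic = any qualifying loss at
    or below the deep-deletion amplitude.
    """
    if genome.rb1_interval is None:
        raise ValueError("annotation is missing the RB1 interval")
    if genome.ldb_boundary_bp is None:
        raise ValueError("annotation is missing the LDB boundary")
    segs = sample_segments
    on13 = segs[segs["chrom"].map(normalize_chrom) == genome.chrom13]
    losses = on13[(on13["seg_mean"] < -amp_threshold)
                  & (on13["n_markers"] >= min_markers)]
    if losses.empty:
        return Del13qCall(sample_id, "none", False, False, None)
    rb1_start, rb1_end = genome.rb1_interval
    overlaps_rb1 = ((losses["start"] < rb1_end) & (losses["end"] > rb1_start)).any()
    distal = int(losses["end"].max())
    return Del13qCall(
        sample_id,
        "typeII" if overlaps_rb1 else "typeI",
        ldb=distal > genome.ldb_boundary_bp,
        biallelic=bool((losses["seg_mean"] <= biallelic_log2).any()),
        distal_boundary=distal,
    )


def classify_del13q_cohort(segments: SegmentTable, genome: GenomeConfig,
                           **kwargs) -> list[Del13qCall]:
    return [classify_del13q(segments.for_sample(s), genome, sample_id=s, **kwargs)
            for s in segments.sample_ids]


def del13q_cohort_stats(calls: list[Del13qCall], cluster_labels: dict[str, str],
                        supergroup_a: set[str], supergroup_b: set[str]) -> dict:
    """Association statistics of del(13q) architecture with subtype supergroups.

    Fisher tests compare type II vs type I and LDB vs non-LDB frequencies
    between the two supergroups (among deleted samples); the one-sample
    proportions test asks whether LDB cases carry type II deletions more
    often than chance (p0 = 0.5). Tests with a zero margin are reported NA.
    """
    deleted = [c for c in calls if c.status != "none"]
    in_a = [c for c in deleted if cluster_labels.get(c.sample_id) in supergroup_a]
    in_b = [c for c in deleted if cluster_labels.get(c.sample_id) in supergroup_b]

    def fisher_or_na(table):
        t = np.asarray(table)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return None
        return fisher_exact_2x2(t)

    type2_table = [[sum(c.status == "typeII" for c in in_a),
                    sum(c.status == "typeI" for c in in_a)],
                   [sum(c.status == "typeII" for c in in_b),
                    sum(c.status == "typeI" for c in in_b)]]
    ldb_table = [[sum(c.ldb for c in in_a), sum(not c.ldb for c in in_a)],
                 [sum(c.ldb for c in in_b), sum(not c.ldb for c in in_b)]]
    ldb_cases = [c for c in deleted if c.ldb]
    n_ldb = len(ldb_cases)
    n_ldb_type2 = sum(c.status == "typeII" for c in ldb_cases)
    return {
        "n_deleted": len(deleted),
        "type2_by_supergroup": {"table": type2_table, "test": fisher_or_na(type2_table)},
        "ldb_by_supergroup": {"table": ldb_table, "test": fisher_or_na(ldb_table)},
        "ldb_type2_cooccurrence": {
            "x": n_ldb_type2, "n": n_ldb,
            "test": one_sample_prop_test(n_ldb_type2, n_ldb, 0.5) if n_ldb else None,
        },
    }


def paired_burden_test(pre_segments: SegmentTable, post_segments: SegmentTable,
                       genome: GenomeConfig, pairing: dict[str, str] | None = None,
                       min_markers: int = 5, amp_threshold: float = 0.2) -> dict:
    """Paired pre/post-treatment aberration-count comparison.

    Counts qualifying segments (post segment filters) per sample at both
    timepoints and applies the Wilcoxon signed-rank test to the pairs.
    ``pairing`` maps pre-sample id -> post-sample id (identity by default).
    """
    pre_ids = pre_segments.sample_ids
    pairing = pairing or {s: s for s in pre_ids}
    post_ids = set(post_segments.sample_ids)
    missing = [s for s in pre_ids if pairing.get(s) not in post_ids]
    if missing:
        raise ValueError(f"samples without a post-treatment pair: {missing}")

    def count(seg_df: pd.DataFrame) -> int:
        ok = (seg_df["n_markers"] >= min_markers) & \
             (seg_df["seg_mean"].abs() > amp_threshold)
        return int(ok.sum())

    pre_counts = np.array([count(pre_segments.for_sample(s)) for s in pre_ids])
    post_counts = np.array([count(post_segments.for_sample(pairing[s])) for s in pre_ids])
    try:
        test = wilcoxon_signed_rank(pre_counts, post_counts)
    except ValueError:
        test = TestResult(0.0, 1.0, "wilcoxon-signed-rank (no change)")
    return {
        "pre_counts": pre_counts, "post_counts": post_counts,
        "mean_pre": float(pre_counts.mean()), "mean_post": float(post_counts.mean()),
        "test": test,
    }
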