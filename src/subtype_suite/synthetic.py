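"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream methods
assume: block-program expression clusters over Gaussian log2 noise,
segmented copy-number profiles with cluster-specific recurrent peaks and a
mix of 13q deletion architectures, multinomial mutation catalogs drawn from
known signature mixtures, subtype-dependent exponential survival with
independent exponential censoring, and qPCR dilution-standard runs. Every
generator is a pure function of its parameters and seed and emits its
ground truth so recovery can be measured.

Default cohort structure: 6 expression clusters of sizes 133/56/30/100/11/7
(the unequal discovered-subtype sizes, which stress small-cluster
behavior), 100-gene programs shifted by 2 log2 units over unit-variance
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import TELOMERE_OLIGO_BP
from .cna import GenomeConfig
from .io_core import AnalyteMatrix, ClinicalTable, SegmentTable
from .signatures import COSMIC_CHANNELS, MutationCatalog, SignatureMatrix

DEFAULT_CLUSTER_SIZES = (133, 56, 30, 100, 11, 7)


@dataclass
class CohortTruth:
    sample_ids: list[str]
    cluster: np.ndarray | None = None            # integer label per sample (1-based)
    activations: np.ndarray | None = None        # samples x signatures fractions
    signature_names: list[str] | None = None
    del13q: dict[str, dict] | None = None        # sample -> status/ldb/biallelic
    hazard: np.ndarray | None = None
    lengths_kb: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.cluster is not None and len(self.cluster) != n:
            raise ValueError("one cluster label per sample required")
        if self.activations is not None:
            sums = np.asarray(self.activations).sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("activation fractions must sum to 1 per sample")


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def make_expression(n_genes: int = 2000, n_samples: int = 337, k: int = 6,
                    cluster_sizes=DEFAULT_CLUSTER_SIZES, program_size: int = 100,
                    effect: float = 2.0, noise_sd: float = 1.0,
                    seed: int | None = None) -> tuple[AnalyteMatrix, CohortTruth]:
    """Expression cohort with k planted block-program clusters.

    Each cluster up-shifts its private block of ``program_size`` genes by
    ``effect`` over i.i.d. Gaussian noise. ``effect=0`` produces a null
    cohort with no structure.
    """
    cluster_sizes = tuple(int(s) for s in cluster_sizes)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(cluster_sizes) != k:
        raise ValueError("cluster_sizes must have k entries")
    if sum(cluster_sizes) != n_samples:
        raise ValueError("cluster sizes must sum to n_samples")
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    if k * program_size > n_genes:
        raise ValueError("program blocks exceed n_genes")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    labels = np.repeat(np.arange(1, k + 1), cluster_sizes)
    for c in range(k):
        genes = slice(c * program_size, (c + 1) * program_size)
        values[genes, labels == c + 1] += effect
    sample_ids = _sample_ids(n_samples)
    feature_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    matrix = AnalyteMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))
    return matrix, CohortTruth(sample_ids, cluster=labels)


def make_signature_matrix(n_signatures: int = 5, concentration: float = 0.5,
                          seed: int | None = None) -> SignatureMatrix:
    """Synthetic stand-in signature catalog: Dirichlet 96-channel profiles.

    A labelled synthetic construct, not the COSMIC catalog; sparse
    Dirichlet draws give the peaked channel profiles real signatures show.
    """
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    names = [f"SigSyn{i + 1}" for i in range(n_signatures)]
    return SignatureMatrix(w, names, COSMIC_CHANNELS)


def make_mutation_catalog(signatures: SignatureMatrix, fractions,
                          n_mutations_per_sample=1000,
                          seed: int | None = None,
                          ) -> tuple[MutationCatalog, CohortTruth]:
    """Multinomial mutation catalog from known per-sample signature mixtures.

    ``fractions`` is samples x signatures, each row on the simplex; each
    sample's 96-vector is Multinomial(n_mutations, W h) so column sums equal
    the requested totals exactly.
    """
    h = np.asarray(fractions, dtype=float)
    if h.ndim != 2 or h.shape[1] != signatures.values.shape[1]:
        raise ValueError("fractions must be samples x signatures")
    if (h < 0).any():
        raise ValueError("negative signature fractions")
    if not np.allclose(h.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("fractions must sum to 1 per sample")
    n_samples = h.shape[0]
    totals = np.broadcast_to(np.asarray(n_mutations_per_sample, dtype=int),
                             (n_samples,))
    rng = np.random.default_rng(seed)
    probs = h @ signatures.values.T  # samples x channels
    counts = np.stack([rng.multinomial(totals[i], probs[i])
                       for i in range(n_samples)], axis=1)
    sample_ids = _sample_ids(n_samples)
    catalog = MutationCatalog(counts, sample_ids, signatures.channels)
    truth = CohortTruth(sample_ids, activations=h,
                        signature_names=list(signatures.names))
    return catalog, truth


def default_genome(n_autosomes: int = 4, chrom_mb: int = 120) -> GenomeConfig:
    """Small synthetic genome for simulation: equal-length chromosomes plus a
    full-length chr13 carrying an RB1 interval and the 54.7 Mb LDB boundary."""
    lengths = {str(c): chrom_mb * 1_000_000 for c in range(1, n_autosomes + 1)}
    lengths["13"] = 114_000_000
    return GenomeConfig(build="synthetic", chrom_lengths=lengths,
                        rb1_interval=(47_775_000, 47_954_000),
                        ldb_boundary_bp=54_700_000)


@dataclass
class PeakSpec:
    cluster: int
    chrom: str
    start: int
    end: int
    amp: float            # signed log2 amplitude
    penetrance: float


@dataclass
class Del13qSpec:
    rate: float = 0.5                 # fraction of samples carrying a 13q loss
    type2_fraction: float = 0.5       # of carriers, fraction overlapping RB1
    ldb_fraction: float = 0.2         # of carriers, fraction extending distally
    biallelic_fraction: float = 0.1   # of carriers, fraction at deep amplitude
    focal_start: int = 49_000_000     # proximal edge of the 13q14 focal region
    focal_end: int = 51_500_000
    shallow_amp: float = -0.45
    deep_amp: float = -1.5


def make_cna_cohort(truth_labels, peak_specs, genome: GenomeConfig,
                    del13q_spec: Del13qSpec | None = None,
                    background_rate: float = 2.0,
                    background_amp_range: tuple[float, float] = (0.2, 1.0),
                    background_len_mb: tuple[int, int] = (2, 15),
                    seed: int | None = None,
                    ) -> tuple[SegmentTable, CohortTruth]:
    """Segmented CNA cohort with planted recurrent peaks and 13q deletions.

    Background segments are Poisson-many per sample with |log2| amplitudes
    drawn uniformly from ``background_amp_range`` (the lower edge sits at
    the 0.2 segment filter so the threshold is exercised) and random sign.
    Planted peaks appear in ``penetrance`` of their cluster's samples;
    background segments colliding with an already placed segment on the
    same chromosome are dropped to keep per-sample segments non-overlapping.
    """
    labels = np.asarray(truth_labels)
    n = labels.size
    sample_ids = _sample_ids(n)
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    for spec in peak_specs:
        c = spec.chrom
        if c not in genome.chrom_lengths:
            raise ValueError(f"peak on unknown chromosome {c!r}")
        if not (0 <= spec.start < spec.end <= genome.chrom_lengths[c]):
            raise ValueError(f"peak interval outside chromosome bounds: {spec}")
    rows = []
    del13q_truth: dict[str, dict] = {}

    def try_add(sample, chrom, start, end, amp, n_markers):
        for r in rows:
            if r[0] == sample and r[1] == chrom and start < r[3] and end > r[2]:
                return False
        rows.append((sample, chrom, int(start), int(end), int(n_markers), float(amp)))
        return True

    for i, sample in enumerate(sample_ids):
        # planted recurrent peaks for this sample's cluster
        for spec in peak_specs:
            if labels[i] == spec.cluster and rng.random() < spec.penetrance:
                n_markers = max(5, (spec.end - spec.start) // 100_000)
                try_add(sample, spec.chrom, spec.start, spec.end, spec.amp, n_markers)
        # 13q deletion architecture
        truth = {"status": "none", "ldb": False, "biallelic": False}
        if del13q_spec is not None and rng.random() < del13q_spec.rate:
            spec = del13q_spec
            type2 = rng.random() < spec.type2_fraction
            ldb = rng.random() < spec.ldb_fraction
            biallelic = rng.random() < spec.biallelic_fraction
            rb1_start, rb1_end = genome.rb1_interval
            if type2:
                # start proximal of RB1 so the loss spans it
                start = int(rng.integers(max(rb1_start - 2_000_000, 0),
                                         rb1_start - 100_000))
                end_min = rb1_end + 500_000
            else:
                # start distal of RB1, inside the focal 13q14 region
                start = int(rng.integers(rb1_end + 500_000, spec.focal_end))
                end_min = start + 1_000_000
            if ldb:
                end = int(rng.integers(genome.ldb_boundary_bp + 1_000_000,
                                       genome.chrom_lengths[genome.chrom13]))
            else:
                end = int(rng.integers(end_min, genome.ldb_boundary_bp))
            amp = spec.deep_amp if biallelic else spec.shallow_amp
            n_markers = max(5, (end - start) // 100_000)
            if try_add(sample, genome.chrom13, start, end, amp, n_markers):
                truth = {"status": "typeII" if type2 else "typeI",
                         "ldb": ldb, "biallelic": biallelic,
                         "start": start, "end": end}
        del13q_truth[sample] = truth
        # random background segments
        for _ in range(rng.poisson(background_rate)):
            chrom = chroms[rng.integers(len(chroms))]
            length = int(rng.integers(background_len_mb[0], background_len_mb[1] + 1)
                         ) * 1_000_000
            max_start = genome.chrom_lengths[chrom] - length
            if max_start <= 0:
                continue
            start = int(rng.integers(0, max_start))
            amp = float(rng.uniform(*background_amp_range)) * (1 if rng.random() < 0.5 else -1)
            n_markers = int(rng.integers(3, max(4, length // 200_000)))
            try_add(sample, chrom, start, start + length, amp, n_markers)

    seg = SegmentTable(pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_markers", "seg_mean"]))
    truth = CohortTruth(sample_ids, cluster=labels, del13q=del13q_truth)
    return seg, truth


def make_clinical(truth_labels, hazard_by_cluster, arm_effect: float = 1.0,
                  censor_rate: float = 0.3, os_hazard_scale: float = 0.5,
                  seed: int | None = None) -> tuple[ClinicalTable, CohortTruth]:
    """Exponential survival cohort with subtype-dependent hazards.

    PFS event time for sample i is Exponential(hazard[cluster_i] *
    arm_effect^arm_i); OS uses the same structure with hazards scaled by
    ``os_hazard_scale``. Independent exponential censoring with per-sample
    rate chosen so the expected censored fraction equals ``censor_rate``
    exactly; ``censor_rate=0`` observes every event.
    """
    labels = np.asarray(truth_labels)
    hazards = {int(k): float(v) for k, v in dict(hazard_by_cluster).items()}
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazards must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    if arm_effect <= 0:
        raise ValueError("arm_effect must be positive")
    n = labels.size
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 2, size=n)
    rate = np.array([hazards[int(c)] for c in labels]) * arm_effect**arm

    def endpoint(rates):
        t_event = rng.exponential(1.0 / rates)
        if censor_rate == 0:
            return t_event, np.ones(n, dtype=int)
        c_rate = censor_rate / (1 - censor_rate) * rates
        t_cens = rng.exponential(1.0 / c_rate)
        return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)

    pfs_time, pfs_event = endpoint(rate)
    os_time, os_event = endpoint(rate * os_hazard_scale)
    sample_ids = _sample_ids(n)
    table = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "arm": arm,
        "pfs_time": pfs_time, "pfs_event": pfs_event,
        "os_time": os_time, "os_event": os_event,
        "cluster": labels,
    }))
    return table, CohortTruth(sample_ids, cluster=labels, hazard=rate)


def make_qpcr(true_lengths_kb, efficiency: float = 2.0, noise_sd_ct: float = 0.0,
              standard_top_molecules: float = 1e8, n_dilutions: int = 6,
              tel_intercept: float = 40.0, scg_intercept: float = 38.0,
              scg_molecules_per_sample: float = 2e4,
              seed: int | None = None) -> dict:
    """qPCR run: tenfold dilution standards plus sample Cts from true lengths.

    Ct = intercept - log(molecules)/log(efficiency) + Gaussian noise. Sample
    telomere molecule counts are the exact inverse of the absolute-length
    arithmetic, so at zero noise the downstream length estimate is an
    identity.
    """
    lengths = np.asarray(true_lengths_kb, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("telomere lengths must be positive")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must lie in (1, 2]")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(efficiency)  # Ct per log10(molecules)

    def ct_of(molecules, intercept):
        return intercept + slope * np.log10(molecules)

    std_molecules = standard_top_molecules / 10.0 ** np.arange(n_dilutions)
    standards = {}
    for target, intercept in (("telomere", tel_intercept), ("scg", scg_intercept)):
        cts = ct_of(std_molecules, intercept) + rng.normal(0, noise_sd_ct, n_dilutions)
        standards[target] = pd.DataFrame({"target": target,
                                          "molecules": std_molecules, "ct": cts})
    genomes = scg_molecules_per_sample / 2.0
    mol_tel = lengths * genomes * 1000.0 / TELOMERE_OLIGO_BP
    sample_ids = _sample_ids(lengths.size)
    recs = []
    for sid, mt in zip(sample_ids, mol_tel):
        recs.append({"sample_id": sid, "target": "telomere",
                     "ct": float(ct_of(mt, tel_intercept)
                                 + rng.normal(0, noise_sd_ct))})
        recs.append({"sample_id": sid, "target": "scg",
                     "ct": float(ct_of(scg_molecules_per_sample, scg_intercept)
                                 + rng.normal(0, noise_sd_ct))})
    samples = pd.DataFrame(recs)
    truth = CohortTruth(sample_ids, lengths_kb=lengths)
    return {"samples": samples, "telomere_standards": standards["telomere"],
            "scg_standards": standards["scg"], "truth": truth}
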