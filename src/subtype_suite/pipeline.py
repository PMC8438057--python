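"""End-to-end orchestration: synthesize or load, cluster, enrich, score CNAs,
project signatures, stratify survival — from one validated config.

Stages communicate through files and explicit label vectors (pure dataflow):
the expression-cluster assignment feeds the CNA subsets, the signature group
comparison and the survival grouping, and can be replaced by user-supplied
labels. The run report is machine-readable JSON with deterministic key
order and a full parameter/seed echo, so a repeated run with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, clustering, cna, gsea, signatures as sigs, survival, synthetic
from .io_core import write_matrix, write_segments

logger = logging.getLogger(__name__)

STAGES = ("synth", "cluster", "de", "gsea", "cna", "signatures", "survival", "assays")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # synth parameters
    n_genes: int = 800
    n_samples: int = 120
    k_true: int = 3
    cluster_sizes: tuple[int, ...] | None = None
    program_size: int = 60
    effect: float = 2.0
    noise_sd: float = 1.0
    n_signatures: int = 5
    active_signatures: tuple[int, ...] = (0, 2)
    mutations_per_sample: int = 1000
    hazard_base: float = 0.03
    hazard_ratio_per_cluster: float = 1.6
    arm_effect: float = 0.6
    censor_rate: float = 0.3
    # analysis parameters
    sd_threshold: float = 0.5
    k_min: int = 2
    k_max: int = 8
    consensus_iterations: int = 100
    subsample_frac: float = 0.8
    de_n_perm: int = 200
    gsea_n_perm: int = 100
    gsea_fdr_cut: float = 0.05
    cna_n_perm: int = 200
    cna_spacing: int = 1_000_000
    cna_q_threshold: float = 0.25
    signature_max_size: int = 4
    signature_tol_drop: float = 0.02

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not self.stages:
            raise ValueError("nothing to run: no stage enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cluster_sizes", "active_signatures", "stages"):
            if key in raw and raw[key] is not None and key != "stages":
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(stage_results: dict, path) -> None:
    """Serialize stage results as JSON with deterministic key order."""
    if not stage_results:
        raise ValueError("at least one stage result required")
    with open(path, "w") as fh:
        json.dump(_jsonable(stage_results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # parameter echo for reproducibility; the output path is location, not result
    echo = {k: v for k, v in config.__dict__.items() if k != "out_dir"}
    report: dict = {"config": _jsonable(echo)}
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FNS[stage](config, state, report, out)
        except Exception as exc:
            report[stage] = {"status": "incomplete", "error": str(exc)}
            write_report(report, out / "report.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    write_report(report, out / "report.json")
    return report


def _stage_synth(config, state, report, out):
    sizes = config.cluster_sizes
    if sizes is None:
        base = np.full(config.k_true, config.n_samples // config.k_true)
        base[: config.n_samples % config.k_true] += 1
        sizes = tuple(int(x) for x in base)
    matrix, truth = synthetic.make_expression(
        config.n_genes, config.n_samples, config.k_true, sizes,
        config.program_size, config.effect, config.noise_sd, seed=config.seed)
    genome = synthetic.default_genome()
    peaks = [synthetic.PeakSpec(1, "1", 30_000_000, 40_000_000, 0.8, 0.6),
             synthetic.PeakSpec(2, "2", 60_000_000, 68_000_000, -0.8, 0.6)]
    segs, cna_truth = synthetic.make_cna_cohort(
        truth.cluster, peaks, genome, synthetic.Del13qSpec(),
        seed=config.seed + 1)
    W = synthetic.make_signature_matrix(config.n_signatures, seed=config.seed + 2)
    fracs = np.zeros((config.n_samples, config.n_signatures))
    active = list(config.active_signatures)
    rng = np.random.default_rng(config.seed + 3)
    raw = rng.dirichlet(np.ones(len(active)), size=config.n_samples)
    fracs[:, active] = raw
    catalog, sig_truth = synthetic.make_mutation_catalog(
        W, fracs, config.mutations_per_sample, seed=config.seed + 4)
    hazards = {c + 1: config.hazard_base * config.hazard_ratio_per_cluster**c
               for c in range(config.k_true)}
    clinical, surv_truth = synthetic.make_clinical(
        truth.cluster, hazards, config.arm_effect, config.censor_rate,
        seed=config.seed + 5)
    qpcr = synthetic.make_qpcr(rng.uniform(2.0, 9.0, size=8), seed=config.seed + 6)
    state.update(matrix=matrix, truth=truth, genome=genome, segments=segs,
                 cna_truth=cna_truth, signature_matrix=W, catalog=catalog,
                 sig_truth=sig_truth, clinical=clinical, qpcr=qpcr)
    write_matrix(matrix, out / "expression.tsv")
    write_segments(segs, out / "segments.seg")
    catalog.to_frame().to_csv(out / "mutation_catalog.tsv", sep="\t")
    W.to_frame().to_csv(out / "signature_matrix.tsv", sep="\t")
    clinical.data.to_csv(out / "clinical.tsv", sep="\t", index=False)
    report["synth"] = {"status": "ok", "seed": config.seed,
                       "n_genes": config.n_genes, "n_samples": config.n_samples,
                       "cluster_sizes": list(sizes)}


def _stage_cluster(config, state, report, out):
    filtered = clustering.variance_filter(state["matrix"], config.sd_threshold)
    result = clustering.consensus_cluster(
        filtered, range(config.k_min, config.k_max + 1),
        iterations=config.consensus_iterations,
        subsample_frac=config.subsample_frac, seed=config.seed + 10)
    selection = clustering.select_k(result)
    k = selection.selected_k
    labels = result.assignments[k]
    state.update(labels=labels, consensus=result, selection=selection)
    np.savetxt(out / "cluster_assignments.tsv",
               np.column_stack([result.sample_ids, labels.astype(str)]),
               fmt="%s", delimiter="\t", header="sample_id\tcluster", comments="")
    report["cluster"] = {
        "status": "ok", "seed": config.seed + 10,
        "n_features_kept": filtered.shape[0],
        "selected_k": k, "no_structure": selection.no_structure,
        "delta_areas": {str(kk): v for kk, v in selection.delta_areas.items()},
    }


def _stage_de(config, state, report, out):
    labels = state["labels"]
    k = int(labels.max())
    n_sig = {}
    for cluster in range(1, k + 1):
        if (labels == cluster).sum() < 2:
            continue
        de = gsea.class_comparison(state["matrix"], labels, cluster,
                                   n_perm=config.de_n_perm,
                                   seed=config.seed + 20 + cluster)
        de.to_csv(out / f"de_cluster{cluster}.tsv", sep="\t")
        n_sig[str(cluster)] = int(((de["q"] <= 0.05)
                                   & (de["fold_change"].abs() >= 1)).sum())
    report["de"] = {"status": "ok", "seed": config.seed + 20,
                    "n_significant_q05_fc2": n_sig}


def _stage_gsea(config, state, report, out):
    from .io_core import GeneSet, GeneSetCollection
    # gene sets matching the planted programs, plus decoys
    feature_ids = state["matrix"].feature_ids
    ps = config.program_size
    sets = {}
    for c in range(config.k_true):
        members = tuple(feature_ids[c * ps: (c + 1) * ps])
        sets[f"PROGRAM_{c + 1}"] = GeneSet(f"PROGRAM_{c + 1}", "planted", members)
    rng = np.random.default_rng(config.seed + 30)
    for d in range(3):
        members = tuple(rng.choice(feature_ids, size=ps, replace=False))
        sets[f"DECOY_{d + 1}"] = GeneSet(f"DECOY_{d + 1}", "random", members)
    collection = GeneSetCollection(sets)
    nes = gsea.enrichment_matrix(state["matrix"], state["labels"], collection,
                                 fdr_cut=config.gsea_fdr_cut,
                                 n_perm=config.gsea_n_perm,
                                 seed=config.seed + 31)
    nes.to_csv(out / "nes_matrix.tsv", sep="\t")
    report["gsea"] = {"status": "ok", "seed": config.seed + 31,
                      "n_sets_passing": int(nes.shape[1]),
                      "sets": sorted(nes.columns.tolist())}


def _stage_cna(config, state, report, out):
    genome = state["genome"]
    markers = cna.segments_to_markers(state["segments"], genome,
                                      spacing=config.cna_spacing)
    sample_ids = state["segments"].sample_ids
    labels = state["labels"][: len(sample_ids)]
    peak_summary = {}
    for cluster in sorted(set(labels.tolist())):
        subset = [s for s, l in zip(sample_ids, labels) if l == cluster]
        if len(subset) < 5:
            continue
        track = cna.gistic_lite(markers, subset, n_perm=config.cna_n_perm,
                                q_threshold=config.cna_q_threshold,
                                seed=config.seed + 40 + cluster)
        track.peaks.to_csv(out / f"peaks_cluster{cluster}.tsv", sep="\t", index=False)
        peak_summary[str(cluster)] = int(len(track.peaks))
    calls = cna.classify_del13q_cohort(state["segments"], genome)
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(
        out / "del13q_calls.tsv", sep="\t", index=False)
    n_by_status = {s: sum(c.status == s for c in calls)
                   for s in ("none", "typeI", "typeII")}
    report["cna"] = {"status": "ok", "seed": config.seed + 40,
                     "peaks_per_cluster": peak_summary,
                     "del13q_status_counts": n_by_status}


def _stage_signatures(config, state, report, out):
    selection = sigs.select_signatures(state["catalog"], state["signature_matrix"],
                                       max_size=config.signature_max_size,
                                       tol_drop=config.signature_tol_drop,
                                       seed=config.seed + 50)
    projection = sigs.project_activations(
        state["catalog"], state["signature_matrix"].subset(list(selection.selected)),
        seed=config.seed + 51)
    frame = pd.DataFrame(projection.fractions, index=projection.signature_names,
                         columns=projection.sample_ids)
    frame.to_csv(out / "signature_fractions.tsv", sep="\t")
    state["signature_selection"] = selection
    report["signatures"] = {
        "status": "ok", "seed": config.seed + 50,
        "selected": list(selection.selected),
        "cost_curve": {str(s): c for s, c in selection.cost_curve.items()},
    }


def _stage_survival(config, state, report, out):
    clin = state["clinical"].data
    groups = [(clin.loc[clin["cluster"] == c, "pfs_time"].to_numpy(),
               clin.loc[clin["cluster"] == c, "pfs_event"].to_numpy())
              for c in sorted(clin["cluster"].unique())]
    lr = survival.logrank(groups)
    fit = survival.cox_fit(clin["pfs_time"], clin["pfs_event"],
                           clin[["arm"]].astype(float))
    medians = {}
    for c in sorted(clin["cluster"].unique()):
        sub = clin[clin["cluster"] == c]
        curve = survival.km_estimate(sub["pfs_time"], sub["pfs_event"])
        medians[str(c)] = curve.median if curve.median_reached else "not reached"
    fit.summary().to_csv(out / "cox_arm.tsv", sep="\t")
    report["survival"] = {
        "status": "ok",
        "logrank_chi2": lr.statistic, "logrank_p": lr.p_value,
        "arm_hr": float(fit.hr[0]), "arm_hr_ci": [float(fit.ci_lower[0]),
                                                  float(fit.ci_upper[0])],
        "median_pfs_by_cluster": medians,
    }


def _stage_assays(config, state, report, out):
    q = state["qpcr"]
    lengths = assays.telomere_qpcr_length(q["samples"], q["telomere_standards"],
                                          q["scg_standards"])
    lengths.to_csv(out / "telomere_lengths.tsv", sep="\t")
    err = float(np.max(np.abs(lengths["length_kb"].to_numpy()
                              - q["truth"].lengths_kb)))
    report["assays"] = {"status": "ok",
                        "max_abs_length_error_kb": err,
                        "median_length_kb": float(lengths["length_kb"].median())}


_STAGE_FNS = {
    "synth": _stage_synth, "cluster": _stage_cluster, "de": _stage_de,
    "gsea": _stage_gsea, "cna": _stage_cna, "signatures": _stage_signatures,
    "survival": _stage_survival, "assays": _stage_assays,
}
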