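#!/usr/bin/env python
"""Simulate the full multi-platform cohort used by the downstream analyses.

Writes a 2000-gene x 337-sample expression matrix with six planted clusters
of the discovered unequal sizes (133/56/30/100/11/7), a segmented
copy-number cohort with cluster-specific peaks and mixed del(13q)
architectures, a 96-channel mutation catalog drawn from two active
signatures, a clinical table with subtype-dependent hazards, and a
noise-free qPCR telomere run — plus the planted truth for each.
"""

import json
from pathlib import Path

import numpy as np

from subtype_suite.io_core import write_matrix, write_segments
from subtype_suite.synthetic import (Del13qSpec, PeakSpec, default_genome,
                                     make_clinical, make_cna_cohort,
                                     make_expression, make_mutation_catalog,
                                     make_qpcr, make_signature_matrix)

SEED = 20260101
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, truth = make_expression(seed=SEED)
    write_matrix(matrix, OUT / "expression.tsv")

    genome = default_genome()
    genome.to_yaml(OUT / "genome.yaml")
    peaks = [PeakSpec(1, "1", 30_000_000, 40_000_000, 0.8, 0.5),
             PeakSpec(2, "2", 60_000_000, 70_000_000, -0.8, 0.5),
             PeakSpec(4, "3", 10_000_000, 18_000_000, 0.6, 0.4)]
    segs, cna_truth = make_cna_cohort(truth.cluster, peaks, genome,
                                      Del13qSpec(rate=0.55), seed=SEED + 1)
    write_segments(segs, OUT / "segments.seg")

    W = make_signature_matrix(5, seed=0)
    W.to_frame().to_csv(OUT / "signature_matrix.tsv", sep="\t")
    rng = np.random.default_rng(SEED + 2)
    fractions = np.zeros((len(truth.sample_ids), 5))
    fractions[:, [0, 2]] = rng.dirichlet(np.ones(2), len(truth.sample_ids))
    catalog, sig_truth = make_mutation_catalog(W, fractions, 1000, seed=SEED + 3)
    catalog.to_frame().to_csv(OUT / "mutation_catalog.tsv", sep="\t")

    hazards = {c: 0.03 * 1.6 ** (c - 1) for c in range(1, 7)}
    clinical, _ = make_clinical(truth.cluster, hazards, arm_effect=0.6,
                                censor_rate=0.3, seed=SEED + 4)
    clinical.data.to_csv(OUT / "clinical.tsv", sep="\t", index=False)

    qpcr = make_qpcr(rng.uniform(2.0, 9.0, size=24), seed=SEED + 5)
    qpcr["samples"].to_csv(OUT / "qpcr_samples.tsv", sep="\t", index=False)
    qpcr["telomere_standards"].to_csv(OUT / "qpcr_telomere_standards.tsv",
                                      sep="\t", index=False)
    qpcr["scg_standards"].to_csv(OUT / "qpcr_scg_standards.tsv",
                                 sep="\t", index=False)

    json.dump({
        "seed": SEED,
        "true_cluster": truth.cluster.tolist(),
        "sample_ids": truth.sample_ids,
        "del13q_truth": cna_truth.del13q,
        "active_signatures": ["SigSyn1", "SigSyn3"],
        "true_lengths_kb": qpcr["truth"].lengths_kb.tolist(),
    }, open(OUT / "truth.json", "w"), indent=2)
    print(f"cohort written to {OUT}: {matrix.shape[0]} genes x "
          f"{matrix.shape[1]} samples, {len(segs.data)} segments, "
          f"{catalog.counts.sum()} mutations")


if __name__ == "__main__":
    main()
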