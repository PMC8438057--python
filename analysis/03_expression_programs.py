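#!/usr/bin/env python
"""Characterize each discovered subtype's expression program.

One-vs-rest differential expression (Welch t with permutation p, BH q) per
cluster, then one-vs-rest GSEA against gene sets matching the planted
programs plus random decoys, producing the cluster x gene-set NES matrix.
The planted program of each cluster should dominate its own contrast.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from subtype_suite.gsea import class_comparison, enrichment_matrix
from subtype_suite.io_core import GeneSet, GeneSetCollection, read_matrix

SEED = 20260121
BASE = Path(__file__).resolve().parents[1] / "results"
PROGRAM_SIZE = 100


def main() -> None:
    matrix = read_matrix(BASE / "cohort" / "expression.tsv")
    labels = pd.read_csv(BASE / "subtypes" / "assignments.tsv", sep="\t"
                         ).set_index("sample_id").loc[matrix.sample_ids,
                                                      "cluster"].to_numpy()
    out = BASE / "programs"
    out.mkdir(parents=True, exist_ok=True)

    n_sig = {}
    for cluster in sorted(set(labels.tolist())):
        # 2000 permutations keep the p floor (1/2001) well under the BH cut
        # even for the 100-gene programs of the smallest clusters
        de = class_comparison(matrix, labels, cluster, n_perm=2000,
                              seed=SEED + cluster)
        de.to_csv(out / f"de_cluster{cluster}.tsv", sep="\t")
        n_sig[cluster] = int(((de["q"] <= 0.05)
                              & (de["fold_change"].abs() >= 1)).sum())
    print("significant genes (q <= 0.05, |log2 FC| >= 1) per cluster:", n_sig)

    sets = {}
    for c in range(6):
        members = tuple(matrix.feature_ids[c * PROGRAM_SIZE:
                                           (c + 1) * PROGRAM_SIZE])
        sets[f"PROGRAM_{c + 1}"] = GeneSet(f"PROGRAM_{c + 1}", "planted", members)
    rng = np.random.default_rng(SEED)
    background = matrix.feature_ids[6 * PROGRAM_SIZE:]  # genes in no program
    for d in range(4):
        members = tuple(rng.choice(background, size=PROGRAM_SIZE,
                                   replace=False))
        sets[f"DECOY_{d + 1}"] = GeneSet(f"DECOY_{d + 1}", "random", members)
    nes = enrichment_matrix(matrix, labels, GeneSetCollection(sets),
                            fdr_cut=0.05, n_perm=200, seed=SEED)
    nes.to_csv(out / "nes_matrix.tsv", sep="\t")
    print(f"{nes.shape[1]} gene sets pass FDR <= 0.05 in >= 1 contrast; "
          f"NES matrix written to {out / 'nes_matrix.tsv'}")


if __name__ == "__main__":
    main()
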