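#!/usr/bin/env python
"""Discover expression subtypes by resampling consensus clustering.

Filters the simulated cohort to variable genes (SD > 0.5), runs consensus
clustering for k = 2..10 (200 resampling iterations, Pearson distance),
reports the delta-area / stability profiles behind the k choice, and writes
the chosen assignment. Prints the adjusted Rand index against the planted
truth — expected ~1.0 at the planted k = 6.
"""

import json
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from subtype_suite.clustering import (consensus_cluster, select_k,
                                      variance_filter)
from subtype_suite.io_core import read_matrix

SEED = 20260111
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = read_matrix(BASE / "cohort" / "expression.tsv")
    truth = json.load(open(BASE / "cohort" / "truth.json"))
    filtered = variance_filter(matrix)
    print(f"{filtered.shape[0]} / {matrix.shape[0]} genes pass SD > 0.5")
    result = consensus_cluster(filtered, range(2, 11), iterations=200,
                               seed=SEED)
    selection = select_k(result)
    k = selection.selected_k
    labels = result.assignments[k]
    ari = adjusted_rand_score(truth["true_cluster"], labels)
    out = BASE / "subtypes"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": result.sample_ids, "cluster": labels}
                 ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame({
        "k": result.k_range,
        "area": [result.areas[kk] for kk in result.k_range],
        "delta_area": [result.delta_areas[kk] for kk in result.k_range],
        "min_stability": [selection.min_stability[kk] for kk in result.k_range],
    }).to_csv(out / "k_selection_profile.tsv", sep="\t", index=False)
    print(f"selected k = {k} (no_structure={selection.no_structure}); "
          f"ARI vs planted truth = {ari:.3f}")


if __name__ == "__main__":
    main()
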