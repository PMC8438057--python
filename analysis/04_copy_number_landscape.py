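#!/usr/bin/env python
"""Copy-number landscape per subtype: G-score peaks and del(13q) architecture.

Rasterizes the simulated segments (five-marker / |log2| > 0.2 filters),
computes per-cluster G-score significance tracks with the circular-shift
permutation null (q <= 0.25 peaks), classifies each sample's 13q deletion
(type I/II, long distal break, biallelic), and runs the cohort association
statistics between deletion architecture and subtype supergroups.
"""

import json
from pathlib import Path

import pandas as pd

from subtype_suite.cna import (classify_del13q_cohort, del13q_cohort_stats,
                               GenomeConfig, gistic_lite, segments_to_markers)
from subtype_suite.io_core import read_segments

SEED = 20260131
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    genome = GenomeConfig.from_yaml(BASE / "cohort" / "genome.yaml")
    segments = read_segments(BASE / "cohort" / "segments.seg")
    truth = json.load(open(BASE / "cohort" / "truth.json"))
    labels = pd.read_csv(BASE / "subtypes" / "assignments.tsv", sep="\t")
    out = BASE / "copy_number"
    out.mkdir(parents=True, exist_ok=True)

    markers = segments_to_markers(segments, genome,
                                  sample_ids=truth["sample_ids"])
    for cluster, grp in labels.groupby("cluster"):
        subset = grp["sample_id"].tolist()
        if len(subset) < 5:
            print(f"cluster {cluster}: {len(subset)} samples, skipped")
            continue
        track = gistic_lite(markers, subset, n_perm=1000, seed=SEED + cluster)
        track.peaks.to_csv(out / f"peaks_cluster{cluster}.tsv", sep="\t",
                           index=False)
        print(f"cluster {cluster} (n={len(subset)}): "
              f"{len(track.peaks)} significant peak(s) at q <= 0.25")

    calls = classify_del13q_cohort(segments, genome)
    call_df = pd.DataFrame([c.__dict__ for c in calls])
    call_df.to_csv(out / "del13q_calls.tsv", sep="\t", index=False)
    counts = call_df["status"].value_counts().to_dict()
    print("del(13q) architecture counts:", counts)

    label_map = dict(zip(labels["sample_id"], labels["cluster"].astype(str)))
    report = del13q_cohort_stats(calls, label_map,
                                 supergroup_a={"1", "2"},
                                 supergroup_b={"3", "4", "5", "6"})
    t2 = report["type2_by_supergroup"]["test"]
    co = report["ldb_type2_cooccurrence"]
    print(f"type II enrichment between supergroups: "
          f"p = {t2.p_value:.3g}" if t2 else "type II test: NA (zero margin)")
    if co["test"]:
        print(f"LDB/type II co-occurrence: {co['x']}/{co['n']} "
              f"(p = {co['test'].p_value:.3g}, one-sample proportions)")


if __name__ == "__main__":
    main()
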