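# subtype-suite

Multi-platform subtype discovery for chronic lymphocytic leukemia (CLL)
cohorts, built as a reusable, fully tested pipeline: resampling consensus
clustering of expression profiles, one-vs-rest differential expression and
gene-set enrichment (GSEA), GISTIC-style copy-number peak significance,
structural classification of del(13q) (type I/II, long distal breaks,
biallelic loss), projection of 96-channel mutation catalogs onto fixed
mutational signatures with parsimonious signature-set selection,
Kaplan–Meier / log-rank / Cox survival stratification, and the
deterministic assay calculators (absolute telomere qPCR, ΔΔCt, RRBS
methylation summaries). A synthetic-cohort generator plants ground truth
for every stage, so the whole pipeline is testable end to end with no
external data.

It is written for computational biologists who want the statistical core
of this kind of integrative CLL study as an importable library (plus a
thin CLI), rather than a collection of one-off scripts around array
platforms they no longer run.

## The methods at the core

* **Consensus clustering** (Monti-style): repeatedly subsample 80% of
  samples, cluster by agglomerative linkage under Pearson distance
  `d = 1 − r`, and record co-clustering frequencies; `consensus(i,j) =`
  co-cluster count / co-draw count. The cluster number k is chosen from
  the delta-area profile of the consensus CDF, `Δ(k) = (A(k) −
  A(k−1))/A(k−1)`, refined by per-cluster stability (mean within-cluster
  consensus); the selection is reported with its full profile, never
  silently enforced.
* **GSEA**: weighted Kolmogorov–Smirnov running sum; hits add
  `|s|^w / Σ_hits |s|^w`, misses subtract `1/(N − N_hits)`; ES is the
  signed maximum deviation, `NES = ES / mean |null ES of matching sign|`,
  FDR by sign-matched ratio-of-tails over the pooled permutation null.
* **G-scores**: per marker and direction, amplitude × frequency,
  `G(m) = Σ_samples max(±value, 0)/N`, after the segment filters (≥ 5
  markers, |log2| > 0.2, cap ±2). The null circularly shifts each
  sample's genome-wide marker vector; peaks are runs with BH q ≤ 0.25.
* **del(13q) architecture**: type II iff a qualifying 13q loss overlaps
  RB1; long distal break (LDB) iff the loss extends strictly beyond
  54.7 Mb; biallelic iff log2 ≤ −0.9.
* **Signature projection**: with fixed signatures W, activations H
  minimize generalized KL divergence via `H ← H ⊙ (Wᵀ(V⊘WH)) ⊘ (Wᵀ1)`;
  the selected signature set is the smallest whose enlargement no longer
  drops the cost by ≥ 2%.
* **Survival**: product-limit curves, the O−E log-rank chi-square, and
  Newton–Raphson Cox partial-likelihood fits (Efron or Breslow ties,
  Wald 95% CIs, explicit separation flagging).

## Worked example

The `analysis/` directory is a numbered, narrative walk through a full
cohort. `01_simulate_cohort.py` writes a 2000-gene × 337-sample expression
matrix with six planted clusters (sizes 133/56/30/100/11/7), segmented
copy-number profiles, a mutation catalog built from two active signatures,
a clinical table, and a qPCR run under `results/cohort/`. The later
scripts then analyze it:

```text
$ python analysis/02_discover_subtypes.py
2000 / 2000 genes pass SD > 0.5
selected k = 6 (no_structure=False); ARI vs planted truth = 1.000

$ python analysis/03_expression_programs.py
significant genes (q <= 0.05, |log2 FC| >= 1) per cluster: {1: 63, 2: 118, 3: 182, 4: 127, 5: 143, 6: 128}
6 gene sets pass FDR <= 0.05 in >= 1 contrast; NES matrix written to results/programs/nes_matrix.tsv

$ python analysis/06_survival_stratification.py
median PFS by cluster (months): {1: 1.6, 2: 3.54, 3: 8.14, 4: 12.14, 5: 24.42, 6: 13.68}
log-rank across clusters: chi2 = 57.25 (df 5), p = 4.49e-11
arm HR = 0.706 (95% CI 0.544-0.916); cluster-adjusted arm HR = 0.632
```

Reading those numbers: consensus clustering recovers the six planted
subtypes exactly (adjusted Rand index 1.0) and the delta-area/stability
report picks k = 6; each subtype's one-vs-rest contrast recovers its
planted 100-gene program (the NES matrix is diagonal-positive and the
four decoy sets are excluded at FDR ≤ 0.05); and the survival stage
separates the clusters (planted hazards rise 1.6-fold per cluster) while
estimating the planted treatment effect (arm hazard ratio 0.6) with its
confidence interval. `04_copy_number_landscape.py`,
`05_mutational_signatures.py` and `07_telomere_assays.py` do the same for
peaks/del(13q), signature selection (recovering the planted SigSyn1 +
SigSyn3 support), and telomere lengths (exact recovery under noise-free
qPCR).

The same stages are available as a CLI (`subtype-suite synth | cluster |
de | gsea | cna | signatures | survival | assays | run`) driven by flags
or one YAML config; `subtype-suite run --config cfg.yaml` executes the
whole pipeline and writes a deterministic, machine-readable
`report.json`.

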