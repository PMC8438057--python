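# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, a
multi-platform subtype-discovery analysis for chronic lymphocytic leukemia
(CLL): expression-based consensus clustering, per-subtype gene-set
enrichment, copy-number peak significance, structural classification of
13q14 deletions, projection of mutation catalogs onto fixed mutational
signatures, survival stratification, and the small deterministic assay
calculators (telomere qPCR, delta-delta-Ct, RRBS summaries). Real
patient-level trial data are not distributed with the package; every stage
is exercised against simulated cohorts with planted ground truth, so each
method's output can be scored against what was planted.

## Subtype discovery by consensus clustering

Expression input is a features x samples matrix of log2-scale values,
assumed pre-normalized. Unspecific variance filtering keeps genes with
across-sample standard deviation strictly above 0.5 (n-1 denominator).
Consensus clustering repeats, for a configurable number of iterations
(default 1000; the analysis scripts use 200, which the convergence
property test shows is already stable at these cohort sizes): draw 80% of
samples without replacement, cluster the subsample agglomeratively under
Pearson correlation distance (1 - r, not 1 - |r|), and cut the tree at
every k in 2..10. The consensus matrix entry for a sample pair at a given
k is the fraction of co-draws in which the pair co-clustered. Because the
reference procedure lists "average or complete" linkage without mapping
them to roles, the inner (subsample) linkage defaults to average and the
final cut over 1 - consensus to complete; both are configurable.

k selection combines the delta-area profile with cluster stability. A(k)
is the area under the empirical CDF of the upper-triangle consensus
entries; delta(k) is A(2) for the first k and the relative increment
otherwise. Two facts, both reproducible with the synthetic generator,
shape the rule:

* the area increment from resolving a cluster that holds a few percent of
  the cohort is quadratically small in its size (pair mass), so a pure
  delta threshold can never see an 11-of-300 cluster;
* on a null cohort the raw increments stay large for many k (resampled
  noise keeps shifting consensus mass), so a delta threshold alone cannot
  flag the absence of structure either.

A candidate k therefore counts as evidence of structure only if
delta(k) >= epsilon (default 0.03) **and** its least stable cluster keeps
mean within-cluster consensus >= 0.8. The largest such k is the elbow;
among k at or above the elbow, the k with the highest minimum per-cluster
stability wins (smallest k on ties). If no k qualifies, selection falls
back to the smallest k with a `no_structure` flag. The full delta and
stability profiles are always reported: the original discovery also used
clinical and biological information, and the selection here is a report,
not an enforcement.

## Differential expression and GSEA

One-vs-rest class comparison uses the unequal-variance t statistic with a
label-permutation p-value (exact fraction over all arrangements when their
count is <= 20,000, otherwise the add-one estimator over sampled
permutations) and Benjamini-Hochberg q-values. The permutation engine is
vectorized across genes but property-tested equal, gene by gene, to the
scalar permutation routine.

The enrichment score is the weighted Kolmogorov-Smirnov running sum
(weight exponent 1): hits add |score|^w normalized over the set's hits,
misses subtract 1/(N - N_hits); ES is the signed maximum deviation.
Phenotype permutation re-ranks genes by signal-to-noise (with the
reference tool's SD floor) under shuffled sample labels; preranked
permutation redraws gene identities. NES divides ES by the mean |null ES|
of matching sign, and the FDR is the sign-matched ratio-of-tails over the
pooled normalized null — the conventions of the widely used GSEA
implementation, chosen so that q <= 0.05 means the same thing here as
there. Set-size bounds default to 5..500.

## Copy-number analysis

Segments arrive in SEG coordinates (1-based inclusive on disk, converted
to 0-based half-open internally) and pass two filters before anything
else: at least five markers and |log2 ratio| strictly greater than 0.2.
Surviving segments are painted, clipped to +/-2 (to bound single-sample
dominance), onto a uniform marker grid (default 1 Mb; the original works
on SNP-array markers that this pipeline does not reproduce, and the grid
preserves the score's semantics). The per-marker G-score per direction is
aberration amplitude x frequency: sum of positive (or negative) values
over samples divided by cohort size.

Significance uses a permutation null that operationalizes "the overall
pattern of aberrations seen across the genome": each permutation
circularly shifts every sample's whole-genome marker vector by an
independent uniform offset, preserving per-sample burden and segment
lengths while randomizing location. Per-marker p-values count permutations
with G at least the observed value (add-one estimator), BH correction runs
per direction, and peaks are maximal same-chromosome runs of markers with
q <= 0.25. This is an explicitly simplified re-implementation of the
described scoring, not a GISTIC2 clone: no arm-level analysis, no
peel-off, no gene-level deconvolution.

del(13q) architecture is a pure function of one sample's chr13 segments
plus an annotation config (RB1 interval, long-distal-break boundary,
default 54,700,000 bp on hg18 coordinates; gene coordinates are never
hard-coded). Qualifying losses pass the same segment filters. A deletion
is type II if any qualifying loss overlaps RB1 (half-open interval
overlap), type I otherwise; LDB if the most distal loss boundary is
strictly beyond the cutoff; biallelic if any loss reaches log2 <= -0.9.
The amplitude rule stands in for genotype-based biallelic detection, which
needs allele data this pipeline does not model; the spec's alternative
trigger (two overlapping annotated loss segments) is unavailable because
the segment table forbids within-sample overlaps by construction. Cohort
statistics (type II and LDB enrichment between subtype supergroups,
LDB-type II co-occurrence against p0 = 0.5) use Fisher's exact test and
the continuity-corrected one-sample proportions test; zero-margin tables
are reported NA rather than tested.

## Mutational-signature projection

Catalogs are 96-channel single-base-substitution counts in canonical
COSMIC channel order (substitution-major, then 5' and 3' context). With a
fixed signature matrix W (columns on the simplex), activations H solve the
generalized Kullback-Leibler NMF problem by the multiplicative update
`H <- H * (W^T(V/(WH))) / (W^T 1)` with 1e-12 guards; with W fixed the
problem is convex in H, so the uniform-positive seeded initialization
affects only iteration count, and the cost trajectory — certified
monotone non-increasing in tests — is returned. Convergence is a relative
cost change below 1e-6 (10,000-iteration cap). KL divergence is the
natural cost for count data; a Frobenius option was considered and
dropped as out of scope for the count catalogs used here.

Parsimonious selection scans subset sizes 1..max_size, exhaustively when
C(S, s) <= 10,000 and by greedy forward search from the previous best
subset otherwise (ties at a size broken lexicographically). "Large drop"
is operationalized as relative cost improvement >= tol_drop (default
0.02) when adding one signature; the selected size is the smallest s
whose improvement to s+1 falls below that, and tol_drop = 0 degenerates
to max_size by construction. The full cost curve is always emitted so the
elbow can be inspected. Group comparisons of activation fractions use the
two-sided Mann-Whitney test; a median-centered fraction table is provided
for heatmap-style display.

## Survival

Kaplan-Meier estimation, the two-sided non-stratified log-rank test
(O-E chi-square with k-1 degrees of freedom via the generalized inverse of
the covariance of the first k-1 groups), and Cox proportional-hazards
regression are implemented directly: the contract requires both Efron
(default) and Breslow tie handling and an explicit monotone-likelihood
flag, and the surrounding ecosystem's fitters expose only part of that.
lifelines serves as an independent cross-check in the tests, alongside
grid-search maximization of literally coded partial likelihoods. Newton's
method with step halving converges at |delta log-likelihood| < 1e-9 (100
iterations); coefficients beyond |beta| > 10 are flagged as
non-convergence (complete separation), never returned silently. Wald 95%
intervals come from the inverse observed information. Conventions:
censoring at an event time is ordered after the event; the median is the
first time S(t) <= 0.5, with infinity as the not-reached sentinel; missing
covariates are handled complete-case, matching per-analysis varying n.

## Auxiliary assays

Absolute telomere length: both standard curves (telomere 84 bp and
single-copy-gene 81 bp oligos, tenfold dilution series) are ordinary
least-squares fits of Ct on log10(molecules); replicate sample Cts are
averaged on the Ct scale before conversion (the averaging order is not
specified by the source protocol; Ct-scale averaging is the common lab
convention). Telomere kilobases are molecules x 84 / 1000 and the
denominator is diploid genomes = single-copy-gene molecules / 2, following
the oligomer-standard absolute-qPCR method. Positive curve slopes are
rejected; sample Cts outside the standard range warn. The qPCR-to-TRF
calibration is a plain OLS map with R^2. Delta-delta-Ct fold change is
2^-((Ct_t,test - Ct_ref,test) - (Ct_t,ctrl - Ct_ref,ctrl)). RRBS
summaries drop CpGs under 10 reads, drop regions with fewer than 5
surviving CpGs, and average methylation fractions unweighted; promoters
are TSS +/- 2 kb regardless of strand.

## Synthetic cohorts: what they emulate, and what they do not

The generators are pure functions of parameters and seed and always emit
their ground truth. Defaults are the study conditions the pipeline is
tested under:

* **Expression**: 2000 genes x 337 samples, six clusters of sizes
  133/56/30/100/11/7 (the discovered unequal sizes, kept to stress
  small-cluster behavior), each cluster up-shifting a private 100-gene
  program by 2 log2 units over i.i.d. unit-variance Gaussian noise.
  Gaussian noise on the log2 scale is the simplest model consistent with
  Pearson-distance clustering; no probe-level artifacts, batch structure
  or correlated noise are simulated, so passing recovery tests shows the
  procedure works when its distance model is right, not that it survives
  array artifacts.
* **Copy number**: per-sample Poisson(2) background segments, lengths
  2-15 Mb, amplitudes uniform on +/-[0.2, 1.0] so the 0.2 filter is
  exercised at its boundary; planted peaks appear at a configured
  penetrance; 13q deletions mix type I/II, LDB and biallelic
  architectures with boundaries drawn around the RB1 interval and the
  54.7 Mb cutoff. The synthetic genome (4 x 120 Mb autosomes plus a
  full-length chr13) keeps permutation tests cheap without changing any
  scoring semantics.
* **Mutations**: per-sample 96-channel counts are
  Multinomial(n, W h_true); the bundled 5-profile signature catalog is a
  labelled synthetic stand-in (sparse Dirichlet profiles), not the COSMIC
  matrix, which users supply as a TSV when they have it.
* **Survival**: exponential event times with per-sample rate
  hazard(cluster) x arm_effect^arm and independent exponential censoring
  whose rate is chosen so the expected censored fraction equals the
  requested rate exactly.
* **qPCR**: Ct = intercept - log(molecules)/log(efficiency) + Gaussian
  noise; sample telomere molecule counts invert the length arithmetic, so
  the noise-free run is an exact identity through the length calculator.

Noise magnitudes are calibration choices for the test bed, not claims
about any clinical cohort.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` scale the study conditions to
desk size as the package's own choice of test bed: consensus recovery uses
the 337-sample cluster proportions rescaled to n = 300 with 200 resampling
iterations over 3-10 seeds; GSEA calibration uses 1000 random sets on a
400 x 30 null matrix with 200 permutations; G-score runs use 100-sample
cohorts with 500-1000 permutations; signature recovery uses 100 samples at
1000 mutations each; hazard recovery uses n = 2000. Headline numbers of
the original study that derive from patient-level trial data (cluster
sizes, hazard ratios, telomere medians, signature p-values, del(13q)
percentages) are not reproducible without those data and are therefore
documented but never asserted.

## Known limitations

* The G-score module is deliberately GISTIC-lite: no broad/focal
  separation, no peel-off, marker grid instead of real array markers.
* Biallelic del(13q) detection by amplitude is a proxy; genotype-based
  detection would need allele-specific data.
* The consensus k rule is a heuristic with two thresholds (epsilon,
  stability floor); cohorts whose smallest real cluster is unstable under
  resampling will be under-split, which is the designed trade-off.
* Exact statistical modes switch to asymptotics beyond enumeration limits
  (20 observations for rank tests, 20,000 arrangements for permutations);
  p-values near those switch points change discretely.
* GSEA nominal p and FDR inherit the reference tool's conventions
  (sign-matched tails, pooled null); they are not BH-adjusted p-values,
  and the two can disagree for small set collections.
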