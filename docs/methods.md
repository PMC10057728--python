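# Methods

## The analysis in one paragraph

A landrace core collection is genotyped as four single seeds per accession
and partitioned (by prior clustering, taken here as given labels) into a
"red" and a "blue" genetic cluster. Per-marker differentiation between the
clusters is measured by the fixation index; outlier markers are flagged by
an empirical percentile rule backed by a max-statistic permutation null,
merged into genomic regions and co-localized with candidate adaptation
genes. In parallel, grain-quality phenotypes (kernel geometry, CIELAB
colour, hardness, protein, kernel weights) are summarised per cluster,
contrasted nonparametrically, and fed to a PLS-DA that asks whether the
two genetic clusters are separable from quality traits alone. A digital-PCR
module converts chip well counts into gene copy-number calls.

## Differentiation estimator

The per-locus statistic is the Nei / Nei–Chesser decomposition with
sample-size corrections. For one biallelic marker and clusters
k ∈ {red, blue} with post-missing sample sizes n_k, allele frequencies p_k
and observed heterozygote fractions Ho_k:

    ñ   = harmonic mean of n_k
    Ho  = mean_k Ho_k
    Hs  = ñ/(ñ−1) · ( mean_k 2 p_k (1−p_k) − Ho/(2ñ) )
    Ht  = 2 p̄ (1−p̄) + Hs/(2ñ) − Ho/(4ñ),   p̄ = mean_k p_k
    Fst = 1 − Hs/Ht

Conventions that matter:

* missing calls are removed per marker within cluster (complete-case; no
  imputation);
* negative estimates are reported as computed — clipping would bias the
  percentile threshold;
* markers with Ht = 0 (monomorphic over both clusters) have no defined
  Fst; they are flagged and excluded from thresholding, never treated as
  zero, since silently keeping them would deflate the 99th percentile;
* a cluster with no data at a marker excludes that marker with its own
  flag. Both exclusion counts are surfaced in the scan metadata so users
  can reconcile flagged-outlier counts against marker totals.

A Weir–Cockerham θ estimator (two-population, biallelic) is available via
`estimator="wc"` for comparison; the two conventions differ for unbalanced
samples and the Nei form is the default throughout.

## Outlier thresholds

Two routes, used together:

* **Permutation null of the maximum.** Accession-to-cluster assignment is
  shuffled (cluster sizes preserved), the full scan recomputed, and the
  genome-wide maximum of defined Fst stored; 100 permutations by default.
  The permutation unit is the accession — its four seeds are not
  independent samples and move together. The observed labelling is not
  included in the null; the p-value for the observed maximum uses the
  standard +1 correction. The fraction of markers above the permutation
  threshold is reported (on realistic simulated data it exceeds several
  percent — the threshold is liberal by construction, which is exactly why
  a stricter rule is also provided).
* **Empirical 99th percentile.** The quantile (linear interpolation on
  sorted defined values) of the observed per-marker Fst; markers strictly
  above it are flagged, so ties at the threshold behave conservatively.

Flagged markers are merged per chromosome by single linkage: consecutive
flagged markers at most `max_gap_mb` apart (default 15 Mb, wide enough to
hold the broadest empirically reported cluster spans) join one region;
a singleton is a zero-width region. Genes from a BED annotation
(0-based half-open on disk, 1-based inclusive in memory) are attached to a
region when their intervals intersect; with a proximity window (default
5 Mb) padding-only matches are reported separately from strict overlaps.
Positions are stored in bp and reported in Mb with one decimal.

## Synthetic genotypes

The generator emulates the study design: 2 clusters × 12 accessions ×
4 single seeds, ~16,000 SNPs on the 21 bread-wheat chromosomes (1A–7D,
rounded lengths; only relative positions matter downstream), with a small
strongly differentiated minority (160 divergent loci by default, ~1% of
markers).

* **Neutral loci** follow the Balding–Nichols model: ancestral frequency
  p ~ U(0.05, 0.95); each cluster draws its frequency from
  Beta(p(1−c)/c, (1−p)(1−c)/c), whose variance is c·p(1−p). The per-deme
  drift is calibrated as c = 2F/(1+F) so that the *configured* F equals
  the expected two-cluster Fst the scan estimates: with two demes the Nei
  statistic is referenced to the pooled pair, not the unobservable
  ancestor, and two independent demes at drift c show pooled-pair
  differentiation (c/2)/(1−c/2). Without this calibration the generator's
  parameter would overstate the measurable differentiation by a factor of
  about two, and parameter-recovery checks would be ill-posed. (The mean
  per-locus estimate is still very slightly below F — a mean-of-ratios
  effect — but within ±0.01 at F = 0.05 over 5,000 loci.)
* **Divergent loci** are planted with a deterministic contrast: a midpoint
  q̄ ~ U(F/(1+F), 1/(1+F)) and cluster frequencies q̄ ± √(F·q̄(1−q̄)),
  randomised in sign, which fixes the parametric pairwise Fst of every
  divergent locus at exactly `fst_divergent`. Independent drift draws were
  deliberately not used here: at F = 0.6 the Balding–Nichols Beta is
  strongly U-shaped and both clusters land on the *same* frequency extreme
  at roughly two-thirds of loci, leaving most "divergent" loci
  undifferentiated — the opposite of the strongly differentiated minority
  the scan is meant to detect. As F → 1 the construction degenerates to
  opposite fixation.
* Dosages are Binomial(2, q_cluster) per seed; seeds are treated as
  independent draws from the cluster frequency (within-accession
  relatedness is not modelled); missingness is uniform at random; loci are
  independent (no linkage, no selfing structure despite wheat autogamy).

What passing simulation-based tests does **not** show: robustness to
linkage disequilibrium, to structured (platform-specific) missingness, to
within-accession relatedness, or to unbalanced cluster sizes beyond what
the estimator corrections handle.

## Kernel traits, colour, dPCR

* `V = π·L1·L2·L3/6` with diameters in mm gives mm³ (an occasional cm³
  label in the field literature for this equation is inconsistent with mm
  inputs; this package fixes mm in → mm³ out).
* Cluster summaries expose both averaging orders — mean of per-kernel
  volumes and the formula applied to mean diameters — because published
  tables mix them; with positively correlated kernel dimensions the
  mean-of-volumes is the larger of the two (Jensen-type gap), matching the
  small discrepancies seen between printed volumes and volumes recomputed
  from printed mean diameters.
* Colour: C\* = √(a\*² + b\*²); h° = atan2(b\*, a\*) in [0, 360); ΔE is
  CIE76 (Euclidean in Lab), computed only when the caller supplies a
  reference colour, with perceptibility at the 2.3 just-noticeable-
  difference convention that belongs to CIE76.
* dPCR: each well is positive with probability 1 − exp(−λv); the estimator
  λ = −ln(1 − k/n)/v with a delta-method 95% interval from the binomial
  variance of k/n. A saturated chip (k = n) is an error, not an estimate.
  The CNV is the target/reference concentration ratio; the integer copy
  call rounds half up (1.9 → 2, 1.0 → 1). Per-seed calls are never
  averaged across seeds of an accession, so mixed-copy accessions remain
  visible. Chip defaults: 20,000 wells of 0.809 nL.
* The Gaussian trait generator uses the published cluster means of the
  core collection for kernel diameters, redness, hue-consistent b\*,
  hardness and thousand-kernel weight; the remaining means and all SDs are
  single realistic choices for bread wheat (documented in
  `simulate.DEFAULT_TRAIT_PARAMS`), fixed once.

## Nonparametric machinery

Kruskal–Wallis H with tie correction; p from the χ² approximation with
k−1 df, or exactly by enumerating all assignments of the observed values
to groups of the observed sizes (`method="exact"`, feasible for n ≤ ~10;
at n ≤ 8 the χ² approximation can deviate from the exact p by more than
0.1, which is why the exact route exists). Post-hoc comparisons are
Dunn-type z-tests on mean ranks with the tie-corrected variance, Bonferroni
multiplied over all pairs within one trait/context, and rendered as a
compact-letter display via the insert-and-absorb algorithm with groups
ordered by mean rank (deterministic, input-order invariant).

Relative ranks use mean-tie fractional ranks rescaled as (r−1)/(n−1) to
[0, 1] within each experiment — the cleanest contract attaining both
endpoints — and are combined as the mean of an accession's scores over the
experiments in which it appears. Rank-based interaction tests are out of
scope. Cluster-contrast tables report the blue−red difference of means for
date-like traits (dates subtract) and the blue/red ratio for everything
else.

## PLS-DA

Single-response PLS1 on autoscaled predictors (mean 0, SD 1) with class
membership coded {0, 1} and centred. Components by NIPALS deflation; the
sign convention forces the first non-zero weight element non-negative so
score plots are reproducible. The latent-variable count minimises
cross-validated PRESS — leave-one-out by default (the natural regime for a
two-dozen-accession collection), k-fold with a seed available; ties in
PRESS resolve to the smaller model. Missing predictor values are
mean-imputed within column and reported on the model; constant columns are
dropped with a warning. VIP uses the standard formula over retained
components (mean squared VIP is 1 by construction); variables above 0.8
are reported in descending importance. Classification thresholds the
predicted response at the midpoint of the class codes, with rates overall
and per class.

## Numerical choices and degenerate inputs

* Quantiles everywhere use linear interpolation on sorted values.
* A permutation count too small to resolve the requested quantile warns
  and returns the null maximum.
* Zero-width regions, empty annotations, empty trait tables and all-equal
  samples are valid inputs with defined outputs, exercised by tests.
* All generators and the pipeline derive their randomness from explicit
  integer seeds; the pipeline spawns per-stage child seeds from one root
  seed via SHA-256 and logs them in the run manifest together with output
  checksums.

## Problem sizes used in the test suite

The suite exercises the estimator exhaustively at 2+2 and 3+3 samples,
calibration of the permutation null on 200 structure-free replicates of
300 markers × 96 seeds (99 permutations each), outlier recovery on five
replicates of 2,020 markers × 96 seeds, dPCR coverage on 300 chips, and
brute-force interval algebra on 1,000 random fixtures — sizes chosen so
the whole suite completes in well under a minute per heavy test while
keeping Monte-Carlo error small relative to the asserted bounds.
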