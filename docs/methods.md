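# Methods

This note documents the statistical models behind `aneuadapt`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical corner cases.

## Scientific setting

Cells engineered to carry an extra chromosome (trisomy or tetrasomy)
initially proliferate poorly; after prolonged passaging (~50 passages, "p50"
vs the starting "p0" population) they recover fitness. The package
quantifies this adaptation along five axes:

1. **Copy-number state** — arm-level gain/loss calls, an aneuploidy score,
   and a total-relative-DNA heuristic from binned log2 copy-number ratios.
2. **Proliferation** — bootstrap AUC fold changes of luminescence growth
   curves.
3. **Proteome response** — moderated differential abundance between cell
   lines/passages, arm-level dosage compensation, and a tumor-cohort
   classifier of proteins that scale with arm gain.
4. **Tumor relevance (AADEPT)** — per-gene Spearman correlation between
   tumor aneuploidy scores and tumor-minus-normal expression change across a
   patient cohort.
5. **Integration** — N-dimensional rank enrichment of gene sets,
   hypergeometric overrepresentation, and a per-protein relevance score with
   permutation p-values.

## Copy-number segmentation and summaries

Binned log2 ratios (profile minus its unevolved parental reference) are
partitioned by recursive binary segmentation: for each candidate segment the
split maximizing `|mean_L - mean_R| * sqrt(n_L n_R / n)` is accepted when a
within-segment permutation test yields p <= alpha, then both halves are
processed recursively. Defaults: alpha 0.01, 1000 permutations, minimum
segment width 3 bins. This is the CBS family of algorithms; the
permutation-acceptance rule makes the procedure distribution-free. The
implementation is validated against exhaustive small-instance checks and
localizes a log2(3/2) step under noise sd 0.2 to within ±2 bins in >= 95% of
simulations. Segmentation is deterministic given a seed and idempotent on
its own piecewise-constant reconstruction.

**Arm event calls.** An arm is called gained (lost) when segments with mean
log2 ratio above 0.2 (below -0.2) cover more than 75% of the arm's length.
Gains and losses on one arm are never summed. The **aneuploidy score (AS)**
is the number of autosomal arms called gained or lost. Both thresholds are
exposed as parameters; raising the log2 threshold can only decrease AS.

**WGD filter.** Patients whose ABSOLUTE-style ploidy is >= 2.5 are treated
as whole-genome doubled and excluded; the boundary is strict (`ploidy <
2.5` retained) and configurable.

**Total relative DNA.** `D = sum_i round(R_i) * L_i` with
`R_i = 2 (2^{q_i} - 1)`, `q_i` the segment's mean log2 ratio and `L_i` its
length. Under a diploid reference, `R_i` approximates the integer
copy-number difference of segment i, so D approximates the base pairs of DNA
gained (signed) or altered (unsigned; the default, suitable for correlating
total aberration burden with phenotypes). Rounding is half-away-from-zero
to the nearest integer. Sex chromosomes are excluded.

## Growth-curve quantification

Raw luminescence traces are normalized by subtracting each replicate's
reading at the initial timepoint, then fitted with a continuous
piecewise-linear (linear spline) least-squares model. Knots default to
every interior measured timepoint — the maximum-flexibility piecewise-linear
fit, whose fitted value at each timepoint is the replicate mean. The area
under the fitted curve is the trapezoid sum over adjacent timepoints.

Uncertainty comes from a homoscedastic residual bootstrap (default 10,000
replicates): residuals pooled within one curve are resampled with
replacement, added to the fitted values, the spline refit and the AUC
recomputed. Each bootstrap AUC is divided by the reference line's AUC from
the same run and bootstrap index; the paired ratios are averaged across
experimental runs, and the 95% interval is the 2.5%/97.5% empirical
quantiles of the run-averaged ratios. Bootstrap replicates in which the
reference AUC is non-positive are dropped (warned when > 1%). With
noise-free inputs the interval collapses to a point, and a planted true
ratio of 1.5 at 5% measurement CV is covered by the interval in >= 90% of
simulations. One master seed spawns an independent substream per
(sample, run), so partial re-runs are reproducible.

## Proteome preprocessing and differential abundance

Protein groups flagged as contaminant / reverse / identified-by-site and
rows with any missing intensity are removed; intensities are
log2-transformed. Between-sample scale normalization subtracts each
sample's median log2 ratio to the row-median reference profile
(median-of-log-ratios, as in size-factor normalization); this cancels the
shared between-protein baseline exactly, so the per-sample offset is
estimated with far less noise than a plain median centering. Batch effects
are then removed per protein by least squares on biological-group dummies
plus batch dummies, subtracting only the batch component — planted batch
offsets are removed to machine precision while group contrasts are
untouched.

Pairwise comparisons use moderated t-statistics: the pooled within-group
variance s² (df = n1+n2-2) is shrunk toward a prior,
`s~² = (d0 s0² + df s²)/(d0 + df)`, with (d0, s0²) estimated across proteins
by the method of moments on log sample variances (digamma/trigamma moment
matching; the trigamma inverse is solved by Newton iteration, and a
non-positive excess variance yields d0 capped at 10⁶, i.e. near-complete
shrinkage). t = FC / (s~ sqrt(1/n1 + 1/n2)) on d0+df degrees of freedom;
p-values are BH-adjusted per comparison. Forcing d0 = 0 recovers the
ordinary pooled t-test exactly (tested). Observation-level precision
weights are not applied by default; complete-case TMT-style matrices gain
little from them.

**Dosage compensation.** Per arm, compensation = (overlap-length-weighted
mean DNA log2 ratio) - (mean protein log2 fold change of the arm's genes),
both relative to the same parental line. 0 means protein fully scales with
DNA; log2(3/2) on a trisomic arm means full buffering. Protein fold changes
can also be segmented along gene order (same change-point engine) for a
comparative genome-wide view.

*Known limitation:* global normalization computed over all proteins absorbs
a sliver of the dosage signal — with ~4% of the proteome on the trisomic
arm the compensation estimate carries a positive bias of roughly +0.01 log2
units. This is inherent to any total-signal normalization under aneuploidy,
not an implementation artifact; recovery of a planted compensation factor
c = 0.5 remains within ±0.03.

**Scaling with arm gain in tumors.** Per protein, tumor-minus-normal deltas
are compared between tumors with and without gain of the encoding arm using
Welch's t-tests. One-sided test of (mean difference) < log2(3/2) at BH FDR
0.05 labels the protein *non-scaling*; otherwise a two-sided test with a
significant positive difference labels it *scaling*; anything else (and any
protein with < 2 tumors on a side) is *unclassified*. The 3/2 threshold is
the abundance ratio expected from a single-copy gain in a diploid
background, applied on the log2 scale. Tumors with gains of other arms
remain in the "without gain" group.

## AADEPT

Cohort preprocessing: genes must have valid (non-missing, positive) values
in at least 60% of samples (tumor and normal pooled); each sample is divided
by the 75th percentile of its positive values (upper-quartile
normalization) and log2-transformed; the matched normal is subtracted per
patient; WGD patients are excluded. The AADEPT score of a gene is the
Spearman rank correlation (average ranks for ties) between its deltas and
the patients' aneuploidy scores, with the two-sided p-value from the
t approximation `t = rho sqrt((n-2)/(1-rho²))` — adequate at cohort sizes of
hundreds — and BH FDR across genes. Constant AS is an error; a constant
gene yields a missing score. The pan-cancer cohort is pooled (no per-type
stratification by default).

## Rank enrichment and overrepresentation

Values are ranked per dimension (average ranks for ties) and scaled
linearly to [-1, 1]. The enrichment score of a set is
mean(set) - mean(background); significance is a two-group one-way ANOVA in
one dimension and a two-group multivariate ANOVA in N dimensions, using
Pillai's trace with its exact two-group F transform
`F = V/(1-V) * (n-p-1)/p` on (p, n-p-1) df (with two groups Pillai, Wilks
and Hotelling coincide). The closed form matches `statsmodels` MANOVA to
machine precision and keeps large calibration runs fast. Items missing in
any dimension are dropped listwise; a singular within-group covariance
raises an error naming the collinear dimensions. One BH family per gene-set
collection.

Overrepresentation of a k-item hit list in an m-item set among N background
items: p = P(X >= q) under Hypergeometric(N, m, k), and the strength
`s = log10(N q / (k m))` is the log10 ratio of observed to expected overlap
(undefined, reported missing, when q = 0).

## Protein relevance score

Fold changes of every pairwise cell-line comparison are ranked across
proteins and scaled to [-1, 1], then grouped: G1 (unevolved polysomic vs
parental), G2 (evolved polysomic vs its p0), G3 (evolved disomic control vs
its p0). The score is `S = |sum(G1) + sum(G2) - penalty|` where the penalty
is the G3 rank of largest magnitude sharing the sign of sum(G2) (0 when
sum(G2) = 0 or no such rank exists) — discounting the strongest
same-direction passaging effect. Reading "maximum same-sign rank" as
maximum magnitude keeps the penalty conservative in both directions; a
literal maximum over negative ranks would subtract the weakest effect and
could inflate scores for downregulated proteins. Only proteins quantified
in all comparisons are scored.

Empirical p-values permute protein labels independently within each
comparison column (breaking the per-protein dependence across comparisons
while preserving each comparison's marginal rank distribution), pool the
resulting null scores to the requested count (default 100,000), and use the
add-one estimator p = (1 + #{null >= observed})/(1 + B), which is never 0.
On exchangeable data the p-values are uniform (KS-tested).

## Synthetic-data generator

The generator produces every input the pipeline consumes, with planted
truth returned alongside:

* **Genome catalog** — chromosomes of 60–240 Mb, a centromere at 30–50% of
  the length, a configurable number of genes per arm (20–200 kb, sorted).
* **Patient cohort** — each patient gets a random karyotype (AS = number of
  altered arms, drawn uniformly over 0..n_arms); planted genes receive
  delta = beta * AS + N(0, sigma), null genes pure noise. Defaults
  beta = 0.2, sigma = 1, 200 patients, 5% planted — a regime where planted
  genes separate from nulls (ROC AUC > 0.9) without being trivial.
* **Cell-line proteomes** — log2 intensity = baseline N(20, 2) +
  (1 - c) * log2(arm copy number / 2) + adaptation term + batch offset +
  N(0, replicate_sd). The compensation factor c in [0, 1] scales dosage
  transmission (c = 1 full buffering). Adaptation genes (sign-symmetric,
  half up half down) are planted only in polysomic lines with a per-passage
  weight; the default "progressive" pattern (weight 1 at p0, 2 at p50)
  makes the p0 response deepen during evolution, producing rank-consistent
  G1/G2 contributions that the relevance score is built to reward.
  "Emergent" (0, 1) and "reversal" (1, -1) patterns are available; note a
  strict reversal yields G1 and G2 ranks of opposite sign that cancel in
  the score, so it exercises the penalty logic rather than top-rank
  recovery. One TMT-style batch per replicate set with configurable
  offsets.
* **Growth curves** — RLU(t) = baseline + amplitude (e^{rt} - 1) * eps,
  eps lognormal with the configured CV (multiplicative noise on the raw
  scale, matching luminescence assays); triplicate wells, several runs.
  With equal rates, per-line amplitude scaling plants an exact true AUC
  ratio.
* **Binned profiles** — per-bin value = arm log2 ratio + N(0, noise_sd),
  bins assigned to arms by midpoint.

Determinism: every generator draws from `default_rng` streams derived from
(seed, tag) via SHA-256, so identical configurations give bit-identical
output and substreams are independent of call order.

What the generator does **not** emulate: missing values (complete-case
matrices only, as the analysis removes incomplete protein groups),
intra-arm focal events, GC/mappability artifacts, peptide-level effects,
correlated gene modules, or cancer-type heterogeneity in cohorts. Passing
tests therefore demonstrate correctness of the estimators under the stated
noise models, not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

* Ranks use average ties throughout; a single-item ranking returns 0 with a
  warning.
* BH adjustment is the standard step-up with monotonicity enforcement; NaN
  p-values are passed through and do not count toward the family size.
* Spearman p-values use the t approximation; |rho| = 1 maps to p = 0.
* Hypergeometric p uses the survival function at q-1 (P(X >= q)).
* The trigamma inverse in the variance prior is Newton-iterated from
  x0 = 0.5 + 1/y to relative tolerance 1e-10.
* Segmentation of a chromosome with fewer than `min_width` bins returns a
  single segment; an empty chromosome is skipped with a warning.
* Coordinates are 0-based half-open internally; SEG files are written
  1-based inclusive and converted at the I/O boundary; BED stays 0-based.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
catalogs of 2–12 chromosomes (40–2,400 genes), cohorts of 200 patients,
proteomes of 18 samples, 100-replicate coverage/localization simulations,
2,000-set enrichment calibrations, and 50,000–100,000-draw permutation
nulls. These sizes were chosen so each statistical claim is testable with
comfortable Monte-Carlo margins while an entire run stays in the minutes
range on one CPU.
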