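# Methods

## Statistical model

Each SNP–CpG pair within the cis window (±500 kb, boundary inclusive) is
tested with nested ordinary least squares on the M scale:

* full model: intercept + sex + age + weight category + PC1 + PC2 + dosage
* reduced model: the same without the dosage term

The test statistic is the Gaussian-likelihood ratio, LRT = n·ln(RSS₀/RSS₁),
referred to χ² with 1 df — for Gaussian linear models this is the exact
deviance form of the likelihood-ratio test of nested least-squares fits,
and it agrees asymptotically with the partial-F test. Effect size is the
partial R² = (RSS₀ − RSS₁)/RSS₀, the fraction of methylation variance not
already explained by the covariates that the genotype explains. Because
"total variance explained" is also a common way to report such effects, the
scan additionally emits a `marginal_r2` column, (RSS₀ − RSS₁)/TSS, without
asserting that either is the only correct summary.

Assumptions: additive allelic effects (a single numeric dosage term, 1 df),
independent samples (no relatedness/mixed models), homoscedastic Gaussian
residuals on the M scale, and that two principal components of the
reference CpG panel suffice to absorb cell-composition confounding.

Genotype handling per SNP: samples with missing dosage are dropped
(complete-case), and a homozygote class observed fewer than 10 times is
merged with the heterozygotes, after which the variable is recoded to two
levels with the risk direction preserved (rare risk homozygotes: 2→1; rare
non-risk homozygotes: {0,1}→0, 2→1). A class count of exactly 10 is kept.
SNPs monomorphic after masking or merging are reported as untestable, not
errors.

## Multiple testing

q-values are computed over all testable pairs as one family. π₀ is
estimated by the smoother method: π₀(λ) = #{p > λ}/(m(1 − λ)) over
λ = 0.05, 0.10, …, 0.90, a cubic smoothing spline
(`scipy.interpolate.UnivariateSpline`, default smoothing) evaluated at the
largest λ, clamped to (1/m, 1]. With π₀ fixed at 1 the procedure reduces
exactly to Benjamini–Hochberg, which is verified against an independent
step-up implementation. The R qvalue package's `smooth.spline(df = 3)` is a
different smoother; the two agree on the calibration checks (π₀ within
0.05 of 1 on uniform p-values) but are not bit-identical.

## Preprocessing

* β values of exactly 0 or 1 are clamped to [1e−6, 1 − 1e−6] before the
  logit2 transform to avoid infinities; the β↔M round trip is exact to
  1e−12 inside the open interval.
* Probe QC removes probes with any missing β, probes with fewer than 75 %
  of samples at detection p < 0.01 (strict boundary: exactly 75 % passes),
  and probes flagged as sex-chromosomal, cross-reactive, or containing a
  common SNP. The flag table is an input; nothing is hard-coded.
* The 95 % reference range is p97.5 − p2.5 with linear-interpolation
  percentiles (numpy's default); probes with range ≥ 0.20 enter the sample
  QC PCA.
* Sample outliers: a sample is excluded if |score − mean|/SD > 3 on any of
  the first 8 PCs. Neither the number of PCs nor the z rule has a canonical
  value; both are configurable and echoed in the run manifest. The test
  suite demonstrates the rule on a fixture whose scree elbow is at the six
  planted corruption components.
* The cell-composition surrogate is the first two PCs of the reference
  panel (43 CpGs in the blood application; the panel is always an input
  list). A rank-1 panel yields a zero second component rather than an
  error.

## Genomic context

BED/BEDPE intervals are 0-based half-open; probe and TSS positions are
1-based and converted internally (a probe at 1-based position p occupies
0-based coordinate p − 1). TSS = start on the + strand, end on −. Promoter
= within ±1500 bp of any TSS; a position in both a promoter window and a
transcript span is "ambiguous"; the four classes partition the probe set.
Chromatin-state segmentations are consumed as per-tissue tilings into seven
collapsed categories (enhancer, tss, transcription, quiescent,
heterochromatin, polycomb, znf_repeats); the mapping from raw state labels
to categories is a required input when labels differ.

Enrichment builds the 2×2 table from disjoint groups — associated CpGs vs
tested-but-not-associated — because Fisher's exact test requires disjoint
rows; figures in the literature sometimes compare "associated vs all
tested", which double-counts the associated set, and
`background="overlapping"` reproduces that variant for comparison. The
two-sided p is the conventional sum of all table probabilities not
exceeding the observed table's probability (delegated to
`scipy.stats.fisher_exact` and verified against complete hypergeometric
enumeration for every table with margins ≤ 30). The q-value family is all
(tissue × category) state tests pooled; genomic region classes and enhancer
membership form their own families.

Interaction counting: an anchor pair hits a CpG if either anchor contains
its position; the promoter-interaction flag is set when any partner anchor
overlaps a promoter window. Count distributions are compared with a
two-sided Mann–Whitney U. With combined n ≤ 12 an exact p is computed by
complete enumeration of group labelings (correct under ties, unlike the
no-tie exact formula); larger samples use the tie-corrected normal
approximation.

## Power

Power for one model term follows the Cohen f² framework: f² = R²/(1 − R²),
u = 1, v = n − (number of model terms) − 1, noncentrality λ = f²(u + v + 1)
— the convention of the standard f²-based power calculators. λ = f²·n is
available behind a flag; the two coincide when the model contains only the
tested term. At f² = 0 power equals α exactly, and the analytic values
match a 100 000-draw Monte-Carlo regression oracle within 0.01.

## Synthetic-data generator

The generator emulates the structure of a ~350-sample blood methylation
cohort genotyped at dozens of obesity-class SNPs:

* covariates: sex ~ Bernoulli(0.4 female), age ~ Uniform(14, 34) years,
  weight category ~ (0.76, 0.20, 0.04) for lean/overweight/obese — the
  demographic mix of a young, mostly lean cohort;
* genotypes: Binomial(2, maf) per SNP (Hardy–Weinberg), risk-allele
  oriented, with optional missingness; planted effects use the latent
  complete dosages so missingness does not distort them;
* cell composition: Dirichlet with concentrations (18, 5, 3, 2, 1, 3) for
  granulocytes, CD4 T, CD8 T, B, NK, monocytes — means near typical whole
  blood fractions with realistic between-person spread (granulocyte SD
  ≈ 0.09);
* methylation: M = base + Σ offsets·composition + covariate effects +
  δ·dosage + N(0, 0.25²) by default, mapped to β = 2^M/(2^M + 1). The
  default residual SD of 0.25 M units reflects typical per-probe residual
  variability on 450K-style arrays; simulation studies that specify a
  different noise level (e.g. 0.5) pass it explicitly.
* reference panel: 43 cell-type discriminating probes with a two-contrast
  offset design — half contrast myeloid (granulocyte, monocyte) vs lymphoid
  types at ±4 M units, half contrast T cells vs B/NK — so the panel's
  between-sample variance is dominated by two composition axes, its top two
  PCs explain well over 70 % of panel variance, and the surrogate
  canonically correlates > 0.99 with the true composition;
* detection p-values: Beta(0.1, 100) for passing measurements (mass far
  below 0.01) and Uniform(0, 1) for injected failures;
* annotation fixtures: non-overlapping genes with strand, per-tissue state
  tilings that exactly partition each chromosome, BEDPE anchors planted to
  overlap chosen probes (with decoys kept clear of probe positions), and
  enhancer intervals, all with memberships recorded as ground truth.

All stages draw from independent, salted streams of one seed, so a fixed
seed reproduces every table bit-identically.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real cohorts: probe type I/II design differences and
raw-intensity artefacts (NOOB/BMIQ territory), batch effects, LD between
SNPs, spatial correlation of methylation along the genome, age trends or
genotype×environment structure in methylation, non-additive genetic
effects, and case-mix differences between sub-cohorts. Linear mixing of
cell-type logit offsets on the M scale is a modelling convenience — real
mixing is linear on the β scale — but it is exactly the structure the
PCA-based surrogate assumes, which is the property under test.

## Numerical conventions and degenerate inputs

* RSS values below 1e−12 × max(TSS, 1) are treated as exactly zero: a
  reduced model that already fits perfectly yields p = 1 and partial
  R² = 0; a perfect full fit yields partial R² = 1 with p at the smallest
  positive double rather than 0.
* p-values are floored at the smallest subnormal double so they remain in
  (0, 1].
* Rank-deficient designs raise an error naming the collinear columns
  (diagnosed from the QR diagonal).
* PCA fixes component signs by making each component's largest-magnitude
  loading positive; requests beyond the numerical rank truncate with a
  warning.
* Odds ratios use ad/bc with ∞ for a zero denominator with nonzero
  numerator and a p of 1 for any table with a zero margin.

## Problem sizes

The test suite and the acceptance script run the studies at: 2000 null
pairs (n = 350) for calibration; 50 replicates of 50 pairs with 10 planted
1.0 M-unit effects for FDR; 100 replicates for CI coverage of a 0.5 M-unit
effect; 100 random designs for LRT oracle agreement; every 2×2 table with
margins ≤ 30 for Fisher enumeration; 30 small-sample configurations for the
exact Mann–Whitney check; and 3 × 100 000 draws for the power oracle. These
sizes give Monte-Carlo standard errors comfortably below the tolerances
they are checked against.

## Known limitations

* The LRT/χ² p-value is asymptotic; at the study's n ≈ 350 it is
  indistinguishable from the partial-F p in the calibration checks, but at
  much smaller n the F form would be preferable.
* π₀ estimation on very small families (e.g. a handful of enrichment
  categories) is noisy; the implementation clamps rather than stratifies,
  and `pi0=1` (pure BH) is available wherever q-values are produced.
* The pipeline consumes chromatin-state segmentations; it does not learn
  them, and no LD or eQTL lookups are performed.
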