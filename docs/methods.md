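# Methods

`kynscan` implements a "virtual biomarker study": given a plasma metabolite
with known genetic instruments, it asks which clinical diagnoses those
instruments associate with, whether the associations are mediated by the
metabolite or by variant-level (horizontally pleiotropic) pathways, and
whether the metabolite is causally up- or downstream of other traits. The
package contains both the analysis machinery and a generative model that
produces every input with known ground truth, so each stage can be tested
against the truth it was generated from.

## Instrument construction

Instruments are selected from GWAS summary statistics by a strict
significance filter (default p < 5×10⁻⁸) followed by greedy LD clumping:
repeatedly take the remaining variant with the smallest p-value as an index
variant and absorb every variant on the same chromosome within a window
(default 1000 kb, measured center-to-center) whose squared Pearson
correlation of dosages against the index reaches the threshold (default
r² ≥ 0.05 absorbs; indices are independent at r² < 0.05). Ties in p are
broken by (chrom, pos, variant_id) so the result is invariant to input row
order. LD is computed from an explicit reference genotype matrix (VCF with
DS or GT, or a dosage TSV) over pairwise-complete observations.

Cohort-level QC follows common biobank practice: variants with imputation
quality strictly below 0.3 are dropped (missing quality is kept and
logged), and one member of each related pair (pi-hat > 0.2, strict) is
removed by a seeded random draw, iterating until no retained pair exceeds
the threshold.

## Summary-statistic harmonization

Effect sizes are always relative to an explicit effect allele; flipping
negates beta and complements the allele frequency, leaving SE and p
untouched (an involution). Harmonizing an outcome study to an exposure
study accepts exact or strand-complement allele matches. Palindromic (A/T,
C/G) variants cannot be strand-resolved from allele letters, so they are
kept only when the minor-allele frequency is below 0.42 in both studies and
the aligned frequencies fall on the same side of 0.5; otherwise (including
any missing frequency) they are dropped with a logged reason. Indels are
never treated as palindromic. The 0.42 default is the conservative
community convention; the threshold is configurable.

## Phenome construction

ICD-9-CM/ICD-10 events are grouped into phecodes via a mapping table that
carries, per phecode, an exclusion range (closed numeric interval
containing the phecode) and an optional sex restriction. An "instance" is a
distinct (person, phecode, date) triple, so same-day duplicate codes count
once; raw-row counting would let a single encounter create a case.

Per phecode: persons with ≥ 2 instances (configurable) are cases; persons
with some but fewer instances are excluded (neither case nor control, the
convention of the standard PheWAS tooling); persons carrying any code in
the exclusion range are excluded unless they are cases; everyone else is a
control, further restricted to the [min, max] age (or birth-decade) range
observed among the cases — range matching, not 1:1 pairing. Phecodes with
fewer than 300 cases (configurable) or with a sex restriction are dropped
from the scan set. Cases, controls and exclusions partition the cohort for
every retained phecode.

Controls are required to be free of exclusion-range codes only, not of all
codes: unrelated diagnoses do not disqualify a control.

## Association engine

Logistic regression is fit by iteratively reweighted least squares: at most
25 iterations, converged when the maximum absolute score drops below 10⁻⁸.
Quasi-separation is flagged (|beta| > 15 or non-convergence) rather than
raised so a phenome scan can continue past degenerate phenotypes; constant
outcomes or predictors yield flagged rows. Wald z tests provide p-values
(matching the behaviour of the standard PheWAS tooling); classical
homoskedastic SEs and t tests are used for the linear model. Rank-deficient
designs raise an error naming the collinear columns.

Genetic encodings: additive uses the dosage in [0, 2] as-is; recessive
codes 1 for effect-allele homozygotes, hard-calling imputed dosages at 1.5
(round-to-nearest). The polygenic score is Σⱼ dosageᵢⱼ·βⱼ with weights
aligned to each variant's effect allele (flipping 2−d where needed) and
missing dosages mean-imputed within the cohort; the standardized score
(mean 0, SD 1 over the cohort) is used in scans so odds ratios are per SD
of the score. Zero score variance is flagged rather than raised.

## Mendelian randomization

With per-variant exposure effects (bx, sx) and outcome effects (by, sy)
from two non-overlapping samples:

* **Wald ratio** (1 variant): by/bx with first-order SE sy/|bx|.
* **IVW** (fixed-effect, first-order weights 1/sy²): the zero-intercept
  weighted regression of by on bx; β̂ = Σ bxⱼbyⱼ/syⱼ² / Σ bxⱼ²/syⱼ²,
  SE = (Σ bxⱼ²/syⱼ²)^(−1/2). No residual overdispersion scaling by default.
* **MR-Egger** (≥ 3 variants): the same regression with an intercept, after
  orienting every variant to bx > 0. The slope estimates the causal effect
  under InSIDE; the intercept estimates average directional pleiotropy.
  SEs are scaled by the residual dispersion floored at 1 (never deflated
  below the fixed-effect SE) with t-tests on m−2 df, following the
  convention of the standard MR implementations.
* **Weighted median** (≥ 3 variants): per-variant ratios rⱼ = byⱼ/bxⱼ
  weighted by bxⱼ²/syⱼ²; the estimate interpolates r at cumulative-weight
  percentile 0.5 (the j-th order statistic sits at Sⱼ − wⱼ/2). Its SE comes
  from a seeded parametric bootstrap (default 1000 draws) resampling
  (bx, by) from their normal sampling distributions. Consistent when valid
  instruments carry ≥ 50% of the weight.

Cochran's Q = Σ (byⱼ − β̂bxⱼ)²/syⱼ² is referred to χ²(m−1); inflation
suggests heterogeneity/pleiotropy. Note a subtlety of first-order weights:
when bx itself is estimated with error, the true residual variance is
sy² + β²sx², so Q is slightly overdispersed relative to χ²(m−1) unless the
exposure sample is large. The null-calibration checks therefore simulate
homogeneity at the summary level (fixed bx, by = θ·bx + noise), which is
the exact null of the statistic as defined; with weak instruments users
should expect mild Q inflation. Similarly, MR-Egger's intercept is only
clean when errors-in-variables attenuation of the slope is negligible, so
its recovery is demonstrated in a strong-instrument regime (exposure
n = 12 000, per-allele effects 0.06–0.24 SD).

The bidirectional driver harmonizes and runs all applicable estimators in
both directions, each direction using instruments selected in its own
exposure study; a direction with no harmonizable instruments is skipped
with a warning. Estimates are on the outcome scale per unit (typically SD)
of exposure.

## Meta-analysis and multiple testing

Two schemes: sample-size-weighted z combination, z = Σ zᵢ√nᵢ / √Σnᵢ (the
default, as in METAL under default settings), and fixed-effect
inverse-variance weighting of effect sizes. Benjamini–Hochberg adjusted
p-values are computed by the step-up rule q₍ᵢ₎ = minⱼ≥ᵢ m·p₍ⱼ₎/j with a
stable sort; the FDR family is one scan (one predictor against one
phenome) by default. q < 0.05 is the conventional significance line.

## Generative model

Haplotypes are generated by thresholding a latent multivariate normal with
AR(ρ) correlation inside each LD block at the per-variant frequency
quantile; dosage is the sum of two haplotypes. This gives exact expected
allele frequencies and Hardy–Weinberg genotype proportions, and dosage LD
that increases monotonically in ρ. Thresholding attenuates the latent
correlation (ρ = 0.99 yields dosage r² ≈ 0.85, not 0.98), which is
accepted: the purpose is controllable block structure, not a calibrated
recombination map. Blocks are laid 1.5 Mb apart so distinct blocks fall
outside the default clumping window.

The metabolite is yᵢ = Σⱼ γⱼgᵢⱼ + δCᵢ + εᵢ with confounder C ~ N(0,1) and ε
scaled so the marginal variance is 1; effects γ are in SD units per allele.
The default instrument set emulates a six-SNP discovery at frequencies
(0.37, 0.02, 0.48, 0.43, 0.64, 0.21) and standardized effects
(−0.10, 0.32, 0.14, 0.11, 0.14, 0.21) — the magnitudes implied by
genome-wide-significant hits in a metabolite GWAS of ~8000 people.

Diseases follow logit P(D=1) = α_d + θ_d·y + Σⱼ πⱼ_d·gᵢⱼ + λ_d·C with α_d
solved numerically so the marginal prevalence matches the configured base
rate. Each case emits two ICD events (one ICD-9-CM, one ICD-10 code of the
mapped phecode) on distinct dates uniform over a ten-year window; every
person emits Poisson-distributed unmapped noise codes, so true controls
never acquire exclusion-range codes. The bundled toy phecode map spaces
phecode values so exclusion ranges of different diseases never overlap.

Two-sample summary statistics are produced by drawing two disjoint samples,
computing per-variant simple-regression betas with SEs from each
regression's own residuals (not asymptotic formulas, so SE calibration is
an honest property of the generator), with configurable horizontal
pleiotropy (fraction of invalid instruments, mean and SD of their direct
outcome effects), a shared within-sample confounder, and optional variants
that act on the outcome only (the outcome's own instruments, needed for a
meaningful reverse direction — reverse MR run with the *exposure's*
instruments would estimate 1/θ by construction, not 0).

All randomness flows from a single mandatory seed, with fixed per-stage
substreams; identical configurations give byte-identical outputs.

### What the generator does not emulate

Real ICD ontologies and phecode hierarchies (the toy map is flat and
non-overlapping across diseases); population structure (PCs are simulated
as pure noise covariates); sex chromosomes and sex-differential effects;
genotyping/imputation error (dosages are exact); informative observation
processes (everyone is fully observed for ten years). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to the messiness of real EHR data.

## The pleiotropy-versus-causality contrast

The scenario behind `kynscan.contrast`: six metabolite instruments, one of
which (frequency 0.48) additionally carries a direct log-OR of 0.30 per
allele on three of twelve diseases; the metabolite itself has no causal
disease effect; n = 20 000, 8% base rates. The single-SNP scan of the
pleiotropic variant is expected to flag its three diseases (Wald z ≈ 8),
while the PRS scan is expected to stay null because the pleiotropic variant
is assigned a small metabolite effect (0.03 SD/allele against 0.14–0.32 for
the others) and hence a minority of the score weight — a deliberate design
choice: the contrast is only identifiable when the score dilutes any single
variant's direct effects, and the residual leakage into the standardized
score works out to z ≈ 0.7. Because Benjamini–Hochberg has a ~5% chance of
at least one rejection even under a complete null, the contrast is asserted
as a majority over three seeded replicates rather than a single run.

## Problem sizes and numerical choices

Simulation-based checks use: 500 replicates for IVW recovery (50
instruments, exposure/outcome samples of 5000); 200 replicates each for the
Egger and weighted-median robustness comparisons; 500 replicates for
Cochran's Q calibration; 1000 phenotypes at n = 2000 for scan type-I error;
200 replicates of a 900-null/100-alternative mixture for FDR control; three
replicates of the n = 20 000 contrast. p-values are clipped into (0, 1];
linear predictors are clipped at ±30 before the logistic link; the
weighted-median bootstrap floors a zero SE at machine precision. Degenerate
inputs (constant outcome or predictor, rank deficiency, zero score
variance, monomorphic variants) are either flagged in results or raised as
typed errors, as documented per function.
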