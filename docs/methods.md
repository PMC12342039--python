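# Methods

## Statistical model

Each variant is tested with ordinary least squares on standardized data.
Let `y` be the outcome, `g` the additive genotype (count of the minor
allele), `m`/`s` indicators for the moderate- and severe-TBI groups
(orthopedic injury is the reference), and `x` the covariate block
(age, sex, age×sex, PC1).  The interaction model is

    y = α + xᵀγ + δ_m m + δ_s s + β g + τ_m (g·m) + τ_s (g·s) + ε

and the null "the variant's association does not differ by injury group"
(τ_m = τ_s = 0) is tested with the joint 2-df F-test; per-term Wald
p-values are also reported for sensitivity.  The TBI-only model drops the
OI group and the interaction, keeping a moderate/severe severity dummy:

    y = α + xᵀγ + δ_s s + β g + ε.

The outcome, continuous covariates, and the genotype are standardized to
mean 0 and sample SD 1 (denominator n−1) *once*, inside the design
builder, on the analysis subset — so TBI-only coefficients are standardized
with respect to the TBI subsample, and all coefficients are on the
standardized-effect scale (0.1 small / 0.3 medium / 0.5 large for
continuous predictors).  The age×sex product is formed from the
standardized age.  Missing genotype calls are handled complete-case per
variant (the convention of genome-scan tools); a design made rank-deficient
by, e.g., a variant constant within one group is flagged unestimable and
excluded from all downstream counting.

If the alternate allele turns out to be the major one in the analysis
sample, the coding is flipped so that 0/1/2 always counts the minor allele;
this only flips coefficient signs.

### Implementation

The scan is batched: the fixed covariate block is shared across variants,
per-variant complete-case Gram matrices `XᵀWX` are assembled from a handful
of dense matrix products, and the resulting (m × p × p) stack is solved and
inverted with vectorized LAPACK calls.  Estimability is decided by a
relative eigenvalue cutoff (smallest eigenvalue > 1e-9 × largest).  A scan
of ~50,000 variants at n = 400 takes well under a second per model; the
unit tests verify coefficient-level agreement (1e-8) with both an explicit
normal-equations solve and `statsmodels.OLS`.

## Quality control

Filters use the standard chip + imputed-data thresholds: participant call
rate ≥ 0.90 (applied first, after which all variant statistics are
recomputed on the analysis sample), SNP call rate ≥ 0.95, MAF ≥ 0.10,
Hardy–Weinberg exact p ≥ 1e-4, imputation Rsq ≥ 0.95, intergenic exclusion
for variants more than 5,000 bp from the nearest gene ("more than" read
strictly: 5,000 bp exactly is kept).  The filters are independent
predicates, so the surviving set does not depend on stage order; the
per-stage removal counts in the QC report use the fixed order
call-rate → MAF → HWE → Rsq → gene-distance.  HWE is computed on all
participants pooled, with a chi-squared alternative behind a flag; the
exact test evaluates the conditional distribution of the heterozygote count
given the allele counts via log-gamma arithmetic, summing all outcomes no
more likely than the observed one.  Gene assignment takes the nearest
annotated interval (1-based, inclusive), ties going to the earlier gene in
sorted order.

## Gene sets, matching, and the permutation null

Ranked case genes are cut into nested cumulative epochs at 0 %, 5 %, …,
100 % (epoch 0 = training genes only; top-k = ⌈pct/100 × n_ranked⌉) and
into disjoint incremental slices.  Gene→variant expansion uses post-QC
variants only.

Control draws match the case epoch's MAF-band profile *exactly*: within
each band ([0.10, 0.15), [0.15, 0.20), [0.20, 0.30), [0.30, 0.50]; bands
left-closed, last band closed) the draw samples, without replacement,
exactly the case count from the control-pool variants in that band.
Matching on exact per-band counts (rather than proportions) is the stricter
reading of MAF-ratio matching and makes every null draw the same size as
the case set.  SNP-level stratified sampling is used rather than whole-gene
sampling, because gene-level draws cannot satisfy exact band matching.
Each draw's RNG stream is derived counter-style from
(master seed, epoch label, draw index), so any draw is reproducible in
isolation and the draw set is independent of evaluation order.

Enrichment at an epoch compares the case set's count of variants with
p < 0.05 (strict; joint interaction p for the interaction model, main-
effect p for the TBI-only model; unestimable fits never count) to the
permutation null: the 95th percentile is the type-1 discrete percentile
(smallest value with ≥ 95 % of draws at or below it), the case set is
enriched only when it strictly *exceeds* that cutoff (ties are not
enriched), and the empirical p uses the add-one estimator
(r + 1)/(B + 1) ≥ 1/(B + 1).  With B = 10,000 the choice among the standard
discrete percentile definitions moves the cutoff by at most one count.
Because hit counts are integers, ties at the cutoff make the call slightly
conservative: on all-null synthetic data the observed call rate at a fixed
epoch is ≈ 0.03–0.05.

No multiplicity correction is applied across epochs: the cumulative sets
are nested, not disjoint, and the question is aggregate enrichment rather
than per-epoch testing.

## Effect-size reports

Per-variant magnitudes (interaction model: max |τ̂| over the two
interaction terms; TBI-only: |β̂|) are binned into <0.2, [0.2, 0.3),
[0.3, 0.4), [0.4, 0.5), ≥0.5.  Each SNP lands in exactly one bin, so SNP
counts conserve the analyzed total; a gene is counted in every bin where it
has a SNP, so gene columns are deliberately not a partition.  Top-centile
gene sets take the ⌈c/100 × m⌉ variants with the largest magnitudes (ties
broken by smaller p, then variant id) and return their distinct genes;
overlap across the four outcome × model sets is reported as exact Venn
region sizes, and the gene lists are exported one-symbol-per-line
(uppercased, deduplicated) for external pathway-enrichment services.
Running pathway enrichment itself, and producing the gene ranking, are out
of scope: the ranking is an input, the gene lists are an output.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* cohort of 196 participants by default, group fractions 61:49:86
  (OI : moderate : severe), configurable;
* biallelic variants with MAF ~ Uniform(0.10, 0.50), genotypes
  Binomial(2, MAF) per participant (Hardy–Weinberg), optional uniform
  missingness (default 0 — tests that need missingness request it);
* genes on one synthetic chromosome, 1-based inclusive intervals of
  10 kb separated by 20 kb gaps (> the 5 kb intergenic rule), 8 variants
  per gene by default (the real per-gene variant count is not specified
  anywhere authoritative, so it is a config knob), variants strictly inside
  genes; 18 training genes, 1,000 ranked case genes, 5,000 control genes by
  default;
* age ~ Uniform(0, 17), sex ~ Bernoulli(½), PC1 ~ N(0, 1) (no generative
  claim — only the covariate list matters to the analysis);
* outcome = group means (0 / 0.3 / 0.6) + small covariate effects +
  Σ_causal (β_main + β_int,group) · z + N(0, 1) noise, with z the
  HWE-standardized dosage; two outcomes by default, sharing the systematic
  part with noise correlated at 0.8;
* causal variants: a configurable fraction (default 10 %) of the variants
  inside a configurable rank band of the case genes (default top 5 %),
  with standardized effects β_main = 0.2, β_int = 0.3 by default.

Generating betas are on the **unit-noise scale**: a causal variant's
coefficient is β in units of the residual SD.  When the planted genetic
variance is small, these coincide with the standardized coefficients the
scan reports.  When many causal variants are planted at once, the summed
genetic variance inflates the outcome SD, so realized standardized
coefficients are attenuated by that factor — e.g. 40 variants at
β_int = 0.3 inflate the outcome SD to ≈ 1.85 and realize standardized
interaction effects of ≈ 0.16.  This is not an implementation artifact but
an identity: independent variants with true standardized effects of 0.3
each cannot number 40, since Σβ² would exceed the total variance.  The
power consequences are visible in the acceptance suite and documented
there.  Relatedly, the observed correlation between the two outcomes equals
the 0.8 noise correlation only under weak signal; shared genetic signal
pushes it higher.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), imputation uncertainty (Rsq is recorded, defaulting to
1.0), chip-specific genotyping error, and ancestry structure beyond a
single PC1 covariate.  Passing tests therefore validate the statistical
machinery and its calibration under the model's own assumptions, not
robustness to LD-induced correlation between case and control variants or
to confounding that one PC cannot absorb.

## Problem sizes and numerical choices

The test suite validates calibration at deliberately desk-scale sizes: the
type-I study uses 200 all-null datasets of 400 participants with 2,000
case-gene and 10,000 control-pool variants and B = 500 draws per epoch;
power/ordering studies use 50 replicates with 8,000 case-gene variants and
B = 500–1,000.  The acceptance script runs the full two-outcome pipeline at
400 participants with ~48,000 variants and B = 1,000.  These sizes keep a
complete validation run in the tens of minutes on a single CPU while
leaving the Monte-Carlo error of each calibration check well inside its
assertion band.

Tolerances: fitted coefficients are asserted against oracles at 1e-8, the
HWE exact test at 1e-10 (exhaustively for all configurations with ≤ 50
participants), standardization idempotence at 1e-12.  Degenerate inputs are
handled by convention: monomorphic variants have HWE p = 1 and are
unestimable in the scan; an all-missing variant fails the call-rate filter;
a zero-variance column is an error in standardization; an empty ranked list
yields only epoch 0; a control band smaller than its case count is an error
naming the band.
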