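# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `privateqtl`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Phenotype hierarchy and BLUP estimation

All sizes are natural-log transformed (declared as `log_base=e` in file
metadata). Sex is coded as a +1/2 (female) / −1/2 (male) contrast and diet
as +1/2 (fed) / −1/2 (starved), so every fixed-effect coefficient reads
directly as a female−male or fed−starved difference on the log scale, and
an interaction coefficient as a difference of such differences.

The per-lineage BLUP model contains no diet term; it is fitted separately
within each diet stratum, the only structure that yields the four distinct
quantities (female/male × fed/starved) the downstream indices require.
Within a stratum:

* fixed: intercept and sex contrast;
* random: a correlated lineage (intercept, sex-slope) pair with an
  unstructured 2×2 covariance, and a crossed block intercept;
* estimation: REML (see *Numerical choices*); on non-convergence the
  lineage covariance falls back to diagonal and the fallback is recorded
  in the diagnostics.

A lineage's BLUP for a sex is the fitted fixed part plus its predicted
intercept and sex deviation; block effects have mean zero and drop out.
Lineages lacking a sex within a stratum receive a missing BLUP there, and
all indices built on it are flagged incomplete. Blocks only enter through
the records present in the stratum.

The derived indices (sex-averaged size, SSD, Δ, sex-averaged Δ, SSP) are
arithmetic on the four BLUPs; `SSP = SSD_fed − SSD_starved` is an exact
algebraic identity and is enforced to 1e-12 in the tests. The
fed-independent plasticity index is the per-sex OLS residual of the starved
BLUP on the fed BLUP; its sign convention is therefore "larger than
expected starved size", opposite in orientation to Δ, which does not affect
its use as an association phenotype.

Group filtering precedes estimation: any lineage × sex × diet group with
fewer than `min_n` (default 10) measurements is removed, and removed groups
are reported with their counts.

## Two-step association

**Stage 1 (screen).** For each marker, an OLS of the lineage-level index on
the allele class (0 = major homozygote, 1 = minor), plus Wolbachia status,
inversion statuses, and genotype principal components as additive
covariates. With no covariates and balanced classes this is exactly the
pooled two-sample t-test. Markers with fewer than `min_minor_lineages`
(default 4) lineages in either class are skipped. Ranking is by p-value
with deterministic (chromosome, position) tie-breaks. For SSP the screen is
run on both the raw and the fed-independent index and the top-k sets are
unioned; ties at the k-th p-value are included.

**Stage 2 (mixed model).** Block effects are removed from the individual
records by per-block centering (identical to regressing on the block factor
and keeping residuals); the BLUP stage instead retains block as a random
intercept, since the shrinkage model can absorb it coherently there.
Each phenotype maps to a fixed/random structure whose target term isolates
its genetic signal (see the module docstring of `privateqtl.assoc_mlm` for
the full table). Lineage covariates are chosen once per phenotype by
substituting each covariate for genotype in the model and backward-
eliminating its terms, interactions first, at `alpha = 0.05`; the retained
terms are then fixed for every marker fit. Missing genotype calls drop the
lineage for that marker only; monomorphic markers are skipped.

Inference on the target term is a Wald z-test from the REML fit with the
plug-in GLS covariance (no small-sample degrees-of-freedom correction;
noted in output metadata). Candidates use the fixed 1 × 10⁻⁵ threshold; no
false-discovery layer is added. Two diagnostics probe whether stage 1 loses
stage-2 signal: the cumulative count of stage-2 hits as a function of
stage-1 rank (with its plateau rank), and a negative-control mixed-model
scan of markers sampled from outside the top set.

## The mixed-model engine

Per-marker mixed models are the pipeline's computational bottleneck, so the
package ships its own REML solver (`privateqtl.lmm`) built on an exact
collapse to cell sufficient statistics: all designs here are categorical,
so records sharing a (group, fixed-row, random-row) signature are
exchangeable, the within-cell sum of squares informs only the residual
variance, and the restricted likelihood reduces to a weighted model on the
cell means. Lineages with identical design and replication collapse further
into shared sufficient statistics, and the remaining per-class linear
algebra is batched through LAPACK. One objective evaluation costs
microseconds regardless of the number of records, which is what makes
5,000-marker single-step scans and the calibration experiments feasible on
one core.

Two solver paths: a grouped path (random effects block-diagonal by lineage
— all GWAS models) and a Woodbury path for crossed terms (lineage × block —
the BLUP model). Both profile out the residual variance and parametrize
each relative covariance by its log-Cholesky factor (diagonal entries on
the log scale, bounded in [−10, 6]; off-diagonals in [−30, 30]), guaranteeing
positive semi-definiteness; optimization is L-BFGS-B with numerical
gradients. Unstructured fits are seeded from a diagonal pre-fit; marker
scans warm-start each fit from the previous marker's solution. The
fallback ladder on non-convergence is unstructured → diagonal →
intercept-only, recorded per result row. BLUPs are `Γ Z' V⁻¹ (ȳ − X β̂)` on
the cell-mean scale; with `fix_gamma` the solver evaluates at supplied
variance ratios without optimizing, which is how the closed-form shrinkage
oracle is checked.

The engine is cross-checked in the test suite against statsmodels'
`MixedLM` (estimates, standard errors, variance components, and BLUPs agree
to ~1e-4 on shared models); statsmodels serves only as the independent
oracle, never as the implementation.

## Gene-based test and enrichment

Markers are assigned to genes from the annotation table; markers annotated
as intergenic, or flanking a gene by more than 2 kb, are excluded; a marker
annotated to several genes counts under each. Per gene, marker p-values
convert to 1-df chi-square values via the inverse CDF at 1 − p (p = 0 is
clamped to the smallest positive double, with a warning), monomorphic
markers are ignored, and the values are summed. The null distribution
samples multivariate-normal vectors with the gene's genotype correlation
matrix, squares, and sums. The LD matrix uses pairwise-complete Pearson
correlations with constant columns dropped, eigenvalues floored at 1e-8,
and rescaling to unit diagonal — under identity LD the null is exactly
chi-square with one df per marker, which anchors the Monte Carlo machinery
analytically (the module's principal oracle).

The empirical p defaults to the upper tail (proportion of null sums ≥
observed), the only direction under which small gene-level p means strong
association and the 1 × 10⁻⁵ candidate rule is coherent; a literal
lower-tail convention is available behind `tail="lower"`, and an optional
(1+count)/(1+n) correction behind `add_one` (off by default, so a zero
count reports 0, displayed as < 1/n_reps). Per-gene null streams derive
from the run seed plus the gene's sorted index, so results are independent
of iteration order. A warning is emitted when `n_reps` cannot resolve the
candidate threshold. Replicates default to 10⁶ in production; the tests and
the acceptance script run at 10⁵, which resolves every probability they
assert.

Gene-set enrichment summarizes each gene by its minimum marker p, takes the
mean over set members found in the tested universe, and compares it to
means of randomly drawn same-size gene sets (gene-level sampling, 10,000
permutations by default); the one-sided empirical p is the proportion of
null means at or below the observed mean. On small universes this
converges to the exhaustive enumeration, which the tests check exactly.

## Knockdown analysis

Each validation experiment is a single cross, so the factorial
`size ~ S * D * T` is fitted by OLS with the same ±1/2 contrasts. Per-term
p-values are drop-one model-comparison F-tests. Backward elimination
removes, at each step, the least significant currently-highest-order
non-significant term involving fly type, refitting after each removal;
sex, diet, and sex×diet are never candidates for removal (every experiment
is expected to show sex and diet effects regardless of knockdown), and
marginality is never violated. Ties break toward higher order, then
lexicographic term name. The retained type terms classify the knockdown:
S·D·T → SSP; else D·T → plasticity and/or S·T → SSD; else T → size; none →
no detected effect.

## Synthetic-data generator

The generator emulates a DGRP-style study: 100–200 isogenic lineages,
thousands of homozygous biallelic markers in LD blocks, lineage covariates,
and individual log pupal-case areas under the same hierarchical structure
the GWAS fits, plus planted marker effects in any of the four context
classes. Default parameters (all overridable):

| parameter | default | rationale |
|---|---|---|
| fixed intercept | 0.95 log mm² | log pupal-case area scale |
| sex effect (F−M) | 0.18 | females ~20% larger |
| diet effect (fed−starved) | 0.25 | starvation shrinks size ~22% |
| sex×diet | 0.02 | small baseline SSP |
| var(lineage intercept) | 0.010 | broad-sense size heritability ~50% at the lineage level |
| var(sex slope) | 0.002 | genetic variance in SSD |
| var(diet slope) | 0.004 | genetic variance in plasticity |
| var(sex×diet slope) | 0.001 | genetic variance in SSP |
| var(block) | 0.002 | modest batch effects |
| var(residual) | 0.010 | within-line SD ≈ 0.1 log units, matching the lineage-level SD |
| MAF range | (0.05, 0.5) | panel-realistic spectrum |
| LD block size / within-block r | 5 / 0.8 | stand-ins; the real panel's LD decay is not emulated |

LD is generated by a Gaussian copula per block: an exchangeable latent
correlation is calibrated numerically (bivariate normal CDF root-solve) so
the *phi* correlation of the thresholded genotypes targets the requested
value, and thresholding is by latent rank, which pins each marker's
realized minor-lineage count inside the MAF range exactly (before
missingness). Missing calls are completely at random. Blocks are assigned
per record uniformly, crossed with lineage — real rearing blocks are
batches of whole vials and partially confounded with lineage, which this
deliberately simplifies. Lineage random intercepts and slopes are drawn
independently (no genetic correlation among the four components), and
planted effects enter as `β · (dose/2) · c(S, D)` with the class-specific
contrast multiplier, so a planted G×S×D effect equals the minor-vs-major
difference in the cell-mean double contrast exactly in the noise-free
limit.

What passing tests on these data do *not* show: robustness to residual
heteroskedasticity or non-Gaussian size distributions, to LD decay over
physical distance, to population structure beyond what random genotype PCs
capture, to confounded block/lineage designs, or to heterozygosity
(excluded by construction).

## Numerical choices

* REML throughout; L-BFGS-B with default scipy tolerances on the profiled
  criterion; convergence is the optimizer's success flag, with the explicit
  fallback ladder on failure.
* Wald z against the standard normal; no Satterthwaite/Kenward-Roger-style
  correction (the asymptotic reference is recorded in output metadata).
* GLS quadratic forms are clipped below at 1e-12 to keep the profiled
  residual variance positive in degenerate (noise-free) inputs.
* Screen OLS uses the pseudo-inverse of the normal equations, so collinear
  covariates degrade gracefully; the allele test then refers to the t
  distribution with the residual degrees of freedom.
* Empirical p-values are plain proportions by default; determinism is
  end-to-end given seeds (per-gene and per-stage streams are derived from
  the run seed, never from global state).
* Deterministic orderings everywhere ranks or ties matter: screen ranking
  by (p, chromosome, position); covariate elimination worst-first with
  lexicographic tie-breaks; top-k boundary ties included.

## Evaluation problem sizes

The statistical acceptance checks run at desk scale, chosen to keep the
full suite within a few minutes while leaving each check well-powered:
type-I calibration uses 400 null marker fits (100 lineages, 10 per cell)
split across 8 independent phenotype replicates — tests sharing one
phenotype realization are correlated through the common lineage effects,
so a single-realization rejection fraction would fluctuate well beyond the
binomial band used for the check; effect recovery uses 50 replicates of a
planted 0.05 log-unit three-way effect at 20 per cell; screen completeness
uses a 5,000-marker panel of 150 lineages with ten planted SSP effects
graded from 0.05 to 0.30 log units (graded because each unmodeled planted marker inflates
lineage-level SSP variance, capping the attainable signal of the others);
the strong-effect candidacy arm plants 3× the residual standard error of a
lineage's cell-mean SSP contrast (2σ_ε/√n). Gene-test and enrichment checks
run at 10⁵ Monte Carlo replicates and 2,000–10,000 permutations.

## Known limitations

* The Wald z reference is mildly approximate at small lineage counts;
  a likelihood-ratio option is a natural extension but is not implemented.
* The engine's collapse requires categorical designs; continuous
  covariates are supported (each lineage then forms its own sufficient-
  statistic class) at a constant-factor cost, but per-individual continuous
  covariates would defeat the collapse entirely.
* VCF import accepts only biallelic, fully homozygous records, by design
  (isogenic panels); anything else is rejected and counted.
* The enrichment null samples genes, not matched SNP sets; genes with many
  markers have stochastically smaller minimum p under the null, which the
  gene-level resampling reflects but does not correct.
* Production-scale marker counts (10⁶+) are supported by the formats and
  the per-marker cost (~10 ms), but no parallel or chunked execution layer
  is provided.
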