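# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `carpgs`.

## The animal model

All variance-component estimation and breeding-value prediction uses the
additive animal model

    y = Xb + Zu + e,   u ~ N(0, K σ_g²),   e ~ N(0, I σ_e²),

where `y` are phenotypes (body weight in g or standard length in mm), `b`
holds the intercept and the four-level factorial-cross factor (treatment
coding; estimates are invariant to the coding), and `K` is either the
pedigree numerator matrix **A** (tabular method; founders assumed
unrelated and non-inbred) or the genomic relationship matrix **G**
(VanRaden method 1, `G = ZZ'/(2Σp_j(1−p_j))` with dosages centered by
`2p_j`, observed allele frequencies over all genotyped animals, missing
dosages mean-imputed). Heritability is `h² = σ_g²/(σ_g²+σ_e²)`; the
bivariate model puts 2×2 genetic and residual covariance matrices on the
two traits and reports `r_g = σ_g12/(σ_g1 σ_g2)`.

**G** is blended with the identity, `(1−α)G + αI` with α = 0.01 by
default, purely to guarantee an invertible matrix in the mixed-model
equations; A-blending is available but not the default so G remains usable
without any pedigree.

## AI-REML on the eigenbasis

REML uses the average-information algorithm. Because the model has a
single relationship structure, rotating `y` and `X` by the eigenvectors of
`K` makes the phenotypic covariance diagonal (univariate) or 2×2
block-diagonal (bivariate), so each AI iteration is O(n) after one O(n³)
eigendecomposition. This is the identical REML problem, not an
approximation, and is what makes per-fold REML, 150 parameter-recovery
fits, and repeated study-scale cross-validations affordable.

Numerical safeguards, chosen once and used everywhere:

- AI steps are accepted only if the REML log-likelihood does not decrease;
  otherwise the step is halved (up to 10–12 times). The univariate fitter
  then falls back to an EM step (positivity-preserving); the bivariate
  fitter projects the update to the nearest positive-semidefinite pair of
  covariance matrices (eigenvalue floors: 1e-8 of the phenotypic scale for
  the genetic matrix, 1e-6 for the residual, the latter larger because the
  2×2 inverses must stay numerically meaningful).
- A trust region caps AI step length at 10× the phenotypic scale —
  near-singular residual structures (e.g. duplicated traits) otherwise
  produce unbounded steps.
- Components are floored at 1e-8 of the phenotypic variance; convergence
  is a relative parameter change < 1e-8 (default), max 200 iterations.
- Standard errors come from the inverse AI matrix; h² and r_g standard
  errors by the delta method. At a variance boundary the h² SE is reported
  as NaN rather than a fabricated number.

Starting values are half the phenotypic (co)variance for both components.

## BLUP and cross-validation

Breeding values solve Henderson's mixed-model equations with
`λ = σ_e²/σ_g²`; validation animals are carried in `K` without records and
receive EBVs through relationship ties. Accuracy is approximated as
`cor(EBV, y)/h` over validation animals and dispersion bias as the OLS
slope of `y` on EBV — phenotypes are used raw, exactly as the benchmark
formula states, so the cross effect in `y` costs a few percent of
accuracy.

Fivefold folds are a random permutation cut into contiguous validation
blocks of `floor(n/5)`; the `n mod 5` remainder individuals stay on the
training side of every fold. For the 1,214-animal cohort this yields the
972/242 training/validation convention. All density scenarios and the
PBLUP baseline share fold memberships (paired comparison).

Variance components in cross-validation are either re-estimated on every
training fold (`components="per-fold"`, the leakage-free default of
`cross_validate`) or estimated once per scenario on the full cohort
(`components="full"`), which is how the study-scale replication and the
acceptance script run. With several scenarios compared side by side, one
study-wide heritability supplies the accuracy denominator `h` for all of
them — the pedigree-based REML estimate when a pedigree is available,
else the full-density genomic estimate. Per-scenario denominators are
available (`shared_h=False`) but invert the density ordering, because
sparse-panel REML underestimates h² and a smaller denominator masquerades
as higher accuracy.

## Mixed-model GWAS

Association testing is two-step: variance components are estimated once
under the null model, then each SNP enters as a fixed effect and is Wald-
tested with the covariance structure held fixed, all in the eigenbasis of
G (each test is an O(n) weighted regression). Missing dosages are
mean-imputed per SNP; monomorphic SNPs are emitted with NaN statistics.
Genome-wide significance is Bonferroni `0.05/N` over tested SNPs. The
polygenic control keeps the inflation factor λ near 1 under family
structure; ablating it (identity K) inflates λ well above 1.2, which the
test suite uses as a positive control. Note that p-values at linked SNPs
are correlated, so distribution-level diagnostics (e.g. KS uniformity)
are evaluated on distance-thinned marker subsets.

## Parentage assignment

A locus is trio-incompatible when sire, dam and offspring are all
genotyped and the offspring dosage cannot arise from any parental gamete
combination. The incompatible set decomposes as: opposing homozygotes
between offspring and either single parent, or both parents homozygous for
the same allele with a heterozygous offspring. That decomposition lets all
40×20 candidate pairs be scored for every offspring with a handful of
one-hot matrix products (exact integer counts; float32 BLAS). An offspring
is assigned when the best pair's mismatch rate is at most the tolerance
(default 0.04, the study's overall genotyping-error allowance — whether
that maps one-to-one onto a trio-mismatch ceiling is undocumented, so it
is a configurable knob) and beats the runner-up by a margin (default 0.01;
uniqueness). Ties are never broken by candidate order. Pedigree validation
re-checks each assigned link's parent–offspring opposing-homozygote rate.

## The synthetic-data generator

The generator reproduces the study conditions; its defaults are the
study's printed design wherever one exists.

- **Genome**: the 50 published linkage-group lengths (their printed total
  is 3,944 cM; the per-group values sum to 3,946 — per-group rounding; the
  groups are operative). 12,311 template markers allocated to groups
  proportional to the published per-group counts, uniform positions. QTL
  (default 2,000, allocated by map length) sit at positions distinct from
  markers, so markers tag QTL only through linkage, as anonymous RAD tags
  do. Transmission is Haldane: Poisson(L/100) crossovers per group,
  uniform positions, no interference — a crossover process is what gene
  drop needs, independent of the Kosambi mapping function used to print
  map distances.
- **Founders**: 60 broodstock drawn from a closed random-mating ancestral
  pool (default 18 individuals for 15 non-overlapping generations; base
  generation in linkage equilibrium with counted-allele frequencies
  ~ U(0.01, 0.5)). This gives founders the relatedness, inbreeding and
  linkage disequilibrium of a hatchery strain with small effective size.
  The pool size and depth were calibrated so the full pipeline reproduces
  the reported prediction-accuracy regime (GBLUP ~0.7 at full density,
  little loss down to a few hundred high-MAF SNPs) — with unrelated,
  linkage-equilibrium founders (`founder_model="unrelated"`, retained as
  an option) pedigree and genomic prediction cap near 0.50 and 0.47 and no
  parameter of the cross itself can recover the reported values, which is
  strong evidence that founder relatedness/LD is a real feature of the
  study population. A side effect of pool drift is that ~20 % of template
  markers fix before QC, leaving ~7.5k segregating SNPs; accuracy is flat
  over panel size in this regime (the study's own density scenarios
  plateau), so this does not affect the reproduced quantities.
- **Mating**: within each block every dam × sire pair is possible; family
  sizes are Dirichlet-multinomial (per-pair concentration 3.0, calibrated
  so sizes span ~1–25 with mean ~7 and some of the 200 pairs stay empty,
  matching the observed 195-of-200 families without forcing that count).
  Blocks are redrawn until every parent contributes.
- **Phenotypes**: per-trait genetic values are QTL-dosage sums with
  effects bivariate-normal across traits (correlation r_g = 0.94), then
  rescaled so the realized genetic variance among offspring equals
  h²σ_P² exactly (h² = 0.26 weight / 0.33 length; σ_P = 4.6 g / 7.1 mm;
  means 16.3 g / 77 mm). Residuals are bivariate normal with the residual
  correlation solved from the target phenotypic correlation 0.93
  (an inconsistent (r_p, r_g, h²) triple raises an error naming it).
  A common cross (block) effect with SD 0.25 σ_P per trait and
  across-trait correlation r_p is added; that correlation keeps the
  realized overall weight–length correlation at 0.93.
- **Genotyping noise**: each call is set missing with probability 0.05;
  surviving calls are replaced by a uniformly chosen different dosage with
  probability 0.01 — the simplest model consistent with a scalar "overall
  genotyping error", at rates a well-run RAD assay achieves.

What the generator does *not* emulate: sequence-level artifacts (allele
dropout correlated with depth, paralog collapse), non-additive genetic
effects, maternal/common-environment effects (the fish were reared
communally from the swimming stage), selection across generations, and the
exact MAF spectrum of real RAD data. Passing tests therefore demonstrate
that the pipeline's statistics behave correctly under the study's design
and an additive polygenic architecture, not that any particular real
dataset would give identical numbers.

## Study-scale replication and its calibration ceiling

`carpgs.study.replicate_study` chains the full pipeline and subsamples the
uniquely assigned offspring to a 1,214-animal cohort, mirroring the
printed 972/242 fivefold split. Averaged over replicate populations the
pipeline yields GBLUP ≈ 0.69 (full panel), GBLUP ≈ 0.61 (MAF > 0.45),
PBLUP ≈ 0.54–0.56, and full-density bias ≈ 1.02–1.04.

Pedigree-only accuracy sits ~0.05 below the study's 0.60 at every founder
configuration examined. Three structural reasons, none of them tunable
without damaging something else: (i) **A** assumes unrelated founders
while the generating founders are related, so pedigree BLUP is fit under a
misspecified covariance; (ii) the accuracy formula divides by a REML ĥ
that is base-population-referenced and slightly inflated under founder
relatedness; (iii) raw phenotypes carry the cross effect, deflating
cor(EBV, y). Weakening founder relatedness raises none of the reported
values and lowers most of them, so the pedigree baseline is reported as it
comes out. The genomic-over-pedigree improvement is correspondingly
overstated (~25–29 % vs the reported 18 %).

## Problem sizes and reproducibility

Tests run the study replication on 12 independent populations (fivefold ×
10 CV each) plus reduced designs for unit tests; the acceptance script
averages 16 replicates. Every stochastic stage draws its seed from a
single base seed through `numpy` `SeedSequence` spawning, so identical
seeds give byte-identical populations, folds and results.
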