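# Methods

`hybridgs` implements a genomic-selection (GS) workflow for F1 hybrid
breeding from a panel of inbred candidate parents: genotype QC, in-silico
synthesis of every possible hybrid's genotype, additive and
additive-plus-dominance prediction models, heritability estimation,
replicated cross-validation, across-population prediction, and selection
of parental combinations.  A breeding-population simulator with full
ground truth backs every claim the test suite makes.

## Genotype data and QC

Biallelic SNP calls are coded `{-1, 0, +1} = {aa, Aa, AA}` with `A` the
VCF alternate allele (alt dosage 2 -> +1).  The orientation is a fixed
convention; every downstream statistic is invariant to flipping it
consistently, so no ancestral/phased information is needed.  Positions
are 1-based throughout.

Filters run in a fixed order — missingness (default max 0.1), minor
allele frequency (default min 0.05), heterozygote excess (default: drop
markers with het frequency strictly above 0.25), window-based LD pruning
(default r² > 0.95 within 1 kb, keeping the earlier-positioned marker),
then imputation.  The het-excess filter matters for diploidized
allopolyploid panels (e.g. octoploid strawberry): loci that stay
heterozygous in inbred material are probably not subgenome-specific and
would violate the diploid coding.  Each rule's removals are recorded in a
`FilterReport`; reruns with the same configuration are byte-identical.

Imputation is per-marker mode (default) or rounded marker mean.  These
replace heavier learned imputers deliberately: below the 10% missingness
cap a per-marker statistic recovers the large majority of masked
homozygous calls on inbred panels (the masking test measures this), and
it is deterministic and dependency-free.  LD r² uses pairwise-complete
observations; pairs with fewer than 3 complete observations count as
r² = 0.

Homozygosity of a line is its fraction of homozygous calls.  For a locus
starting fully heterozygous, expected homozygosity after t selfing
generations is 1 − (1/2)^t (0.9375 at t = 4, the single-seed-descent
depth of the emulated design).  Panel-wide homozygosity of simulated
lines sits above that number because outbred founders are heterozygous
only at Hardy–Weinberg rates; the 0.9375 benchmark applies per
initially-heterozygous locus.

## Hybrid genotypes

Expected F1 genotypes follow the Mendelian expectation rule: equal
homozygotes breed true, opposite homozygotes give a heterozygote, and
any cross involving a heterozygous parent is coded heterozygous — the
most probable class, not a sampled gamete.  The rule is symmetric by
construction and hybrid IDs are canonicalized (`sorted(p1, p2)` joined
by `x`), so reciprocal crosses collide.  Stochastic gamete sampling
exists only in the simulator, where true (sampled) F1 genotypes are
wanted.  n parents admit n(n−1)/2 unordered crosses (105 -> 5,460).

## Relationship matrices

The additive matrix is VanRaden method 1,
`A = W W' / (2 Σ p_m q_m)` with `W` the dosage matrix column-centered by
`2 p_m`.  The dominance matrix uses the dominance-deviation
parameterization with per-genotype codes
`{aa, Aa, AA} -> {−2p², 2pq, −2q²}` and denominator `Σ (2 p q)²`.  These
are the de-facto standards behind the GS packages this workflow mirrors;
both are substitutable via the module surface if a different
parameterization is wanted.  Allele frequencies default to the matrix
supplied; for across-population prediction the kinship over the
train+test union is built with training-population frequencies, and the
source is recorded on the matrix.  A 1e−8 diagonal ridge is used inside
solvers only, never stored.

## Prediction models

The GBLUP mixed model is `y = 1μ + g_A (+ g_D) + e` with
`g_A ~ N(0, A σ²_A)`, `g_D ~ N(0, D σ²_D)`.  Variance components come
from one of two engines:

* **REML** (default): single-kinship fits profile the likelihood over
  the variance ratio in the kinship eigenbasis (an O(n) evaluation per
  candidate ratio, optimized in 1-D); two-kinship fits maximize the REML
  log-likelihood over log-variances by Nelder–Mead with Cholesky solves.
  Deterministic, hence the default for tests and cross-validation.
* **Gibbs**: each genetic term is rotated into its kinship's eigenbasis,
  where its full conditional is diagonal; variances carry scaled-inverse-χ²
  priors (df 5, scales splitting half the phenotypic variance across
  terms).  Seeded and bit-reproducible.

Predictions for unphenotyped individuals are mixed-model conditional
means, `ĝ_test = σ² K[test, train] V⁻¹ (y − μ̂)`, summed over fitted
genetic terms.

**A known degeneracy, and why the engines differ.**  On a nearly
homozygous training panel the dominance codes are almost a deterministic
function of dosage, so D spans nearly the same directions as A plus
extra flexibility; unpenalized REML can then push all variance onto σ²_D
(σ²_A, σ²_e -> 0), fitting the training phenotypes exactly while
transferring poorly to heterozygous test material.  Reported
inbred-panel heritabilities with a dominance term are inflated for the
same reason and should not be taken at face value.  The across-population
drivers therefore fit additive-dominant models with the Gibbs engine,
whose variance priors regularize the split; REML remains the default
wherever the training population itself carries heterozygosity.

Marker-effect models regress y on the coded genotype matrix, plus — for
additive-dominant variants — the column-centered `{0,1,0}`
heterozygosity matrix, so dominance deviations enter as separate
effects.  Centering keeps μ the population mean.

* **BayesB**: spike-and-slab single-site Gibbs.  Each effect is zero
  with prior probability π (default 0.95); the slab is normal with a
  per-effect variance under a scaled-inverse-χ² prior (df 5), i.e. a
  scaled-t slab.  Inclusion is sampled from the marginal likelihood with
  the effect integrated out.  The slab scale is data-derived so that
  included markers explain half the phenotypic variance a priori.
* **Bayesian Lasso**: double-exponential prior via the
  scale-mixture-of-normals representation; 1/τ²_j is inverse-Gaussian,
  λ² carries a gamma hyperprior.  Inverse-Gaussian draws are clamped
  when an effect is numerically zero (the IG mean diverges and the
  Michael–Schucany–Haas transform cancels catastrophically).

Both samplers run their inner loops under numba and are bit-reproducible
given (seed, chain length).  Default chains are 12,000 iterations with
2,000 burn-in and thinning 5, in the style of the Bayesian GS packages;
tests use shorter seeded chains.

**RKHS** builds a Gaussian kernel
`K_ij = exp(−θ d²_ij / median(d²))` on coded-genotype squared Euclidean
distances — the median scaling makes θ = 1 a sensible default — and
reuses the single-kinship mixed-model machinery.  **Random forest**
delegates to scikit-learn's `RandomForestRegressor` (seeded); the
nonlinear learners take no explicit dominance design because they can
represent dominance (a nonlinearity in dosage) themselves, and the model
spec rejects the combination.

## Heritability

`h²_A = σ²_A / (σ²_A + σ²_e)` from the additive fit and
`h²_AD = (σ²_A + σ²_D) / (σ²_A + σ²_D + σ²_e)` from the joint fit.  For
Gibbs fits, h² is computed per posterior draw and summarized by its
posterior mean, avoiding ratio-of-means bias.  A and D built from the
same markers are correlated, so the individual σ²_A/σ²_D split is
imprecise even when the sum is well determined; both are reported, with
that caveat, rather than suppressed.

## Evaluation

Cross-validation is k-fold (default 2) with R replicates (default 50).
The fold partition is a function of (seed, replicate) only — replicate i
uses seed + i — so every model × trait combination is scored on
identical folds and adding replicates never changes earlier ones.
Accuracy is the Pearson correlation between pooled out-of-fold
predictions and observed phenotypes, one value per replicate, summarized
as mean (SD); per-fold averaging is available as an option.  Undefined
correlations (constant predictions or constant y) are recorded as
missing with a warning and excluded.  Within-population CV builds
kinships once over the full population and masks phenotypes — the
standard GS workflow convention.

Across-population prediction trains entirely in one population and
scores the other, with union kinships on training frequencies.  The PCA
overlay is a centered coded-genotype SVD returning coordinates and
per-component variance fractions.

## Hybrid selection

Every candidate cross is scored per trait by a fitted model (marker
models score the synthesized designs directly; kinship models use
relationship blocks between candidates and the training individuals,
relabeling candidates that are themselves in the training set).  Five
classes are drawn from the predicted distributions: high/low on each of
two focal traits from beyond the outer quantiles (default outer
deciles), and an intermediate class from the joint middle band (default
40–60% on both traits).  Classes are disjoint, quotas are config values,
ties break by hybrid ID, and an explicit excluded-pairs list (e.g.
flowering-time incompatibilities) is never selected; an unsatisfiable
quota raises with the shortfall.  Selection on a trait truncates its
distribution and inflates the predicted-vs-observed correlation for that
trait; the evaluation helper documents this rather than correcting it.

## Synthetic populations

The generator emulates the inbred-hybrid breeding design: `n_founders`
outbred founders (allele frequencies uniform on (0.1, 0.9), genotypes at
Hardy–Weinberg proportions), `intercross_cycles` rounds of random mating
(default 3), a sample of `n_lines` lines (default 105) inbred by
single-seed descent for `selfing_generations` (default 4), and
`n_crosses` random F1 combinations (default 275).  Meiosis is the
minimal standard model: independent assortment between chromosomes
(default 7, 1 Morgan each) plus Poisson crossovers at uniform map
positions.  An optional retained-heterozygosity mode marks a fraction of
loci as immune to fixation — a phenomenological stand-in for loci kept
heterozygous by inbreeding depression — which drops realized line
homozygosity below the 1 − (1/2)^t expectation.

Traits get `n_qtl` QTL sampled without replacement; additive effects are
normal, dominance deviations are degree-of-dominance × |additive| with a
configurable degree distribution (default mean 0.5, SD 0.25).  Effects
are rescaled so the realized additive and dominance variance components
in the reference population hit their targets exactly, making
parameter-recovery tests sharp.  True genetic values use the same
`{-1,0,1}` / `{0,1,0}` parameterization as the models.  Phenotype =
μ + genetic value + N(0, σ²_e), plus an optional population-specific
environment shift for studying transfer failure (a year-effect analogue).
The five default traits carry additive-plus-dominance heritabilities in
the 0.6–0.8 range typical of well-replicated vegetative and fruit
traits.  Everything is deterministic from `SimConfig.seed`.

Default problem sizes (2,000 markers; 105 + 275 individuals) keep a full
pipeline run at desk scale while the panels behave statistically like
dense ones; marker count and all dimensions are config values.

**What the simulator does not emulate:** allopolyploid subgenome
structure (the pipeline operates on diploidized subgenome-specific loci
by design), realistic LD decay profiles and ascertainment of real SNP
panels, genotyping error, selection during line development, epistasis,
and genotype-by-environment structure beyond an additive population
shift.  Passing tests therefore demonstrate correctness of the methods
under the stated generative model, not expected accuracy magnitudes on
real panels.

## Numerical choices

REML ratio search is bounded at λ = σ²_g/σ²_e ∈ [1e−8, 1e8]; boundary
estimates (σ̂² = 0 or h² = 1) are legitimate outcomes at small n.
Kinship PSD is enforced to −1e−6 (relative) on the smallest eigenvalue;
Gibbs eigenbases drop eigenvalues below 1e−10 of the maximum.  Mode
imputation breaks ties toward the smaller coded value.  LD pruning keeps
the earlier-positioned marker of a high-LD pair.  All Monte-Carlo
components (samplers, simulator, fold assignment) take explicit seeds
and are reproducible bit for bit.
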