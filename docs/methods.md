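# Methods

## Model and estimands

All prediction flows through the clone-repeatability animal model
`y = Xb + Zu + e`, `Var(u) = Kσ²ₐ`, `Var(e) = Iσ²ₑ`, fitted on tree-level
records. `X` carries fixed site effects in cell-means coding (one column
per site; the intercept is absorbed into the site means, which spans the
same space as a reference-level parameterization and keeps `X` full rank).
`Z` maps trees to clones; clones present in `K` but absent from the data
get zero columns and are predicted purely through their relatives.
Incomplete-block structure within sites is deliberately out of scope: site
is the only fixed effect.

The four breeding-value flavors differ only in `K` and in which phenotypes
enter: EBV1 (K = I, all data; the phenotype-only standard), EBV2 (K = A,
validation clones' data removed), GEBVa (allele-frequency G,
selection-index form) and GEBVb (regression G, inverted-G form).

## Relationship matrices

**A** is built by the tabular method over the topologically sorted
pedigree; unknown parents contribute zero, so founders are unrelated and
non-inbred. Correctness is pinned by a Monte-Carlo gene-dropping IBD
oracle (10⁵ allele drops on a 10-individual pedigree with selfing and
inbreeding, agreement within 3 standard errors).

**G (allele frequency)**: `G = ZZ'/(2Σpᵢ(1−pᵢ))` with `Z = dosage − 2pᵢ`.
The frequency source defaults to the sample, with a hook for supplied
base-population frequencies. Centering at *sample* frequencies puts the
ones-vector in the null space of `Z`, so that G is exactly singular; the
fitting layer then blends `G* = 0.99G + 0.01A` (logged) before
factorizing. The construction is invariant to which allele is counted, as
the centering absorbs orientation.

**G (regression)**: with `M = dosage − 1`, the 2×2 normal equations of
`MM' = g₀11' + g₁A + e` are solved over all n² cell pairs (diagonals
included); `G = (MM' − g₀11')/g₁`. A non-positive slope is an error; m ≤ n
markers triggers a singularity warning. The `M` coding is not dictated by
the regression model itself (the intercept absorbs any affine shift), so
the conventional −1/0/1 coding is used.

## REML

The restricted likelihood of the two-component model is profiled down to
the single ratio γ = σ²ₐ/σ²ₑ using the mixed-model-equation identities
`log|V₀| + log|X'V₀⁻¹X| = log|γK| + log|M(γ)|` and
`y'P₀y = y'y − [b̂;û]'[X'y;Z'y]`, and the one-dimensional profile is
minimized by bounded Brent search on log γ ∈ [−14, 14] (xatol 1e-10). This
is exact REML — no EM iterations, deterministic given data and tolerances
— and each evaluation costs one Cholesky of the (p+q)×(p+q) coefficient
matrix, so a 6000-tree, 165-clone fit takes well under a second. Estimates
at the search boundary (a component collapsing to zero, e.g. a response
with no residual variation) are clamped at a small positive floor and
flagged. Correctness is pinned against the closed-form balanced one-way
ANOVA estimators, which REML must reproduce exactly on balanced data.

## Prediction, PEV and accuracy

ABLUP solves Henderson's MME; prediction-error variances come from the
u-block of the inverse coefficient matrix (they therefore include
fixed-effect estimation error, as mixed-model software reports them).
GBLUP is solved on fixed-effect-adjusted clone means `ȳ − Xb̂` with
`R = diag(1/nᵢ)`, where `b̂` is the GLS solution from the same MME — this
makes the selection-index form `G[G+Rλ]⁻¹` and the inverted-G form
`[R⁻¹+G⁻¹λ]⁻¹R⁻¹` algebraically identical to each other and to the
tree-level MME, an equality enforced to 1e-6 against a brute-force
joint-covariance-inverse oracle. The clone-mean PEV
`σ²ₐ(G − G[G+Rλ]⁻¹G)_jj` treats `b̂` as known; the two GBLUP forms agree
on it exactly (Woodbury identity).

Accuracy uses the standard reliability relation
`r = √(1 − SE²/((1+f)σ²ₐ))`, clamped into [0, 1] with a warning when
numerical overshoot makes SE² exceed `(1+f)σ²ₐ`. `f` is `diag(A) − 1` for
pedigree predictions and `diag(G) − 1` (the genomic inbreeding
coefficient, which can be slightly negative) for genomic ones. The
square-root form is a deliberate choice: the relation is the familiar
reliability identity `SE² = (1 − r²)(1+f)σ²ₐ`, and omitting the radical
would change reported values materially.

## Imputation

Missing calls (~1.2% of cells in the emulated design) are filled four
ways. The stochastic method draws from the observed genotype-class
frequencies of the locus, preserving genotype frequencies in expectation.
The major-homozygote method sets missing cells to dosage 0; under the
package's global minor-allele coding (0 = major homozygote, ties at
p = 0.5 keeping input orientation) "convert to zero" and "set to the major
homozygote" are the same operation. The gene-content method exploits the
fact that the covariance of gene content between relatives is proportional
to A: each locus's observed dosages are treated as the response in a
one-locus mixed model with individual effects of covariance A, a GLS mean,
and a variance ratio fixed by a gene-content heritability of 0.99 (gene
content is essentially fully heritable; the ratio only sets how hard
predictions shrink toward the locus mean). Predictions at missing
individuals are continuous and centered on the locus mean. The *truncated*
variant clips them to [0, 2]; the *scaled* variant first standardizes them
by their own mean and SD to the observed locus SD around gene content 1,
then clips. Both variants therefore respect the dosage range; they differ
only in the mapping of the raw predictions. All methods leave observed
cells untouched (enforced by test).

Marker QC drops monomorphic loci first, then loci with strictly more than
15% missing calls, in that order, so the three counts partition the raw
set exactly.

## Synthetic data

The generator emulates the trial design stage by stage: 13 parents paired
into 9 crosses (disjoint pairs first, then chained pairs so several
crosses share a parent), per-family progeny counts drawn in 3–37 summing
to 165, founder minor-allele frequencies uniform on [0.05, 0.5], genotypes
gene-dropped with fair Mendelian transmission at unlinked loci, each clone
replicated 16–50 times spread evenly over 16 sites (~6250 trees). True
breeding values are `Σᵢ(dosage − 2pᵢ)aᵢ` with
`aᵢ ~ N(0, σ²ₐ/(2Σpᵢ(1−pᵢ)))`, so every marker is causal and the BV
variance among unrelated individuals is σ²ₐ; phenotypes add a fixed site
effect (SD 1.0, same order as the genetic SD) and i.i.d. residuals. The
heritability parameter is the individual-tree ratio
`h² = σ²ₐ/(σ²ₐ+σ²ₑ)`, default 0.25 (σ²ₐ = 1, σ²ₑ = 3). Missing calls are
masked completely at random at rate 0.012, and a raw-marker mode appends
planted monomorphic and high-missing loci to exercise QC.

Two conditionings mimic array ascertainment: loci monomorphic among the
sampled clones are redrawn (a real SNP array only reports segregating
loci), and a random mask that would leave an informative locus
monomorphic-among-observed or above the 15% missing threshold is redrawn
for that locus. Without the first, ~2% of intended-informative loci would
be monomorphic by chance in a 13-founder population.

What the generator does *not* emulate — linkage and LD (loci are
independent, so long-range LD from the small founder set is present but
map-based LD is not), non-causal markers (real arrays tag a small fraction
of causal variation, so real-data GEBV accuracies are substantially lower
than synthetic ones), incomplete-block and spatial field structure,
genotype-by-environment interaction, and selection. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
phenomena (Mendelian-sampling resolution, accuracy ordering of training
fractions, SE advantage of G), not the absolute accuracy levels to expect
from a given real array.

## Cross-validation

Partitions are drawn per replicate with seed `base + replicate`, either
at random or within every family independently; within-family counts
round half-up with at least one clone on each side for families of ≥2
(families as small as 3 must contribute to both sets in the 50%
scenario); singleton families go to training. Variance components are
re-estimated on each training set by default (the conservative
honest-validation choice; a flag reuses full-data fits for sensitivity).
Validation correlations are product-moment, over validation clones only;
replicates with fewer than three validation clones are skipped with a
warning. A canary test asserts that perturbing validation phenotypes
changes no prediction — training data provably exclude them.

## Problem sizes in tests and the acceptance script

The shipped tests and `scripts/acceptance.py` size their simulations to
the study design (165 clones, 16 sites; 3461 markers where marker density
itself is at issue) but use a few hundred markers where only the
relationship machinery is exercised, 20 replicates for parameter-recovery
and Mendelian-sampling comparisons, and 10⁵ gene drops for the pedigree
oracle — sizes chosen so each check is statistically decisive at the
tolerance it asserts.

## Known limitations

Single trait, single random genetic effect; no dominance or epistatic
matrices, no single-step (H-matrix) combination of genotyped and
ungenotyped individuals, no Bayesian marker-effect models, no
multi-environment modeling. The gene-content imputation refits per locus
(patterns of missingness are cached within a locus set but not across
matrices), which is the dominant cost at high missingness.
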