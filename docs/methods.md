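# Methods

This note documents the models and procedures implemented in `gsrefresh`,
the defaults they use, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Simulated genome and trait

The genome is diploid, autosomal, and biallelic: by default 10
chromosomes of 100 cM carrying 200 evenly spaced markers and 20 QTL each
(2,000 markers, 200 QTL; QTL sit between markers so the sets are
disjoint). Meiosis follows the Haldane model: crossover counts per
chromosome are Poisson with mean equal to the map length in Morgans,
crossover positions uniform, no interference. Markers are the loci
visible to evaluation — relationship matrices and heterozygosity use
markers only — while QTL carry the additive effects, mirroring chip-based
evaluation where causal loci are not genotyped. Mutation, dominance,
epistasis, and sex chromosomes are out of scope.

Founders are generated by drawing a frequency per locus from
Uniform(0.05, 0.95), sampling haplotype alleles as independent Bernoulli
draws, then running 100 generations of random mating at constant size 500
(half of each sex) before expanding the final generation to the requested
founder count. The burn-in serves two purposes: it builds linkage
disequilibrium between markers and QTL (without which genomic prediction
has nothing to work with) and lets frequencies drift away from their
initial values. These burn-in settings are this package's own desk-scale
choice of an ancestral-population generator — configurable, and not a
reproduction of any particular historical-population configuration.
Doubling the burn-in mainly increases LD range and allele-frequency
spread; the strategy contrasts are insensitive to it.

QTL effects are drawn standard normal and then rescaled by a single
constant so that the founder true-breeding-value (TBV) sample variance
(ddof = 1) equals the genetic variance exactly. The default variance
components are those of a routinely evaluated dairy milk-yield trait:
sigma2_g = 423,390 kg^2, sigma2_e = 987,910 kg^2, h^2 = 0.3. Phenotypes
are y = TBV + N(0, sigma2_e / w); a record weight w > 1 emulates a
progeny-tested average (an "effective daughter contribution"), which both
reduces residual noise at simulation time and re-enters GBLUP as a
residual-precision weight.

## Relationship matrices and QC

Two genomic relationship matrices are implemented:

* VanRaden: G = ZZ' / (2 sum_i p_i (1 - p_i)) with Z = X - 2p. Allele
  frequencies default to those observed in the supplied matrix; the
  breeding-scheme loop fixes them at the founder frequencies so that
  relationship blocks computed in different generations remain mutually
  consistent (which base population a routine evaluation uses is a known
  ambiguity; fixing the base is the reproducible choice).
* Allele-sharing similarity: G_jk = (2/N) sum_i (x_ij - 1)(x_ik - 1),
  which counts shared alleles and is exactly the VanRaden matrix with all
  frequencies fixed at 0.5 (a property-based test asserts this
  equivalence). Self-similarity is twice the homozygosity fraction, so
  the diagonal lies in [0, 2] and off-diagonals in [-2, 2]. The
  optimal-contribution update uses this matrix by default because it
  tracks raw diversity rather than frequency-weighted rarity.

Marker QC keeps markers with call rate > 0.9, minor-allele frequency
> 0.01, and a 1-df Hardy-Weinberg chi-square p-value >= 1e-4 (no
continuity correction; the three genotype-class counts against their HWE
expectation). Missing dosages are mean-imputed to 2p before any matrix is
built. A configurable ridge (default 1e-2) is added to the diagonal
before any inversion, since G from a finite marker panel is routinely
singular.

## GBLUP

The model is y = mu 1 + g + e, g ~ N(0, sigma2_g G),
e ~ N(0, sigma2_e W^-1), with variance components fixed (never
estimated — REML is out of scope). Although phenotypes are treated as
pre-corrected and only random effects are of interest, a single GLS mean
mu is always fitted for robustness; on centred synthetic data it is
close to the TBV baseline and is added back whenever predictions are
compared with TBVs. The solve uses one Cholesky factorization of
V = sigma2_g (G + ridge I) + sigma2_e W^-1; candidate GEBVs come from the
projection G_cross G_ref^-1 ghat_ref, which reduces algebraically to
sigma2_g G_cross V^-1 (y - mu 1) and is equal to including the candidates
as zero-weight records in a joint mixed-model solve. That equivalence is
enforced by a test against an independently coded joint solve, not
assumed. Numerical edge: with a nonzero ridge, a candidate genotypically
identical to a reference animal differs from it by the ridge on the
reference diagonal; the exact-duplication property therefore holds at
ridge 0, which is how it is tested.

## Optimal contributions

Selecting with contribution vector c (c >= 0, sum c = 1) gives group
coancestry c'Gc/2 — the expected inbreeding of progeny bred from the
group. The expected rate of inbreeding is measured against the current
generation's mean-inbreeding proxy f_t:

    deltaF(c) = (c'Gc/2 - f_t) / (1 - f_t), floored at 0.

In the breeding loop f_t is the mean kinship of the candidate cohort
under equal use, mean(G)/2 clipped to [0, 0.99]; the exact baseline a
black-box implementation would use is unpublished, so this convention is
explicit and logged.

`optimal_contributions` maximizes c'ghat subject to
deltaF(c) <= deltaF_max (default 0.01, the commonly recommended 1%
ceiling). The cap translates to c'Gc <= C with
C = 2 (deltaF_max (1 - f_t) + f_t). The solution path is:

1. If C is at or below the simplex minimum of c'Gc (computed by
   `min_coancestry`: G^-1 1 / (1'G^-1 1) with iterative zeroing of
   negative entries), return the minimum-coancestry contributions; the
   instance is flagged infeasible when even that violates the cap.
2. If the top-GEBV vertex satisfies the cap, it is optimal (linear
   objective).
3. Otherwise the constraint binds: with A = 1'G^-1 1, B = ghat'G^-1 1,
   Q = ghat'G^-1 ghat, the multiplier s = 2 lambda solves
   s^2 = (QA - B^2)/(CA - 1), lambda0 = (B - s)/A, and
   c = G^-1(ghat - lambda0 1)/s; negative entries are zeroed and the
   reduced system re-solved (cap: 10x candidate count iterations).

The optimizer inverts G + r I with its own tiny ridge r = 1e-8 (distinct
from the GBLUP ridge): the constraint is enforced on the ridged matrix,
so the rate evaluated on the raw G can only be smaller, and the returned
group respects the cap with an O(r) margin. Correctness is checked
against exhaustive simplex-grid search on 3-4 candidate instances and a
feasibility/merit contract on random instances up to 200 candidates.
Group-sum (e.g. per-sex) constraints are not implemented; the update
pools both sexes, matching the design being studied. Mate allocation and
multi-generation dynamic contributions are out of scope.

`select_update_group` converts continuous contributions into a fixed-size
group: the n largest contributions, ties broken by higher GEBV then by
ascending id; zero-contribution candidates are admitted (and logged) only
when fewer than n are positive.

## The breeding scheme

One replicate starts from 1,000 ancestral males and 1,000 ancestral
females; the 1,000 males, phenotyped, form the initial GBLUP reference.
Each generation g = 1..10:

1. Fit GBLUP on the current reference and predict the newest cohort.
2. From generation 2 on, add 150 cohort members to the reference by the
   configured strategy (random / truncation on GEBV / optimal
   contributions ranked by contribution); new members are phenotyped on
   entry — entering the reference *is* the phenotyping decision — and no
   one is ever removed, so the reference grows 1000, 1150, ..., 2350.
3. Refit on the updated reference; all selection below uses these
   refreshed predictions — this is the only channel through which the
   update strategy can influence the breeding population.
4. Select 150 sires (top-GEBV males of the cohort, one service
   generation each) and 500 dams (every cohort female, topped up with
   the highest-GEBV dams of the previous generation that have bred fewer
   than 2 times).
5. Mate at random (each dam once; a sire serves at most
   ceil(500/150) = 4 matings), producing 500 offspring.

Offspring sex is assigned at the exact configured ratio (random
permutation of an exactly half-male label vector) rather than by
independent Bernoulli draws: the replacement arithmetic — selection rates
0.6 for males, 1 for new females, 0.5 for previous dams — balances only
when consecutive cohorts contain exactly half females, and with Bernoulli
sexes roughly half of all replicates would be unable to assemble 500 dams
at some generation. Ties in every ranking are broken by GEBV descending,
then id ascending.

Per generation the tidy metrics table records, for the breeding
population (sires + dams): mean TBV, observed heterozygosity (fraction of
heterozygous marker loci), and mean pedigree inbreeding; for the newest
cohort: mean standardized prediction bias |GEBV_k - TBV_k| / sigma_G with
sigma_G the TBV standard deviation of that same cohort (recomputed per
evaluated group); and for the reference population: Ne = 1/(2 f_t) from
its mean pedigree inbreeding — exactly this level-based form, with the
conventional rate-based alternative 1/(2 deltaF) intentionally not
implemented — plus Ne/N. Ne is undefined (infinite) while the reference
is entirely non-inbred; the table stores NaN there. Pedigree inbreeding
comes from Wright's F via the tabular relationship matrix (O(n^2),
default below 3,000 individuals) or a Meuwissen-Luo-style
ancestor-traversal algorithm; the two agree to 1e-10 on random pedigrees
up to 2,000 individuals by test.

Founders are pedigree founders (burn-in ancestry is deliberately
discarded), so the first two breeding populations are structurally
non-inbred and F means start at exactly zero before rising; absolute
inbreeding levels are therefore lower than in a population with deep
recorded ancestry, while the per-generation *increase* is the meaningful
quantity.

Replicates are seeded as SeedSequence([root_seed, replicate]); all
strategies within a replicate share the same founder population and
calibrated trait (strategy contrasts are paired), with separate child
streams per strategy. Identical seeds reproduce the metrics table
bit-for-bit.

## The single-generation update experiment

`run_update_experiment` works on a fixed three-way split: initial
reference A1 predicts candidates A2; each strategy picks an update group
of a given size (100-2000 in the full design); the updated reference
re-predicts a validation group V; evaluation metrics are computed on the
top `top_n` of V by GEBV. The random strategy is repeated (default 100
draws). The same code path accepts the bundled synthetic fixtures or
externally supplied genotype/phenotype/pedigree text files of the same
layout; computing progeny-based phenotypes and weights from raw records
is out of scope — they are consumed as given.

## Trend estimation

`estimate_trends` fits, per strategy and replicate, an OLS regression of
a metric on generation number (optionally adjusted for the Ne/N
covariate), and reports the across-replicate mean slope, its standard
error, and a 1.96-SE normal interval. Proportion-valued metrics
(heterozygosity, inbreeding) can be arcsine-square-root transformed
first. This deliberately replaces a REML mixed model with a random
replicate effect and type-II ANOVA machinery: with a complete
generation-by-replicate layout the mean of per-replicate OLS slopes is an
unbiased estimator of the same fixed slope, and the across-replicate SE
correctly absorbs the replicate variance component. Strategy contrasts
should be read as slope differences with replicate-paired uncertainty,
not as least-square means.

## Problem sizes used by the test and acceptance runs

Unit tests run on toy genomes (2 chromosomes, ~100 markers) and breeding
schemes shrunk in every dimension. The acceptance suite runs the full
design — 2,000 markers, reference 1000 -> 2350, 10 generations, all
three strategies — at 10 replicates, the package's desk-scale preset
(`SchemeConfig.desk()`); 50 replicates is the full-study default
(`n_replicates=50`) and sharpens the same contrasts. The acceptance
script exercises the optimal-contribution cap on 100 simulated candidate
sets of 20-200 individuals.

## What the synthetic data do and do not show

The generator reproduces the *structure* the methods assume — LD between
markers and QTL, family structure, an additive trait with the target
heritability, weighted records — but not the history of any real breed:
no mutation, no selection during burn-in, a uniform genetic map, and
founder frequencies that are not chip-ascertained. Passing tests
demonstrate internal correctness (oracle agreement, constraint
compliance, design arithmetic) and the qualitative strategy ordering
(optimal contributions conserve the most heterozygosity at a small cost
in merit, with truncation the mirror image); absolute trend magnitudes on
real data depend on genome and population parameters outside these
defaults and are not reproduction targets. Real-data use is supported
through the text readers (G-matrix, pedigree, phenotype, genotype
tables) feeding the same pipeline.
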