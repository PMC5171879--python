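# Methods

This note documents the models behind each stage, the defaults and why,
what the synthetic data do and do not emulate, and the numerical choices
a user should know before trusting or changing a result.

## Allometry and selection indices

Characters are ln-transformed and regressed on ln head width by ordinary
least squares, one line per population (a nest-level option exists; the
population level is the default reporting surface, matching how
residual-variance tables are conventionally printed). Residual variance
uses denominator n − 2. OLS rather than reduced-major-axis regression is
the default because the selection index is the *residual* variance around
a predictive line, not a symmetric structural slope; an RMA variant can
be derived from the same fits if needed.

Slope heterogeneity among populations is the extra-sum-of-squares F test
of the population × ln(HW) interaction (full model with per-population
slopes and intercepts vs common-slope reduced model). Variance-ratio
comparisons are two-sided, p = 2·min(P[F ≤ f], P[F ≥ f]), with a
caller-supplied Bonferroni multiplier: published F statistics of this
kind are often printed with inconsistent degrees of freedom, so the
routine is validated against a numerically integrated F CDF rather than
against any printed p. Paired and two-sample t tests follow the classical
pooled forms; a paired test on exactly identical vectors returns t = 0
rather than an error, while zero-variance *nonzero* differences are
refused as undefined.

## Microsatellite statistics

F-statistics are Weir–Cockerham (1984) moment estimators with
variance components summed over alleles and loci: θ (pairwise F_ST) from
the among-population component, f (F_IS) from the within-population
hierarchy. Nulls are permutational — alleles among individuals within a
population for f; whole individuals between the two populations for θ
(the natural exchangeable unit when genotypes, not gametes, are sampled).
All permutation p-values use the add-one convention
p = (exceedances + 1)/(permutations + 1) and report their seed.

Linkage disequilibrium between locus pairs uses the G log-likelihood
ratio on the two-locus genotype contingency table per population, with
single-locus genotypes permuted among individuals; per-population
p-values combine across populations by Fisher's method. Monomorphic
populations contribute p = 1 with a warning.

Queller–Goodnight relatedness is computed per dyad with numerators and
denominators summed over loci and both dyad orderings; reference allele
frequencies exclude the focal dyad's four genes (focal-pair exclusion),
removing the main small-sample bias. The population mean is the mean of
nest means; its 95% CI comes from a delete-one jackknife over nests
under a normal approximation. This is a documented stand-in for the
weighting scheme of the classic RELATEDNESS program, whose internals are
not fully published; the jackknife-over-nests CI respects the nest as
the natural resampling unit. The conventional "severe" significance
level (0.001) used with such relatedness scans is left to the caller,
not hard-coded.

Chord distance follows the PHYLIP gendist normalization
Dc² = 4[Σ_l(1 − Σ_a√(x·y))]/Σ_l(m_l − 1) with m_l the alleles observed
across the pair at locus l; a locus with no genes in either population is
skipped with a warning. The by-locus bootstrap resamples loci with
replacement (always the full locus count per replicate) and rebuilds the
whole Dc matrix.

## Trees

Neighbour joining is the standard Saitou–Nei Q-criterion agglomeration.
Two non-default behaviours are deliberate: ties in Q are broken by the
lexicographically smallest pair of cluster names (each cluster named by
its smallest member tip), making output independent of input row order;
and negative branch-length estimates — expected on non-additive chord
matrices — are clamped to zero with the deficit moved to the sister
edge, preserving the pair's path length (PHYLIP-compatible). Bootstrap
support of an internal edge is the integer percentage of replicate trees
containing the same bipartition. Rooting for downstream reconstruction
is an explicit user choice; the pipeline default is midpoint rooting,
since the distance matrices carry no outgroup.

## Random-OU ancestral reconstruction

Each trial draws (α, β, x₀, σ²) from the priors α ~ U(0,1), β and
x₀ ~ U(min, max of observed tips), σ² ~ U(1, 4000); simulates the trait
over the tree using the *exact* OU transition per branch (never an Euler
scheme, so step size cannot confound recovery tests); and scores the
simulated tips against observations with an independent Gaussian kernel
per tip. The kernel bandwidth is κ = 0.1 · SD(observed tips) by default —
scale-aware, so scores are comparable across characters measured on
different scales; note that with a common κ across trials the retained
set depends only on the summed squared tip error, so κ affects reported
scores but not which trials are kept. One simulation per parameter set is
the classical behaviour; `n_sims_per_trial` can average several to reduce
Monte-Carlo noise in the score. The best 100 of 100 000 trials (both
configurable) are retained; ancestral states are per-node means over the
retained set and α is summarized as retained mean ± SD. Ties in score
are broken by trial index; a fixed seed reproduces the retained set
exactly.

Trees are rescaled to unit height before reconstruction so that "α per
unit branch length" and the σ² interval keep a fixed meaning regardless
of the distance units of the input tree. This also means α values are
comparable across characters reconstructed on the same tree, but not
automatically across trees of different depth.

**A caution on α.** Calibration shows the retained-α distribution moves
in the right direction but weakly: on a 10-tip unit-height tree with
three characters generated at α = 0.9/0.7/0.3 (optimum 50, root 0,
σ² = 100), the retained-α means order correctly in aggregate over seeds,
but the full per-seed rank comes back correct in only roughly 4–7 of 10
runs at 20 000 trials. This is not an implementation artifact: an
exact-likelihood check (matrix-normal OU tip likelihood, importance
sampling over the same priors) recovers the rank even less often — a
single 10-tip realization simply carries little information about α
under these priors, and the posterior stays close to the prior mean.
Treat reconstructed α as a coarse comparative index across many tips or
characters, not as a per-character point estimate.

The branch-change analysis pairs |child − parent| state differences with
branch lengths; under drift (α = 0) the correlation with branch length
is positive (change accumulates with time), under strong reversion it is
attenuated. Significance uses Fisher's z = atanh(r)·√(n − 3) with n the
number of branches (published df bookkeeping for this statistic is
ambiguous; the convention here is stated and used consistently).

## Comparative layer

Independent contrasts implement Felsenstein's pruning algorithm with the
standard branch-length correction; polytomies are rejected rather than
silently resolved. Contrast correlations go through the origin,
r = Σab/√(Σa²Σb²), tested with z = atanh(r)·√(n − 2) for n contrasts
(one df absorbed by the origin constraint — again a documented
convention, since published df choices vary).

The partial Mantel statistic is the first-order partial Kendall τ_b —
the tie correction matters because 0/1 species-indicator matrices are
tie-heavy. The null permutes the labels (rows and columns jointly) of
the focal species matrix; p is two-sided with the add-one convention,
and an exact mode enumerates all n! permutations for small n. Because a
label permutation only permutes the off-diagonal pair vector, tie counts
and τ denominators are permutation-invariant; the implementation
exploits this to make 999-permutation tests effectively instant.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical skeleton of the study design:
eight populations × 10 nests × 30 workers with uniform head widths
(collectors deliberately sample all size classes, so no lognormal);
Gaussian ln-scale residuals with character-specific SDs (defaults 0.008 /
0.013 / 0.028 for HTL / FTSL / HTSL, chosen to land the residual-variance
table in the same numeric range as published tables of this design);
island-model allele frequencies via Dirichlet draws with concentration
(1 − F)/F around shared ancestral frequencies (four loci × 10 alleles),
which makes the generating F the exact expected differentiation; optional
one-queen-one-father nests giving diploid full-sib relatedness 0.5; and
exact OU trait simulation. They do **not** emulate measurement error,
null alleles or genotyping failure, mutation processes (stepwise vs
infinite alleles), spatial landscape structure, isolation-by-distance, or
nest-level trait covariance — so a green calibration says the estimators
recover what these idealized processes generate, not that the estimators
are robust to every field complication.

## Problem sizes and numerical choices

Calibration experiments are sized for minutes on one CPU: 20 island-model
replicates for θ recovery; 400 null replicates × 199 permutations for
test size; 1000 dyads for relatedness; 100 random additive matrices
(5–12 taxa) for NJ; 10 seeds × 20 000 trials for the α-recovery study; 50
paired replicates for the Brownian-vs-OU branch-change contrast; 500
replicates × 999 permutations for the partial-Mantel size. Degenerate
inputs are handled explicitly throughout: zero-length observations and
monomorphic loci are refused or flagged rather than silently absorbed,
infinite F ratios are reported as such, and every stochastic routine
takes and records an integer seed.
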