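# stasiscope

Tools for asking how **stabilizing selection** shapes the within- and
among-population variation of allometric characters — built around the
study design used for red wood ants (*Formica truncorum* / *F. yessensis*):
morphometric samples from isolated populations, microsatellite genotypes
of nestmates, a distance-based population phylogeny, and
ancestral-state reconstruction under an Ornstein–Uhlenbeck model of trait
evolution. It is aimed at evolutionary biologists who want the full chain
of that analysis — selection indices, F-statistics, chord-distance trees,
OU reconstruction, phylogenetically informed correlations — as one tested,
scriptable pipeline.

## The science in brief

**Selection index from allometry.** A character *y* growing allometrically
with body size *x* (head width) follows ln *y* = *a* + *S* ln *x*. The
variance of residuals around the fitted line measures how tightly the
character is canalized: strong stabilizing selection ⇒ small residual
variance within populations, small variance of *S* among populations.

**Population structure.** Weir–Cockerham moment estimators give the
inbreeding coefficient *f* (F_IS) and pairwise θ (F_ST), with significance
from permutation nulls; Queller–Goodnight regression relatedness checks
that nestmates are effectively unrelated (polydomous, polygynous
colonies), so nests can be pooled. Genetic distance between populations is
the Cavalli-Sforza–Edwards chord distance

&nbsp;&nbsp;&nbsp;&nbsp;Dc² = 4 [Σ_l (1 − Σ_a √(x_la · y_la))] / Σ_l (m_l − 1),

fed to Saitou–Nei neighbour joining with by-locus bootstrap support.

**Trait evolution.** Along a branch of length *t*, an OU process pulls the
trait toward an optimum β with strength α while diffusing at rate σ²:

&nbsp;&nbsp;&nbsp;&nbsp;x_child | x_parent ~ N(β + (x_parent − β) e^{−αt}, σ²(1 − e^{−2αt}) / 2α),

with α = 0 the Brownian (pure drift) limit. The reconstruction draws
100 000 random parameter sets (α ~ U(0,1); β, x₀ ~ U over the observed tip
range; σ² ~ U(1, 4000)), simulates the trait over the whole tree for each,
scores simulated against observed tips with a Gaussian kernel, keeps the
100 best trials, and averages: retained node states estimate ancestral
phenotypes, and the retained α distribution measures the strength of
stabilizing selection on the character. Independent contrasts and a
Kendall partial Mantel test round out the comparative layer.

Because no raw data are deposited for this kind of field study, the
package ships generators (`stasiscope.synthetic_data`) that emulate the
full design — log-log allometric growth with population-specific slopes,
island-model microsatellite differentiation with nest substructure, exact
OU simulation on a known tree — so every estimator is calibrated against
data whose truth is known (`stasiscope.calibration`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each prints what it found and writes its tables under `results/`:

```sh
python analysis/01_simulate.py          # morphometry + genotypes
python analysis/02_allometry.py         # slopes, residual variances
python analysis/03_popgen.py            # F-statistics, relatedness, Dc
python analysis/04_tree.py              # NJ + by-locus bootstrap
python analysis/05_ancestral_states.py  # OU reconstruction
python analysis/06_comparative.py       # contrasts + partial Mantel
python analysis/07_full_pipeline.py     # the same, one-shot, with manifest
```

`02_allometry.py` prints, for the default eight-population design
(generating residual SDs ordered HTL < FTSL < HTSL):

```
Residual variances (x 1e-5, ln scale), across-population margins:
  HTL   mean    6.5  sd  0.47
  FTSL  mean   16.6  sd  1.43
  HTSL  mean   76.8  sd  4.22
Among-population slope variance:
  HTL   8.948e-05
  FTSL  4.590e-04
  HTSL  1.348e-02
Selection-strength ranking by residual variance: HTL < FTSL < HTSL (strongest first)
```

— the strongly selected tibia (HTL) is the most canalized both within
populations (smallest residual variance) and among them (smallest slope
variance), the weakly selected hind tibial spur (HTSL) the least: the
pattern the selection-index logic is designed to expose. `03_popgen.py`
reports pairwise θ of 0.11–0.31 (all 28 pairs significant after
Bonferroni at 999 permutations) and within-nest relatedness between
−0.03 and +0.03 — differentiated populations, unrelated nestmates — and
`06_comparative.py`'s partial Mantel test on matrices generated with no
true species signal is duly non-significant (τ = −0.023, p = 0.95).

The same stages are available as a CLI (`stasiscope simulate|allometry|
popgen|tree|ou|contrasts|mantel|run|report`) for use on your own TSV,
GenePop and Newick files.

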