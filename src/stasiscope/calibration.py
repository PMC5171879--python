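"""Calibration experiments: does each estimator recover what generated it?

Because no raw data are public for this study design, the pipeline's
quantitative validation is simulation-based: each function here defines
one calibration experiment — its generating conditions, its problem sizes
and its measured quantity — in a single place, so the test suite and the
reproduction script exercise identical conditions.

The conditions are the study's: eight populations, four microsatellite
loci, nests of full sibs or unrelated workers, a 10-tip unit-height tree
with top-100-of-many trial retention, and so on. Problem sizes are chosen
to keep each experiment in the seconds-to-minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import comparative, ou_model, phylo, popgen
from .synthetic_data import (
    OUSimConfig,
    PopGenSimConfig,
    gen_distance_matrices,
    gen_microsatellites,
    gen_ou_traits,
    random_tree,
)

__all__ = [
    "fst_recovery",
    "fst_null_rejection",
    "relatedness_calibration",
    "nj_additive_recovery",
    "ou_alpha_recovery",
    "OU_RECOVERY_TRUTH",
    "bm_vs_ou_branch_signal",
    "mantel_type1_error",
]


def fst_recovery(
    target_fst: float = 0.2,
    n_seeds: int = 20,
    seed: int = 0,
    n_populations: int = 8,
    individuals_per_pop: int = 100,
) -> dict:
    """Mean multi-population Weir-Cockerham theta over replicate simulations.

    Island-model genotypes at the study's marker design (4 loci x 10
    alleles); the Dirichlet construction makes the generating F the
    expected differentiation, so the estimate should straddle it.
    """
    thetas = []
    for k in range(n_seeds):
        cfg = PopGenSimConfig(
            n_populations=n_populations,
            target_fst=target_fst,
            individuals_per_nest=individuals_per_pop // 10,
            nests_per_population=10,
            seed=seed * 1000 + k,
        )
        table = gen_microsatellites(cfg)
        thetas.append(popgen.multilocus_theta(table))
    thetas = np.array(thetas)
    return {
        "target": target_fst,
        "mean_theta": float(thetas.mean()),
        "sd_theta": float(thetas.std(ddof=1)),
        "n_seeds": n_seeds,
    }


def fst_null_rejection(
    n_replicates: int = 200,
    n_perm: int = 199,
    seed: int = 0,
    individuals_per_pop: int = 50,
) -> dict:
    """Type-I error of the pairwise-theta permutation test at F = 0.

    Two samples from one panmictic pool per replicate; the rejection rate
    at alpha = 0.05 should sit near the nominal level.
    """
    rejections = 0
    for k in range(n_replicates):
        cfg = PopGenSimConfig(
            n_populations=2,
            target_fst=0.0,
            individuals_per_nest=individuals_per_pop // 5,
            nests_per_population=5,
            seed=seed * 7919 + k,
        )
        table = gen_microsatellites(cfg)
        res = popgen.pairwise_fst(
            table, "pop01", "pop02", n_perm=n_perm, seed=seed * 31 + k
        )
        if res.p <= 0.05:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_perm": n_perm,
    }


def relatedness_calibration(
    n_dyads: int = 1000, seed: int = 0
) -> dict:
    """Mean Queller-Goodnight relatedness for unrelated vs full-sib nests.

    Unrelated nestmates (random union of gametes) should average near 0;
    single-queen single-father families near the diploid full-sib
    expectation of 0.5. Nest and population counts chosen so the requested
    number of within-nest dyads is available.
    """
    # nests of 5 workers -> 10 dyads per nest
    n_nests = max(1, n_dyads // 10)
    out = {}
    for label, family in (("unrelated", False), ("full_sib", True)):
        cfg = PopGenSimConfig(
            n_populations=1,
            target_fst=0.0,
            loci=(("L1", 10), ("L2", 10), ("L3", 10), ("L4", 10)),
            individuals_per_nest=5,
            nests_per_population=n_nests,
            family_structure=family,
            seed=seed + (1 if family else 0),
        )
        table = gen_microsatellites(cfg)
        rel = popgen.qg_relatedness(table, seed=seed)
        out[label] = {
            "mean_r": float(rel["mean_r"].iloc[0]),
            "n_dyads": int(rel["n_dyads"].iloc[0]),
        }
    return out


def nj_additive_recovery(
    n_matrices: int = 100, seed: int = 0, tol: float = 1e-9
) -> dict:
    """NJ consistency on additive matrices from random 5-12 taxon trees.

    For each random tree (branch lengths 0.05-1), the path-length matrix
    is handed to neighbour joining; success requires the exact bipartition
    set back and every pairwise path distance reproduced to ``tol``.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    for k in range(n_matrices):
        n_tips = int(rng.integers(5, 13))
        tree = random_tree(n_tips, seed=seed * 100000 + k)
        pdm = tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in tree.taxon_namespace)
        taxa = {t.label: t for t in tree.taxon_namespace}
        m = np.zeros((n_tips, n_tips))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    m[i, j] = m[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
        est = phylo.nj_tree(phylo.DistanceMatrix(labels=labels, matrix=m))
        # topology: unrooted bipartition sets must match
        tree_unrooted = tree.clone(depth=1)
        tree_unrooted.is_rooted = False
        tree_unrooted.collapse_basal_bifurcation()
        same_topo = phylo.bipartitions(est) == phylo.bipartitions(tree_unrooted)
        # branch lengths: compare induced path distances
        est_pdm = est.phylogenetic_distance_matrix()
        est_taxa = {t.label: t for t in est.taxon_namespace}
        ok_len = True
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    dd = est_pdm.patristic_distance(est_taxa[a], est_taxa[b])
                    if abs(dd - m[i, j]) > tol:
                        ok_len = False
        if same_topo and ok_len:
            exact += 1
    return {"n_matrices": n_matrices, "n_exact": exact}


#: Frozen truth for the alpha-recovery experiment: per-character
#: (alpha, optimum beta, root state x0, rate sigma2). The rate sits in the
#: usable low-mid range of the U(1, 4000) prior and the root starts away
#: from the optimum, giving the data a depth-dependent adaptation
#: transient — the feature that carries most information about alpha.
OU_RECOVERY_TRUTH = {
    "strong": (0.9, 50.0, 0.0, 100.0),
    "intermediate": (0.7, 50.0, 0.0, 100.0),
    "weak": (0.3, 50.0, 0.0, 100.0),
}


def ou_alpha_recovery(
    n_seeds: int = 10,
    n_trials: int = 20000,
    n_keep: int = 100,
    n_tips: int = 10,
    tree_seed: int = 42,
    seed: int = 0,
) -> dict:
    """Rank recovery of stabilizing-selection strength across characters.

    Three characters are simulated on one 10-tip unit-height tree under
    the frozen truths in :data:`OU_RECOVERY_TRUTH`; each is reconstructed
    with top-``n_keep`` retention and the retained-alpha means are ranked.
    Reports how often the full rank order (strong > intermediate > weak)
    and the extreme pair come back correct, plus the mean retained alpha
    per character over seeds.
    """
    tree = random_tree(n_tips, seed=tree_seed, unit_height=True)
    names = list(OU_RECOVERY_TRUTH)
    rank_ok = 0
    pair_ok = 0
    alpha_means = {ch: [] for ch in names}
    for s in range(n_seeds):
        means = {}
        for k, ch in enumerate(names):
            truth = OU_RECOVERY_TRUTH[ch]
            cfg = OUSimConfig(
                tree=tree, true_params={ch: truth}, seed=seed + 1000 + s * 10 + k
            )
            states = gen_ou_traits(cfg)[ch]
            tips = {
                lab: v for lab, v in states.items() if not lab.startswith("node")
            }
            summary = ou_model.ki_reconstruct(
                tree, tips, n_trials=n_trials, n_keep=n_keep, seed=seed + s * 3 + k
            )
            means[ch] = summary.alpha_mean
            alpha_means[ch].append(summary.alpha_mean)
        rank = sorted(means, key=means.get, reverse=True)
        rank_ok += rank == names
        pair_ok += means["strong"] > means["weak"]
    return {
        "n_seeds": n_seeds,
        "rank_correct": rank_ok,
        "pair_correct": pair_ok,
        "mean_alpha": {ch: float(np.mean(v)) for ch, v in alpha_means.items()},
    }


def bm_vs_ou_branch_signal(
    n_seeds: int = 50,
    n_tips: int = 10,
    tree_seed: int = 42,
    seed: int = 0,
) -> dict:
    """Branch-change/branch-length correlation: Brownian vs strong-OU traits.

    Under drift (alpha = 0) the change along a branch scales with its
    length, so the Pearson correlation between |change| and branch length
    should be positive in most replicates; under strong mean reversion
    (alpha near 1 on long branches) the correlation is attenuated. Each
    seed simulates one Brownian and one matched strong-OU character on the
    same tree (true node states are used for the changes, isolating the
    evolutionary-pattern signal from reconstruction noise).
    """
    tree = random_tree(n_tips, seed=tree_seed, unit_height=True)
    # long branches accentuate mean reversion: stretch the tree 5x
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= 5.0
    r_bm, r_ou = [], []
    for s in range(n_seeds):
        cfg = OUSimConfig(
            tree=tree,
            true_params={"bm": (0.0, 0.0, 0.0, 10.0), "ou": (1.0, 0.0, 0.0, 10.0)},
            seed=seed + 5000 + s,
        )
        states = gen_ou_traits(cfg)
        for name, sink in (("bm", r_bm), ("ou", r_ou)):
            deltas, blens, _ = ou_model.branch_changes(states[name], tree)
            r, _, _ = ou_model.change_length_correlation(deltas, blens)
            sink.append(r)
    r_bm = np.array(r_bm)
    r_ou = np.array(r_ou)
    return {
        "n_seeds": n_seeds,
        "bm_positive_fraction": float((r_bm > 0).mean()),
        "mean_r_bm": float(r_bm.mean()),
        "mean_r_ou": float(r_ou.mean()),
    }


def mantel_type1_error(
    n_replicates: int = 500,
    n_labels: int = 10,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Size of the partial Mantel test under the null.

    The genetic matrix is generated independent of the species labels
    (zero species weight, geography-correlated), so rejections at
    alpha = 0.05 estimate the type-I error.
    """
    rejections = 0
    for k in range(n_replicates):
        geo, species, genetic = gen_distance_matrices(
            n_labels, seed=seed * 4099 + k, geo_weight=1.0, species_weight=0.0
        )
        _, p = comparative.partial_mantel_kendall(
            species.to_numpy(),
            genetic.to_numpy(),
            geo.to_numpy(),
            n_perm=n_perm,
            seed=seed * 53 + k,
        )
        if p <= 0.05:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_perm": n_perm,
    }
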