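"""Population-genetic estimators: frequencies, F-statistics, LD,
relatedness, chord distance and the by-locus bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stasiscope import popgen
from stasiscope.popgen import AlleleFreqs
from stasiscope.synthetic_data import PopGenSimConfig, gen_microsatellites


def geno_table(rows):
    """rows: (pop, nest, ind, locus, a1, a2)"""
    return pd.DataFrame(
        rows,
        columns=["population", "nest", "individual", "locus", "allele_1", "allele_2"],
    )


class TestAlleleFrequencies:
    def test_single_homozygote(self):
        t = geno_table([("p1", "n1", "i1", "L1", 101, 101)])
        f = popgen.allele_frequencies(t)
        assert f.freqs[("p1", "L1")] == {101: 1.0}
        assert f.n_genes[("p1", "L1")] == 2

    def test_three_of_four_genes(self):
        t = geno_table(
            [("p1", "n1", "i1", "L1", 101, 102), ("p1", "n1", "i2", "L1", 102, 102)]
        )
        f = popgen.allele_frequencies(t)
        assert f.freqs[("p1", "L1")][102] == pytest.approx(0.75)

    def test_counting_oracle_on_random_table(self, small_genotypes):
        f = popgen.allele_frequencies(small_genotypes)
        sub = small_genotypes[
            (small_genotypes["population"] == "pop01")
            & (small_genotypes["locus"] == "L2")
        ]
        genes = np.concatenate([sub["allele_1"], sub["allele_2"]])
        for allele in np.unique(genes):
            assert f.freqs[("pop01", "L2")][allele] == pytest.approx(
                (genes == allele).mean()
            )

    def test_missing_genes_excluded_and_flagged(self):
        t = geno_table(
            [("p1", "n1", "i1", "L1", 0, 0), ("p1", "n1", "i2", "L1", 101, 0)]
        )
        # allele code 0 marks a missing gene
        with pytest.warns(UserWarning, match="no observed genes"):
            f = popgen.allele_frequencies(
                geno_table([("p1", "n1", "i1", "L1", 0, 0)])
            )
            assert f.freqs[("p1", "L1")] == {}


class TestWeirCockerham:
    def test_two_allele_textbook_form_on_small_example(self):
        # hand-computable 2-population, 1-locus, 2-allele example
        rows = []
        # pop a: 3 inds: 1/1, 1/2, 1/2 ; pop b: 3 inds: 2/2, 2/2, 1/2
        for i, (a1, a2) in enumerate([(1, 1), (1, 2), (1, 2)]):
            rows.append(("a", "n", f"a{i}", "L1", a1, a2))
        for i, (a1, a2) in enumerate([(2, 2), (2, 2), (1, 2)]):
            rows.append(("b", "n", f"b{i}", "L1", a1, a2))
        t = geno_table(rows)
        theta = popgen.multilocus_theta(t)
        # independent two-allele computation (textbook components for one
        # allele; the second allele mirrors them exactly)
        n_i = np.array([3.0, 3.0])
        p_i = np.array([4 / 6, 1 / 6])  # frequency of allele 1
        h_i = np.array([2 / 3, 1 / 3])
        r = 2
        nbar = 3.0
        n_total = 6.0
        nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
        pbar = (n_i * p_i).sum() / n_total
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_total
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        assert theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_fixed_difference_gives_theta_one(self):
        rows = []
        for i in range(5):
            rows.append(("a", "n", f"a{i}", "L1", 1, 1))
            rows.append(("b", "n", f"b{i}", "L1", 2, 2))
        assert popgen.multilocus_theta(geno_table(rows)) == pytest.approx(1.0)

    def test_panmictic_pool_theta_near_zero(self):
        table = gen_microsatellites(
            PopGenSimConfig(
                n_populations=2, target_fst=0.0,
                individuals_per_nest=20, nests_per_population=5, seed=3,
            )
        )
        res = popgen.pairwise_fst(table, "pop01", "pop02", n_perm=99, seed=1)
        assert abs(res.estimate) < 0.02
        assert res.p > 0.05

    def test_differentiated_pair_detected(self):
        table = gen_microsatellites(
            PopGenSimConfig(
                n_populations=2, target_fst=0.3,
                individuals_per_nest=10, nests_per_population=5, seed=4,
            )
        )
        res = popgen.pairwise_fst(table, "pop01", "pop02", n_perm=199, seed=1)
        assert res.estimate > 0.1
        assert res.p == pytest.approx(1 / 200, abs=1e-12)

    def test_permutation_result_reproducible(self, small_genotypes):
        r1 = popgen.pairwise_fst(small_genotypes, "pop01", "pop02", n_perm=99, seed=5)
        r2 = popgen.pairwise_fst(small_genotypes, "pop01", "pop02", n_perm=99, seed=5)
        assert r1.estimate == r2.estimate and r1.p == r2.p


class TestFis:
    def test_heterozygote_excess_negative_f(self):
        rows = [("p", "n", f"i{k}", "L1", 1, 2) for k in range(10)]
        res = popgen.fis(geno_table(rows), "p", n_perm=49, seed=1)
        assert res.estimate < 0

    def test_hardy_weinberg_f_near_zero(self, rng):
        rows = []
        for k in range(200):
            a1, a2 = rng.integers(1, 6, size=2) if True else (1, 1)
            rows.append(("p", "n", f"i{k}", "L1", int(a1), int(a2)))
        res = popgen.fis(geno_table(rows), "p", n_perm=99, seed=2)
        assert abs(res.estimate) < 0.1

    def test_inbreeding_recovered(self, rng):
        # genotypes with IBD probability 1/2: expected f = 0.5
        freqs = np.full(8, 1 / 8)
        rows = []
        for k in range(500):
            a1 = rng.choice(8, p=freqs) + 1
            a2 = a1 if rng.random() < 0.5 else rng.choice(8, p=freqs) + 1
            rows.append(("p", "n", f"i{k}", "L1", int(a1), int(a2)))
        res = popgen.fis(geno_table(rows), "p", n_perm=99, seed=3)
        assert res.estimate == pytest.approx(0.5, abs=0.08)
        assert res.p == pytest.approx(0.01, abs=1e-12)

    def test_monomorphic_population_reported_na(self):
        rows = [("p", "n", f"i{k}", "L1", 1, 1) for k in range(5)]
        res = popgen.fis(geno_table(rows), "p", n_perm=9, seed=1)
        assert np.isnan(res.estimate) and res.p is None


class TestLD:
    def test_duplicated_locus_maximal_statistic(self, rng):
        rows = []
        for k in range(40):
            a1, a2 = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            rows.append(("p", "n", f"i{k}", "L1", a1, a2))
            rows.append(("p", "n", f"i{k}", "L2", a1, a2))
        p, per_pop = popgen.ld_test(geno_table(rows), "L1", "L2", n_perm=99, seed=1)
        assert per_pop["p"] == pytest.approx(1 / 100, abs=1e-12)

    def test_independent_loci_not_extreme(self, small_genotypes):
        p, per_pop = popgen.ld_test(small_genotypes, "L1", "L2", n_perm=199, seed=2)
        assert p > 0.005

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # 4 individuals: the permutation null has 4! = 24 equally likely
        # genotype arrangements
        rows = []
        genos_a = [(1, 1), (1, 2), (2, 2), (1, 2)]
        genos_b = [(1, 2), (1, 1), (2, 2), (2, 2)]
        for k, ((a1, a2), (b1, b2)) in enumerate(zip(genos_a, genos_b)):
            rows.append(("p", "n", f"i{k}", "La", a1, a2))
            rows.append(("p", "n", f"i{k}", "Lb", b1, b2))
        t = geno_table(rows)
        _, per_pop = popgen.ld_test(t, "La", "Lb", n_perm=4999, seed=3)

        # exhaustive oracle over all arrangements of locus-a genotypes
        def g_stat(ca, cb):
            ua, ia = np.unique(ca, return_inverse=True)
            ub, ib = np.unique(cb, return_inverse=True)
            cont = np.zeros((len(ua), len(ub)))
            np.add.at(cont, (ia, ib), 1.0)
            n = cont.sum()
            row = cont.sum(axis=1, keepdims=True)
            col = cont.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(cont > 0, cont * np.log(cont / (row * col / n)), 0.0)
            return 2 * terms.sum()

        ca = np.array([a1 * 10 + a2 for a1, a2 in genos_a])
        cb = np.array([b1 * 10 + b2 for b1, b2 in genos_b])
        obs = g_stat(ca, cb)
        exceed = sum(
            g_stat(ca[list(perm)], cb) >= obs
            for perm in itertools.permutations(range(4))
        )
        exact = exceed / 24
        assert per_pop["p"] == pytest.approx(exact, abs=0.03)

    def test_monomorphic_locus_flagged(self):
        rows = []
        for k in range(6):
            rows.append(("p", "n", f"i{k}", "La", 1, 1))
            rows.append(("p", "n", f"i{k}", "Lb", int(k % 2) + 1, 2))
        with pytest.warns(UserWarning, match="monomorphic"):
            p, per_pop = popgen.ld_test(geno_table(rows), "La", "Lb", n_perm=9, seed=1)
        assert per_pop["p"] == 1.0


class TestRelatedness:
    def test_clone_relatedness_is_one(self):
        counts = [{1: 10.0, 2: 10.0, 3: 10.0}] * 4
        g = np.array([[1, 2]] * 4)
        assert popgen.pairwise_qg(g, g.copy(), counts) == pytest.approx(1.0)

    def test_unrelated_dyads_centre_at_zero(self):
        table = gen_microsatellites(
            PopGenSimConfig(
                n_populations=1,
                loci=(("L1", 10), ("L2", 10), ("L3", 10), ("L4", 10)),
                target_fst=0.0, individuals_per_nest=5,
                nests_per_population=40, family_structure=False, seed=23,
            )
        )
        rel = popgen.qg_relatedness(table, seed=1)
        assert abs(rel["mean_r"].iloc[0]) < 0.04
        assert rel["ci95_halfwidth"].iloc[0] > 0

    def test_single_nest_population_flagged(self):
        rows = []
        for k in range(4):
            rows.append(("p", "n1", f"i{k}", "L1", (k % 3) + 1, ((k + 1) % 3) + 1))
        with pytest.warns(UserWarning, match="single nest"):
            rel = popgen.qg_relatedness(geno_table(rows), seed=1)
        assert np.isnan(rel["ci95_halfwidth"].iloc[0])


class TestChordDistance:
    def freqs(self, fa, fb, loci=("L1",)):
        f = {}
        n = {}
        for lc in loci:
            f[("a", lc)] = fa
            f[("b", lc)] = fb
            n[("a", lc)] = 10
            n[("b", lc)] = 10
        return AlleleFreqs(freqs=f, n_genes=n, populations=["a", "b"], loci=list(loci))

    def test_identical_frequencies_zero(self):
        f = self.freqs({1: 0.3, 2: 0.7}, {1: 0.3, 2: 0.7})
        assert popgen.chord_distance(f, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_normalization(self):
        # one locus, two alleles, fixed difference: inner term 1, m-1 = 1,
        # Dc^2 = 4 -> Dc = 2
        f = self.freqs({1: 1.0}, {2: 1.0})
        assert popgen.chord_distance(f, "a", "b") == pytest.approx(2.0)

    def test_symmetry_and_positivity_on_random_frequencies(self, rng):
        for _ in range(5):
            va = rng.dirichlet(np.ones(5))
            vb = rng.dirichlet(np.ones(5))
            fa = {i + 1: v for i, v in enumerate(va)}
            fb = {i + 1: v for i, v in enumerate(vb)}
            f = self.freqs(fa, fb, loci=("L1", "L2"))
            d_ab = popgen.chord_distance(f, "a", "b")
            d_ba = popgen.chord_distance(f, "b", "a")
            assert d_ab == pytest.approx(d_ba, abs=1e-12)
            assert d_ab > 0

    def test_empty_locus_skipped_with_warning(self):
        f = self.freqs({1: 1.0}, {2: 1.0}, loci=("L1", "L2"))
        f.freqs[("b", "L2")] = {}
        with pytest.warns(UserWarning, match="skipped"):
            d = popgen.chord_distance(f, "a", "b")
        assert d == pytest.approx(2.0)


class TestBylocusBootstrap:
    def test_replicates_use_full_locus_count(self, small_genotypes):
        reps = popgen.bylocus_bootstrap_dc(small_genotypes, n_reps=3, seed=1)
        assert len(reps) == 3
        for rep in reps:
            assert rep.matrix.shape == (3, 3)

    def test_single_locus_refused(self):
        rows = [("p", "n", f"i{k}", "L1", 1, 2) for k in range(4)]
        rows += [("q", "n", f"j{k}", "L1", 1, 2) for k in range(4)]
        with pytest.raises(ValueError, match="2 loci"):
            popgen.bylocus_bootstrap_dc(geno_table(rows), n_reps=2, seed=1)

    def test_seed_determinism(self, small_genotypes):
        r1 = popgen.bylocus_bootstrap_dc(small_genotypes, n_reps=4, seed=9)
        r2 = popgen.bylocus_bootstrap_dc(small_genotypes, n_reps=4, seed=9)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.matrix, b.matrix)
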