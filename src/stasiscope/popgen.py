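"""Microsatellite population genetics.

Codominant diploid genotypes, individuals grouped by nest within
population. Provides:

* allele frequencies per population and locus,
* Weir-Cockerham moment estimators of F_IS (f) and pairwise F_ST (theta)
  with permutation nulls,
* a genotypic linkage-disequilibrium permutation test,
* Queller-Goodnight regression relatedness of nestmates with a
  jackknife-over-nests confidence interval,
* the Cavalli-Sforza-Edwards chord distance Dc and its by-locus bootstrap.

Permutation p-values use the add-one convention
p = (exceedances + 1) / (permutations + 1), so p is never exactly zero,
and every permutation result records its statistic, p, n_perm and seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import DistanceMatrix

__all__ = [
    "AlleleFreqs",
    "FStatResult",
    "allele_frequencies",
    "fis",
    "pairwise_fst",
    "multilocus_theta",
    "ld_test",
    "qg_relatedness",
    "pairwise_qg",
    "chord_distance",
    "dc_matrix",
    "bylocus_bootstrap_dc",
]

MISSING = 0  # allele code for a missing gene


@dataclass
class AlleleFreqs:
    """Per-(population, locus) allele frequencies over non-missing genes."""

    freqs: dict[tuple[str, str], dict[int, float]]
    n_genes: dict[tuple[str, str], int]
    populations: list[str]
    loci: list[str]

    def vector(self, pop: str, locus: str, alleles: list[int]) -> np.ndarray:
        f = self.freqs[(pop, locus)]
        return np.array([f.get(a, 0.0) for a in alleles])


@dataclass(frozen=True)
class FStatResult:
    estimate: float
    p: float | None
    n_permutations: int
    seed: int | None
    per_locus: dict[str, float] = field(default_factory=dict)


def _split_genotypes(table: pd.DataFrame):
    """(populations, loci, arrays): per locus an (n, 2) int array + pop codes."""
    pops = sorted(table["population"].unique())
    loci = sorted(table["locus"].unique())
    return pops, loci


def allele_frequencies(table: pd.DataFrame) -> AlleleFreqs:
    """Tally allele frequencies; missing genes excluded from the denominator.

    A (population, locus) cell with zero observed genes is kept with an
    empty frequency map and flagged with a warning rather than dropped.
    """
    pops, loci = _split_genotypes(table)
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_genes: dict[tuple[str, str], int] = {}
    grouped = table.groupby(["population", "locus"], sort=True)
    for pop in pops:
        for locus in loci:
            try:
                sub = grouped.get_group((pop, locus))
                genes = np.concatenate(
                    [sub["allele_1"].to_numpy(int), sub["allele_2"].to_numpy(int)]
                )
                genes = genes[genes != MISSING]
            except KeyError:
                genes = np.array([], dtype=int)
            if len(genes) == 0:
                warnings.warn(
                    f"no observed genes for population {pop!r} at locus {locus!r}"
                )
                freqs[(pop, locus)] = {}
                n_genes[(pop, locus)] = 0
                continue
            alleles, counts = np.unique(genes, return_counts=True)
            freqs[(pop, locus)] = {
                int(a): c / len(genes) for a, c in zip(alleles, counts)
            }
            n_genes[(pop, locus)] = int(len(genes))
    return AlleleFreqs(freqs=freqs, n_genes=n_genes, populations=pops, loci=loci)


# ---------------------------------------------------------------------------
# Weir-Cockerham moment estimators


def _locus_matrix(table: pd.DataFrame, locus: str, pops: list[str]):
    """Per-population list of (n_i, 2) genotype arrays at one locus."""
    sub = table[table["locus"] == locus]
    out = []
    for pop in pops:
        g = sub[sub["population"] == pop][["allele_1", "allele_2"]].to_numpy(int)
        g = g[(g != MISSING).all(axis=1)]
        out.append(g)
    return out


def _wc_components(genos: list[np.ndarray]):
    """Variance components (a, b, c) summed over alleles at one locus.

    ``genos`` holds one (n_i, 2) diploid genotype array per population.
    Returns per-allele component sums for the among-population (a),
    among-individual-within-population (b) and within-individual (c)
    levels of the hierarchy.
    """
    r = len(genos)
    n_i = np.array([len(g) for g in genos], dtype=float)
    if np.any(n_i < 1) or r < 2:
        raise ValueError("each population needs >= 1 genotyped individual")
    alleles = np.unique(np.concatenate([g.ravel() for g in genos]))
    nbar = n_i.mean()
    n_total = n_i.sum()
    nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([(g == allele).sum() / (2 * len(g)) for g in genos])
        h_i = np.array(
            [((g == allele).sum(axis=1) == 1).mean() for g in genos]
        )
        pbar = (n_i * p_i).sum() / n_total
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_total
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def multilocus_theta(table: pd.DataFrame, pops: list[str] | None = None) -> float:
    """Weir-Cockerham theta (F_ST) with components summed over loci."""
    all_pops, loci = _split_genotypes(table)
    pops = pops if pops is not None else all_pops
    num = den = 0.0
    for locus in loci:
        genos = _locus_matrix(table, locus, pops)
        a, b, c = _wc_components(genos)
        num += a
        den += a + b + c
    if den == 0:
        return float("nan")
    return num / den


def _single_pop_f(genos_by_locus: list[np.ndarray]) -> float:
    """Weir-Cockerham f (F_IS) for one population, loci components summed."""
    num = den = 0.0
    for g in genos_by_locus:
        n = len(g)
        if n < 2:
            continue
        for allele in np.unique(g):
            p = (g == allele).sum() / (2 * n)
            h = ((g == allele).sum(axis=1) == 1).mean()
            b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
            c = h / 2.0
            num += c
            den += b + c
    if den == 0:
        return float("nan")
    return 1.0 - num / den


def fis(
    table: pd.DataFrame,
    population: str,
    n_perm: int = 999,
    seed: int = 0,
) -> FStatResult:
    """Within-population inbreeding coefficient f with a permutation null.

    The null shuffles alleles among individuals within the population at
    each locus (destroying within-individual correlation while preserving
    allele frequencies); p is one-sided for f > 0. A fully monomorphic
    population yields estimate NaN with p None.
    """
    sub = table[table["population"] == population]
    if sub["individual"].nunique() < 2:
        raise ValueError("need >= 2 individuals")
    loci = sorted(sub["locus"].unique())
    genos = [
        sub[sub["locus"] == lc][["allele_1", "allele_2"]].to_numpy(int)
        for lc in loci
    ]
    genos = [g[(g != MISSING).all(axis=1)] for g in genos]
    obs = _single_pop_f(genos)
    if np.isnan(obs):
        return FStatResult(float("nan"), None, 0, seed)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = []
        for g in genos:
            flat = rng.permutation(g.ravel())
            perm.append(flat.reshape(-1, 2))
        if _single_pop_f(perm) >= obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return FStatResult(float(obs), float(p), n_perm, seed)


def pairwise_fst(
    table: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    n_perm: int = 999,
    seed: int = 0,
) -> FStatResult:
    """Pairwise Weir-Cockerham theta with an individual-permutation null.

    The null reassigns individuals at random between the two populations
    (sample sizes preserved); p is one-sided for theta greater than or
    equal to the observed value.
    """
    loci = sorted(table["locus"].unique())
    genos_a, genos_b = [], []
    for lc in loci:
        ga, gb = _locus_matrix(table, lc, [pop_a, pop_b])
        genos_a.append(ga)
        genos_b.append(gb)
    n_a = len(genos_a[0])
    n_b = len(genos_b[0])
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 individuals in each population")

    def theta_of(split_a, split_b):
        num = den = 0.0
        per_locus = {}
        for lc, ga, gb in zip(loci, split_a, split_b):
            a, b, c = _wc_components([ga, gb])
            per_locus[lc] = a / (a + b + c) if (a + b + c) != 0 else float("nan")
            num += a
            den += a + b + c
        return (num / den if den != 0 else float("nan")), per_locus

    obs, per_locus = theta_of(genos_a, genos_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    pooled = [np.concatenate([ga, gb]) for ga, gb in zip(genos_a, genos_b)]
    for _ in range(n_perm):
        idx = rng.permutation(n_a + n_b)
        pa = [g[idx[:n_a]] for g in pooled]
        pb = [g[idx[n_a:]] for g in pooled]
        t, _ = theta_of(pa, pb)
        if t >= obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return FStatResult(float(obs), float(p), n_perm, seed, per_locus=per_locus)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _g_statistic(contingency: np.ndarray) -> float:
    """G (log-likelihood-ratio) statistic for a two-way table."""
    n = contingency.sum()
    if n == 0:
        return 0.0
    row = contingency.sum(axis=1, keepdims=True)
    col = contingency.sum(axis=0, keepdims=True)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            contingency > 0, contingency * np.log(contingency / expected), 0.0
        )
    return float(2.0 * terms.sum())


def _geno_codes(g: np.ndarray) -> np.ndarray:
    """Order-free single-locus genotype code for each individual."""
    lo = np.minimum(g[:, 0], g[:, 1])
    hi = np.maximum(g[:, 0], g[:, 1])
    return lo * 1000 + hi


def ld_test(
    table: pd.DataFrame,
    locus_a: str,
    locus_b: str,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, dict[str, float]]:
    """Genotypic linkage-disequilibrium test between two loci.

    Within each population, the statistic is the G log-likelihood ratio on
    the two-locus genotype contingency table; the null permutes the
    single-locus genotypes of one locus among individuals within the
    population. Per-population p-values are combined over populations with
    Fisher's method. A population monomorphic at either locus contributes
    p = 1 (flagged by a warning).

    Returns (combined p, per-population p).
    """
    rng = np.random.default_rng(seed)
    per_pop: dict[str, float] = {}
    wide = table.pivot_table(
        index=["population", "individual"],
        columns="locus",
        values=["allele_1", "allele_2"],
        aggfunc="first",
    )
    for pop, sub in wide.groupby(level="population"):
        ga = sub[[("allele_1", locus_a), ("allele_2", locus_a)]].to_numpy(int)
        gb = sub[[("allele_1", locus_b), ("allele_2", locus_b)]].to_numpy(int)
        keep = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
        ga, gb = ga[keep], gb[keep]
        codes_a = _geno_codes(ga)
        codes_b = _geno_codes(gb)
        if len(np.unique(codes_a)) < 2 or len(np.unique(codes_b)) < 2:
            warnings.warn(f"population {pop!r}: monomorphic locus, LD p set to 1")
            per_pop[pop] = 1.0
            continue

        def g_of(ca, cb):
            ua, ia = np.unique(ca, return_inverse=True)
            ub, ib = np.unique(cb, return_inverse=True)
            cont = np.zeros((len(ua), len(ub)))
            np.add.at(cont, (ia, ib), 1.0)
            return _g_statistic(cont)

        obs = g_of(codes_a, codes_b)
        exceed = 0
        for _ in range(n_perm):
            if g_of(rng.permutation(codes_a), codes_b) >= obs:
                exceed += 1
        per_pop[pop] = (exceed + 1) / (n_perm + 1)
    k = len(per_pop)
    x = -2.0 * np.sum(np.log(list(per_pop.values())))
    combined = float(stats.chi2.sf(x, 2 * k))
    return combined, per_pop


# ---------------------------------------------------------------------------
# Queller-Goodnight relatedness


def pairwise_qg(
    gx: np.ndarray,
    gy: np.ndarray,
    counts: list[dict[int, float]],
) -> float:
    """Queller-Goodnight regression relatedness for one dyad.

    ``gx``/``gy`` are per-locus diploid genotypes (k, 2); ``counts`` maps
    allele -> gene count per locus for the reference population *including*
    the dyad — the dyad's own genes are removed here before frequencies are
    formed (focal-pair exclusion). Numerators and denominators are summed
    over loci and both orderings of the dyad before dividing.
    """
    num = den = 0.0
    for locus_i in range(len(counts)):
        a, b = int(gx[locus_i, 0]), int(gx[locus_i, 1])
        c, d = int(gy[locus_i, 0]), int(gy[locus_i, 1])
        if MISSING in (a, b, c, d):
            continue
        cnt = dict(counts[locus_i])
        for al in (a, b, c, d):
            cnt[al] = cnt.get(al, 0) - 1
        total = sum(cnt.values())
        if total <= 0:
            continue
        p = {al: v / total for al, v in cnt.items()}
        for (e, f), (g, h) in (((a, b), (c, d)), ((c, d), (a, b))):
            sxy = 0.5 * (
                (e == g) + (e == h) + (f == g) + (f == h)
            )
            num += sxy - p.get(e, 0.0) - p.get(f, 0.0)
            den += 1.0 + (e == f) - p.get(e, 0.0) - p.get(f, 0.0)
    if den == 0:
        return float("nan")
    return num / den


def qg_relatedness(
    table: pd.DataFrame, max_dyads_per_nest: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Mean within-nest relatedness per population with a jackknife CI.

    All within-nest dyads (optionally subsampled) are scored with
    :func:`pairwise_qg` against population allele frequencies under
    focal-pair exclusion. The 95% CI half-width comes from a delete-one
    jackknife over nests (normal approximation); populations with a single
    nest get a NaN half-width and a warning.

    Returns a DataFrame indexed by population with columns
    ``mean_r, ci95_halfwidth, n_nests, n_dyads``.
    """
    rng = np.random.default_rng(seed)
    pops, loci = _split_genotypes(table)
    wide = table.pivot_table(
        index=["population", "nest", "individual"],
        columns="locus",
        values=["allele_1", "allele_2"],
        aggfunc="first",
    )
    rows = []
    for pop in pops:
        sub = wide.loc[pop]
        geno = np.stack(
            [
                sub[[("allele_1", lc), ("allele_2", lc)]].to_numpy(int)
                for lc in loci
            ],
            axis=1,
        )  # (n_ind, n_loci, 2)
        counts = []
        for li in range(len(loci)):
            genes = geno[:, li, :].ravel()
            genes = genes[genes != MISSING]
            al, ct = np.unique(genes, return_counts=True)
            counts.append({int(a): float(c) for a, c in zip(al, ct)})
        nests = sub.index.get_level_values("nest").to_numpy()
        nest_ids = sorted(set(nests))
        nest_means = []
        n_dyads = 0
        for nest in nest_ids:
            idx = np.flatnonzero(nests == nest)
            dyads = list(itertools.combinations(idx, 2))
            if not dyads:
                continue
            if max_dyads_per_nest is not None and len(dyads) > max_dyads_per_nest:
                pick = rng.choice(len(dyads), size=max_dyads_per_nest, replace=False)
                dyads = [dyads[i] for i in pick]
            vals = [
                pairwise_qg(geno[i], geno[j], counts) for i, j in dyads
            ]
            vals = [v for v in vals if not np.isnan(v)]
            if vals:
                nest_means.append(float(np.mean(vals)))
                n_dyads += len(vals)
        if not nest_means:
            continue
        mean_r = float(np.mean(nest_means))
        if len(nest_means) < 2:
            warnings.warn(f"population {pop!r}: single nest, CI undefined")
            half = float("nan")
        else:
            m = len(nest_means)
            jack = np.array(
                [np.mean(np.delete(nest_means, i)) for i in range(m)]
            )
            se = np.sqrt((m - 1) / m * np.sum((jack - jack.mean()) ** 2))
            half = float(1.959963984540054 * se)
        rows.append((pop, mean_r, half, len(nest_means), n_dyads))
    return pd.DataFrame(
        rows, columns=["population", "mean_r", "ci95_halfwidth", "n_nests", "n_dyads"]
    ).set_index("population")


# ---------------------------------------------------------------------------
# chord distance


def chord_distance(freqs: AlleleFreqs, pop_a: str, pop_b: str) -> float:
    """Cavalli-Sforza-Edwards chord distance Dc between two populations.

    Allele-frequency vectors are unit vectors on a hypersphere once
    square-rooted, so 1 - sum_a sqrt(x_a * y_a) measures angular
    separation at one locus. Following the PHYLIP gendist convention,

        Dc^2 = [sum_l (1 - sum_a sqrt(x_la * y_la))] * 4 / sum_l (m_l - 1)

    where m_l counts the alleles observed at locus l across the pair.
    Loci with zero observed genes in either population are skipped with a
    warning.
    """
    inner = 0.0
    m_sum = 0
    used = 0
    for locus in freqs.loci:
        fa = freqs.freqs[(pop_a, locus)]
        fb = freqs.freqs[(pop_b, locus)]
        if not fa or not fb:
            warnings.warn(f"locus {locus!r}: no genes in one population; skipped")
            continue
        alleles = sorted(set(fa) | set(fb))
        xa = np.array([fa.get(a, 0.0) for a in alleles])
        xb = np.array([fb.get(a, 0.0) for a in alleles])
        inner += 1.0 - float(np.sqrt(xa * xb).sum())
        m_sum += len(alleles) - 1
        used += 1
    if used == 0:
        raise ValueError("no shared locus with observed genes")
    if m_sum == 0:
        return 0.0
    dc2 = inner * 4.0 / m_sum
    return float(np.sqrt(max(dc2, 0.0)))


def dc_matrix(freqs: AlleleFreqs) -> DistanceMatrix:
    """Full symmetric Dc matrix over all populations."""
    pops = freqs.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = chord_distance(freqs, pops[i], pops[j])
    return DistanceMatrix(labels=list(pops), matrix=m)


def bylocus_bootstrap_dc(
    table: pd.DataFrame, n_reps: int = 1000, seed: int = 0
) -> list[DistanceMatrix]:
    """Resample loci with replacement; one full Dc matrix per replicate.

    Each replicate draws exactly as many loci as observed. Repeated draws
    of a locus contribute repeated terms to both sums of the Dc formula.
    """
    pops, loci = _split_genotypes(table)
    if len(loci) < 2:
        raise ValueError("by-locus bootstrap needs >= 2 loci")
    freqs = allele_frequencies(table)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        draw = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        rep = AlleleFreqs(
            freqs={
                (p, f"{lc}#{k}"): freqs.freqs[(p, lc)]
                for p in pops
                for k, lc in enumerate(draw)
            },
            n_genes={
                (p, f"{lc}#{k}"): freqs.n_genes[(p, lc)]
                for p in pops
                for k, lc in enumerate(draw)
            },
            populations=pops,
            loci=[f"{lc}#{k}" for k, lc in enumerate(draw)],
        )
        out.append(dc_matrix(rep))
    return out
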