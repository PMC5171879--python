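"""Synthetic data generators emulating the study design.

No raw morphometric or genotypic data are deposited for this kind of field
study, so every downstream stage is exercised on synthetic inputs that carry
the statistical structure the analysis assumes:

* log-log allometric growth with population-specific slopes and
  character-specific residual variances (:func:`gen_morphometry`),
* island-model microsatellite differentiation with optional queen-family
  substructure within nests (:func:`gen_microsatellites`),
* Ornstein-Uhlenbeck trait evolution on a known tree via the exact
  transition law (:func:`gen_ou_traits`),
* correlated distance matrices for partial Mantel calibration
  (:func:`gen_distance_matrices`).

All generators are pure functions of (config, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "MorphSimConfig",
    "PopGenSimConfig",
    "OUSimConfig",
    "gen_morphometry",
    "gen_microsatellites",
    "gen_ou_traits",
    "ou_transition",
    "gen_distance_matrices",
    "DEFAULT_CHARACTERS",
]

#: Character vocabulary: head width (the body-size proxy) plus tibia and
#: tibial-spur lengths of the fore, middle and hind legs.
DEFAULT_CHARACTERS = ("HW", "HTL", "FTSL", "HTSL", "MTSL")


@dataclass(frozen=True)
class PopulationSpec:
    """One population's true allometric parameters.

    Slopes/intercepts act on the ln scale: ln(y) = intercept + slope*ln(HW).
    ``residual_sd`` is the character-specific SD of the Gaussian deviation
    around that line, i.e. the quantity whose square is the selection index.
    """

    id: str
    latitude: float
    slopes: dict[str, float]
    intercepts: dict[str, float]
    residual_sd: dict[str, float]


@dataclass(frozen=True)
class MorphSimConfig:
    populations: tuple[PopulationSpec, ...]
    nests_per_population: int = 10
    workers_per_nest: int = 30
    hw_range: tuple[float, float] = (1.0, 2.2)
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("populations: at least one population required")
        if self.nests_per_population < 1:
            raise ValueError("nests_per_population: must be >= 1")
        if self.workers_per_nest < 1:
            raise ValueError("workers_per_nest: must be >= 1")
        lo, hi = self.hw_range
        if not lo < hi:
            raise ValueError("hw_range: min must be < max")
        if lo <= 0:
            raise ValueError("hw_range: head widths must be positive (mm)")
        for pop in self.populations:
            for ch, sd in pop.residual_sd.items():
                if sd < 0:
                    raise ValueError(
                        f"residual_sd: negative for character {ch!r} in "
                        f"population {pop.id!r}"
                    )


def default_morph_config(seed: int = 0) -> MorphSimConfig:
    """Eight-population default emulating the field sampling design.

    Ten nests of 30 workers per population; residual SDs ordered
    HTL < FTSL < HTSL, mirroring the strong-to-weak stabilizing-selection
    ranking the analysis is meant to detect. Slopes are scattered around
    unity, with the weakly selected hind-tibial spur the most dispersed.
    """
    rng = np.random.default_rng(seed + 77003)
    names = [
        "Kawayu", "Obihiro", "Furano", "Moshiri",
        "Ishikari", "Ohnuma", "Gotemba", "Norikura",
    ]
    lats = [43.6, 42.9, 43.3, 44.4, 43.2, 42.0, 35.3, 36.1]
    pops = []
    for name, lat in zip(names, lats):
        slopes = {
            "HTL": 1.00 + rng.normal(0.0, 0.01),
            "FTSL": 1.05 + rng.normal(0.0, 0.02),
            "HTSL": 1.00 + rng.normal(0.0, 0.10),
        }
        intercepts = {"HTL": 0.45, "FTSL": -1.10, "HTSL": -1.60}
        residual_sd = {"HTL": 0.008, "FTSL": 0.013, "HTSL": 0.028}
        pops.append(
            PopulationSpec(
                id=name,
                latitude=lat,
                slopes=slopes,
                intercepts=intercepts,
                residual_sd=residual_sd,
            )
        )
    return MorphSimConfig(populations=tuple(pops), seed=seed)


def gen_morphometry(config: MorphSimConfig) -> pd.DataFrame:
    """Simulate a per-individual morphometric table.

    Head width is drawn uniformly on ``hw_range`` (the collectors aim for
    all size classes, which a lognormal would not emulate); every other
    character follows ln(y) = a + b*ln(HW) + N(0, sd) with the population's
    true parameters.

    Returns a long-format table with columns
    ``population, nest, individual, character, length_mm``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, str, str, str, float]] = []
    for pop in config.populations:
        chars = sorted(pop.slopes)
        for nest_i in range(config.nests_per_population):
            nest = f"{pop.id}_n{nest_i + 1:02d}"
            hw = rng.uniform(*config.hw_range, size=config.workers_per_nest)
            noise = {
                ch: rng.normal(0.0, pop.residual_sd[ch], size=config.workers_per_nest)
                for ch in chars
            }
            for w in range(config.workers_per_nest):
                ind = f"{nest}_w{w + 1:03d}"
                rows.append((pop.id, nest, ind, "HW", float(hw[w])))
                for ch in chars:
                    ln_y = (
                        pop.intercepts[ch]
                        + pop.slopes[ch] * np.log(hw[w])
                        + noise[ch][w]
                    )
                    rows.append((pop.id, nest, ind, ch, float(np.exp(ln_y))))
    return pd.DataFrame(
        rows, columns=["population", "nest", "individual", "character", "length_mm"]
    )


# ---------------------------------------------------------------------------
# microsatellites


@dataclass(frozen=True)
class PopGenSimConfig:
    """Island-model microsatellite simulation.

    ``target_fst`` controls differentiation: population allele frequencies
    are Dirichlet draws centred on shared ancestral frequencies with
    concentration (1 - F)/F, whose expected Wright F_ST is exactly F.
    With ``family_structure`` each nest is one queen's full-sib family
    (single father), giving within-nest relatedness ~0.5.
    """

    n_populations: int = 8
    loci: tuple[tuple[str, int], ...] = (
        ("Fy3", 10), ("Fy4", 10), ("Fy7", 10), ("Fy13", 10),
    )
    target_fst: float = 0.2
    individuals_per_nest: int = 10
    nests_per_population: int = 10
    family_structure: bool = False
    population_ids: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.population_ids is not None and len(self.population_ids) != self.n_populations:
            raise ValueError("population_ids length must equal n_populations")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        for locus, k in self.loci:
            if k < 2:
                raise ValueError(f"locus {locus!r}: allele count must be >= 2")
        if self.individuals_per_nest < 1 or self.nests_per_population < 1:
            raise ValueError("counts must be >= 1")


def _population_frequencies(config: PopGenSimConfig, rng: np.random.Generator):
    """Per-population allele frequencies under the Dirichlet island model."""
    freqs: dict[str, np.ndarray] = {}
    for locus, k in config.loci:
        ancestral = rng.dirichlet(np.full(k, 1.5))
        if config.target_fst == 0.0:
            pop_freqs = np.tile(ancestral, (config.n_populations, 1))
        else:
            conc = (1.0 - config.target_fst) / config.target_fst
            pop_freqs = rng.dirichlet(ancestral * conc, size=config.n_populations)
        freqs[locus] = pop_freqs
    return freqs


def gen_microsatellites(config: PopGenSimConfig) -> pd.DataFrame:
    """Simulate a diploid codominant genotype table.

    Returns a long-format table with columns
    ``population, nest, individual, locus, allele_1, allele_2`` using
    positive-integer allele codes (1..k per locus; GenePop-ready).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = _population_frequencies(config, rng)
    rows = []
    for p in range(config.n_populations):
        pop = (
            config.population_ids[p]
            if config.population_ids is not None
            else f"pop{p + 1:02d}"
        )
        for nest_i in range(config.nests_per_population):
            nest = f"{pop}_n{nest_i + 1:02d}"
            n = config.individuals_per_nest
            geno: dict[str, np.ndarray] = {}
            for locus, k in config.loci:
                pf = freqs[locus][p]
                if config.family_structure:
                    queen = rng.choice(k, size=2, p=pf)
                    father = rng.choice(k, size=2, p=pf)
                    maternal = queen[rng.integers(0, 2, size=n)]
                    paternal = father[rng.integers(0, 2, size=n)]
                    geno[locus] = np.column_stack([maternal, paternal]) + 1
                else:
                    geno[locus] = rng.choice(k, size=(n, 2), p=pf) + 1
            for w in range(n):
                ind = f"{nest}_w{w + 1:03d}"
                for locus, _ in config.loci:
                    a1, a2 = geno[locus][w]
                    rows.append((pop, nest, ind, locus, int(a1), int(a2)))
    return pd.DataFrame(
        rows,
        columns=["population", "nest", "individual", "locus", "allele_1", "allele_2"],
    )


# ---------------------------------------------------------------------------
# OU trait evolution


@dataclass(frozen=True)
class OUSimConfig:
    """True parameters for OU simulation on a known tree.

    ``true_params`` maps character -> (alpha, beta, x0, sigma2):
    selection strength per unit branch length, adaptive optimum, root
    state, and diffusion coefficient (variance accrued per unit branch
    length in the Brownian limit).
    """

    tree: dendropy.Tree
    true_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def validate(self) -> None:
        for ch, (alpha, _beta, _x0, sigma2) in self.true_params.items():
            if alpha < 0:
                raise ValueError(f"{ch}: alpha must be >= 0")
            if sigma2 <= 0:
                raise ValueError(f"{ch}: sigma2 must be > 0")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None or edge.length <= 0:
                raise ValueError("all branch lengths must be positive")


def ou_transition(
    parent: np.ndarray | float,
    t: float | np.ndarray,
    alpha: np.ndarray | float,
    beta: np.ndarray | float,
    sigma2: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the exact OU transition over one branch of length ``t``.

    child ~ Normal(beta + (parent - beta) e^{-alpha t},
                   sigma2 (1 - e^{-2 alpha t}) / (2 alpha)),
    degenerating to Brownian motion Normal(parent, sigma2 t) as alpha -> 0.
    The exact law (never an Euler scheme) keeps step size out of
    parameter-recovery comparisons.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("branch length must be nonnegative")
    alpha = np.asarray(alpha, dtype=float)
    decay = np.exp(-alpha * t)
    mean = beta + (np.asarray(parent, dtype=float) - beta) * decay
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            alpha > 1e-12,
            sigma2 * (1.0 - decay**2) / (2.0 * alpha),
            sigma2 * t,
        )
    return rng.normal(mean, np.sqrt(var))


def gen_ou_traits(config: OUSimConfig) -> dict[str, dict]:
    """Simulate trait evolution over the whole tree for each character.

    Returns ``{character: {node_key: value}}`` where ``node_key`` is the
    tip label for leaves and the node's preorder index string for internal
    nodes (see :func:`stasiscope.ou_model.node_key`).
    """
    from .ou_model import node_key  # local import to avoid cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    out: dict[str, dict] = {}
    for ch, (alpha, beta, x0, sigma2) in config.true_params.items():
        states: dict = {}
        node_state: dict[int, float] = {}
        for i, node in enumerate(config.tree.preorder_node_iter()):
            if node.parent_node is None:
                value = x0
            else:
                value = float(
                    ou_transition(
                        node_state[id(node.parent_node)],
                        node.edge.length,
                        alpha,
                        beta,
                        sigma2,
                        rng,
                    )
                )
            node_state[id(node)] = value
            states[node_key(node, i)] = value
        out[ch] = states
    return out


def random_tree(
    n_tips: int,
    seed: int = 0,
    branch_range: tuple[float, float] = (0.05, 1.0),
    labels: list[str] | None = None,
    unit_height: bool = False,
) -> dendropy.Tree:
    """Random rooted bifurcating tree with uniform branch lengths.

    Topology by sequential random joins; branch lengths i.i.d. uniform on
    ``branch_range``. With ``unit_height`` the tree is rescaled so the
    deepest tip sits at depth 1.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    labels = labels or [f"t{i + 1}" for i in range(n_tips)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        node.edge.length = float(rng.uniform(*branch_range))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(*branch_range))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    if unit_height:
        from .ou_model import tree_height

        h = tree_height(tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / h
    return tree


# ---------------------------------------------------------------------------
# distance matrices for Mantel calibration


def gen_distance_matrices(
    n: int,
    seed: int = 0,
    *,
    geo_weight: float = 0.0,
    species_weight: float = 0.0,
    noise_sd: float = 1.0,
):
    """Generate (geographic km, 0/1 species-indicator, genetic) matrices.

    The genetic matrix is ``geo_weight * scaled_geo + species_weight *
    species + half-normal noise``, so both partial associations are
    configurable; with both weights zero, the genetic matrix is pure noise
    and a partial Mantel test should hold its nominal size.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1000.0, size=(n, 2))
    diff = coords[:, None, :] - coords[None, :, :]
    geo = np.sqrt((diff**2).sum(axis=2))
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():  # two species by design: force both
        labels[rng.integers(0, n)] ^= 1
    species = (labels[:, None] != labels[None, :]).astype(float)
    noise = np.abs(rng.normal(0.0, noise_sd, size=(n, n)))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    genetic = geo_weight * geo / geo.max() + species_weight * species + noise
    np.fill_diagonal(genetic, 0.0)
    pops = [f"pop{i + 1:02d}" for i in range(n)]
    return (
        pd.DataFrame(geo, index=pops, columns=pops),
        pd.DataFrame(species, index=pops, columns=pops),
        pd.DataFrame(genetic, index=pops, columns=pops),
    )
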