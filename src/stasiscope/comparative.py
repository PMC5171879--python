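"""Phylogenetically informed correlation: independent contrasts and the
Kendall partial Mantel test.

Independent contrasts remove shared-ancestry pseudo-replication from
trait correlations (Felsenstein's pruning algorithm); the partial Mantel
test asks whether two distance matrices are associated once a third is
controlled for, with significance from label permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "ContrastSet",
    "independent_contrasts",
    "contrast_correlation",
    "partial_mantel_kendall",
]


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts, one per internal node of a bifurcating tree."""

    contrasts: np.ndarray
    variances: np.ndarray  # v_i + v_j of each contrast (before standardizing)
    node_keys: list[str]


def independent_contrasts(
    tree: dendropy.Tree, tip_values: dict[str, float]
) -> ContrastSet:
    """Felsenstein's independent contrasts on a rooted bifurcating tree.

    At each internal node with children (i, j) carrying working values
    (x_i, x_j) and corrected branch lengths (v_i, v_j):

        contrast = (x_i - x_j) / sqrt(v_i + v_j)
        x_node = (x_i / v_i + x_j / v_j) / (1/v_i + 1/v_j)
        v_node = branch_length(node) + v_i * v_j / (v_i + v_j)

    Children are taken in a fixed order (smallest descendant tip label
    first) so contrast signs are deterministic. Polytomies are rejected.
    """
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts, variances, keys = [], [], []
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    min_tip: dict[int, str] = {}
    for node in tree.postorder_node_iter():
        blen = node.edge.length if node.parent_node is not None else 0.0
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_values:
                raise ValueError(f"missing tip value for {label!r}")
            values[id(node)] = float(tip_values[label])
            lengths[id(node)] = float(blen)
            min_tip[id(node)] = label
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"node with {len(children)} children: tree must be bifurcating"
            )
        ci, cj = sorted(children, key=lambda c: min_tip[id(c)])
        xi, xj = values[id(ci)], values[id(cj)]
        vi, vj = lengths[id(ci)], lengths[id(cj)]
        if vi <= 0 or vj <= 0:
            raise ValueError("branch lengths must be positive for contrasts")
        contrasts.append((xi - xj) / math.sqrt(vi + vj))
        variances.append(vi + vj)
        keys.append(f"node{index[id(node)]}")
        values[id(node)] = (xi / vi + xj / vj) / (1.0 / vi + 1.0 / vj)
        lengths[id(node)] = float(blen) + vi * vj / (vi + vj)
        min_tip[id(node)] = min_tip[id(ci)]
    return ContrastSet(
        contrasts=np.array(contrasts[::-1]),
        variances=np.array(variances[::-1]),
        node_keys=keys[::-1],
    )


def contrast_correlation(
    contrasts_a: np.ndarray, contrasts_b: np.ndarray
) -> tuple[float, float, float]:
    """Correlation of two contrast sets through the origin, with Fisher z.

    r = sum(a*b) / sqrt(sum(a^2) * sum(b^2)); contrasts have arbitrary
    sign, and flipping any pair (a_k, b_k) jointly leaves r unchanged.
    Significance: z = atanh(r) * sqrt(n - 2) against a standard normal
    (n = number of contrasts; one df is absorbed by the through-origin
    constraint). Returns (r, z, two-sided p); NaN if fewer than 2
    contrasts or zero norms.
    """
    a = np.asarray(contrasts_a, dtype=float)
    b = np.asarray(contrasts_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("contrast sets differ in length")
    if len(a) < 2:
        return float("nan"), float("nan"), float("nan")
    denom = math.sqrt(float(np.sum(a**2) * np.sum(b**2)))
    if denom == 0:
        return float("nan"), float("nan"), float("nan")
    r = float(np.sum(a * b) / denom)
    n = len(a)
    if abs(r) >= 1.0:
        return r, math.copysign(float("inf"), r), 0.0
    z = float(np.arctanh(r) * math.sqrt(n - 2))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, z, p


def _offdiag_pairs(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _check_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix {name} is not square")
    if not np.allclose(m, m.T):
        raise ValueError(f"matrix {name} is not symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError(f"matrix {name} has a nonzero diagonal")
    return m


def partial_mantel_kendall(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Partial Mantel test with Kendall's tau-b.

    Computes tau on the upper off-diagonal pairs of each matrix pair and
    the first-order partial

        tau_ab.c = (tau_ab - tau_ac * tau_bc)
                   / sqrt((1 - tau_ac^2)(1 - tau_bc^2)),

    with significance from permuting the labels (rows + columns jointly)
    of matrix ``a`` — tau-b's tie correction matters because a 0/1 species
    matrix is tie-heavy. Two-sided p with the add-one convention; with
    ``method='exact'`` all n! label permutations are enumerated and p is
    the exact proportion with |tau*| >= |tau| (identity included).
    """
    a = _check_matrix(a, "a")
    b = _check_matrix(b, "b")
    c = _check_matrix(c, "c")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need >= 4 labels")
    va, vb, vc = _offdiag_pairs(a), _offdiag_pairs(b), _offdiag_pairs(c)
    for name, v in (("a", va), ("b", vb), ("c", vc)):
        if np.all(v == v[0]):
            raise ValueError(f"matrix {name} is constant; tau undefined")

    # tau-b machinery. A label permutation of matrix `a` only permutes its
    # off-diagonal pair vector, so the sign matrix of va and every tie
    # count — hence every tau-b denominator — is permutation-invariant;
    # each permutation costs one pair-index gather and two sums.
    m = len(va)
    n0 = m * (m - 1) / 2.0

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float((counts * (counts - 1)).sum()) / 2.0

    def sign_matrix(v):
        return np.sign(v[:, None] - v[None, :])

    sa, sb, sc = sign_matrix(va), sign_matrix(vb), sign_matrix(vc)
    den_a = n0 - tie_term(va)
    den_b = n0 - tie_term(vb)
    den_c = n0 - tie_term(vc)
    scale_ab = 1.0 / math.sqrt(den_a * den_b)
    scale_ac = 1.0 / math.sqrt(den_a * den_c)
    t_bc = float((sb * sc).sum()) / 2.0 / math.sqrt(den_b * den_c)

    # pair-index lookup: label permutation -> permutation of pair indices
    pair_id = np.zeros((n, n), dtype=int)
    for pid, (i, j) in enumerate(zip(*np.triu_indices(n, k=1))):
        pair_id[i, j] = pair_id[j, i] = pid

    iu = np.triu_indices(n, k=1)

    def partial_tau_of(sa_perm: np.ndarray) -> float:
        t_ab = float((sa_perm * sb).sum()) / 2.0 * scale_ab
        t_ac = float((sa_perm * sc).sum()) / 2.0 * scale_ac
        den = math.sqrt((1 - t_ac**2) * (1 - t_bc**2))
        if den == 0:
            return float("nan")
        return (t_ab - t_ac * t_bc) / den

    obs = partial_tau_of(sa)

    def permuted_sa(idx: np.ndarray) -> np.ndarray:
        pp = pair_id[idx[iu[0]], idx[iu[1]]]
        return sa[np.ix_(pp, pp)]

    if method == "exact":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            if abs(partial_tau_of(permuted_sa(idx))) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        return float(obs), count / total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if abs(partial_tau_of(permuted_sa(idx))) >= abs(obs):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(obs), float(p)
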