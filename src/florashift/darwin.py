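"""Permutation tests of Darwin's naturalization hypothesis.

The observed statistic for a region is the mean patristic distance from
each non-native species to its nearest phylogenetic neighbor in the
recipient (native) flora. The null shuffles non-native status over the
tips of the regional species pool (natives ∪ non-natives by default; the
whole tree in the global sensitivity mode): the label set keeps its size,
and the species not selected act as the recipient flora. Significance uses
the add-one rule p = (r+1)/(n+1); the main test is two-sided (doubled
smaller tail), the superinvader relatedness test one-sided (smaller
observed mean = more closely related than chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .tree import Phylogeny


@dataclass(frozen=True)
class DarwinResult:
    observed_mean_nnd: float  # myr
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    n_permutations: int
    n_nonnatives: int
    region_id: str | None = None


def nearest_neighbor_distance(species: str, native_set, tree: Phylogeny) -> float:
    """Patristic distance (myr) from ``species`` to its nearest neighbor
    in ``native_set`` (which must be non-empty and exclude the species)."""
    natives = [s for s in native_set if s != species]
    if not natives:
        raise ValueError("native set is empty")
    D = tree.patristic_matrix()
    idx = tree.tip_index
    i = idx[species]
    return float(min(D[i, idx[s]] for s in natives))


def _mean_nnd(D: np.ndarray, focal_idx: np.ndarray, pool_idx: np.ndarray) -> float:
    """Mean over focal tips of min distance to pool tips (row-wise)."""
    sub = D[np.ix_(focal_idx, pool_idx)]
    return float(sub.min(axis=1).mean())


def darwin_permutation_test(
    region_natives,
    region_nonnatives,
    tree: Phylogeny,
    n_perm: int = 1000,
    seed: int = 0,
    pool: str = "regional",
    region_id: str | None = None,
) -> DarwinResult:
    """Two-sided tip-shuffle test of non-native phylogenetic distinctness.

    ``pool='regional'`` permutes the non-native label set within the
    region's natives ∪ non-natives; ``'global'`` permutes it over all tree
    tips (remaining tips acting as recipient flora).
    """
    natives = sorted(set(region_natives))
    nonnat = sorted(set(region_nonnatives))
    if not natives or not nonnat:
        raise ValueError("need at least one native and one non-native")
    if set(natives) & set(nonnat):
        raise ValueError("native and non-native sets overlap")
    if pool == "regional":
        pool_species = natives + nonnat
    elif pool == "global":
        pool_species = sorted(tree.tip_set)
    else:
        raise ValueError("pool must be 'regional' or 'global'")
    k = len(nonnat)
    m = len(pool_species)
    if comb(m, k) <= 1:
        raise ValueError(f"pool of {m} with {k} labels admits a single assignment")

    D = tree.patristic_matrix()
    idx = tree.tip_index
    pool_idx = np.array([idx[s] for s in pool_species])
    nat_idx = np.array([idx[s] for s in natives])
    non_idx = np.array([idx[s] for s in nonnat])
    observed = _mean_nnd(D, non_idx, nat_idx)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(m)
        sel = pool_idx[perm[:k]]
        rest = pool_idx[perm[k:]]
        null[r] = _mean_nnd(D, sel, rest)
    p_lo = (np.sum(null <= observed) + 1) / (n_perm + 1)
    p_hi = (np.sum(null >= observed) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    sd = float(null.std(ddof=1))
    z = float((observed - null.mean()) / sd) if sd > 0 else float("nan")
    return DarwinResult(
        observed, float(null.mean()), sd, z, float(p), n_perm, k, region_id
    )


def superinvader_relatedness_test(
    nonnatives,
    superinvaders,
    tree: Phylogeny,
    n_perm: int = 1000,
    seed: int = 0,
) -> DarwinResult:
    """One-sided test: are superinvaders more closely related to the other
    non-natives than random non-native subsets of the same size?

    Statistic: mean over superinvaders of the patristic distance to the
    nearest *other* non-native. Small observed values (relative to the
    shuffle null over non-natives) give small p.
    """
    nonnat = sorted(set(nonnatives))
    supers = sorted(set(superinvaders))
    if len(nonnat) < 2:
        raise ValueError("need at least two non-natives")
    if not set(supers) <= set(nonnat):
        raise ValueError("superinvaders must be a subset of non-natives")
    if not supers:
        raise ValueError("need at least one superinvader")
    if len(supers) == len(nonnat):
        raise ValueError("all non-natives are superinvaders; null is degenerate")

    D = tree.patristic_matrix().copy()
    np.fill_diagonal(D, np.inf)  # exclude self when taking nearest *other*
    idx = tree.tip_index
    non_idx = np.array([idx[s] for s in nonnat])
    sup_idx = np.array([idx[s] for s in supers])
    observed = _mean_nnd(D, sup_idx, non_idx)

    rng = np.random.default_rng(seed)
    k = len(supers)
    null = np.empty(n_perm)
    for r in range(n_perm):
        sel = non_idx[rng.permutation(len(non_idx))[:k]]
        null[r] = _mean_nnd(D, sel, non_idx)
    p = (np.sum(null <= observed) + 1) / (n_perm + 1)
    sd = float(null.std(ddof=1))
    z = float((observed - null.mean()) / sd) if sd > 0 else float("nan")
    return DarwinResult(
        observed, float(null.mean()), sd, z, float(p), n_perm, k, None
    )


def darwin_multitree(
    region_natives,
    region_nonnatives,
    trees: list[Phylogeny],
    n_perm: int = 1000,
    seed: int = 0,
    pool: str = "regional",
    region_id: str | None = None,
) -> DarwinResult:
    """Median DarwinResult across a list of trees (same species universe)."""
    if not trees:
        raise ValueError("need at least one tree")
    results = [
        darwin_permutation_test(
            region_natives, region_nonnatives, t, n_perm, seed + i, pool, region_id
        )
        for i, t in enumerate(trees)
    ]
    med = lambda attr: float(np.median([getattr(r, attr) for r in results]))
    return DarwinResult(
        med("observed_mean_nnd"),
        med("null_mean"),
        med("null_sd"),
        med("z"),
        med("p_value"),
        results[0].n_permutations,
        results[0].n_nonnatives,
        region_id,
    )
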