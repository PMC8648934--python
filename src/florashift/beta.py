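"""Pairwise compositional turnover (β-diversity) and its temporal change.

Species-level decomposition of a cell pair: a = shared species, b/c =
species unique to each cell. The phylogenetic analog replaces species by
branches: each cell spans the union of root-to-tip paths of its species,
and a/b/c are summed branch lengths (myr) shared/unique.

Indices on a decomposition:

* Simpson turnover  βsim = min(b,c) / (a + min(b,c)) — insensitive to
  richness differences; the headline index.
* Sorensen          (b+c) / (2a+b+c)
* Jaccard           (b+c) / (a+b+c)

Each cell's summary value is its unweighted mean dissimilarity to the
other cells of its level-3 region; the richness-standardized phylogenetic
version (SES) uses the same tip-shuffle null engine as the α metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alpha import cell_branch_presence, _species_tip_rows
from .community import CommunityMatrix, SpatialHierarchy, change_rows
from .tree import Phylogeny

INDICES = ("simpson", "sorensen", "jaccard")


@dataclass(frozen=True)
class BetaDecomposition:
    a: float
    b: float
    c: float


def abc_species(cell_x, cell_y) -> BetaDecomposition:
    """Shared/unique species counts of two cells' species sets."""
    x, y = set(cell_x), set(cell_y)
    return BetaDecomposition(len(x & y), len(x - y), len(y - x))


def abc_phylo(cell_x, cell_y, tree: Phylogeny) -> BetaDecomposition:
    """Shared/unique summed branch lengths of two cells' branch sets."""
    idx = tree.tip_index

    def branches(species) -> set[int]:
        out: set[int] = set()
        for s in species:
            out.update(tree.ancestors(int(tree.tip_nodes[idx[s]])))
        return out

    bx, by = branches(cell_x), branches(cell_y)
    lsum = lambda nodes: float(sum(tree.length[n] for n in nodes))
    return BetaDecomposition(lsum(bx & by), lsum(bx - by), lsum(by - bx))


def beta_index(d: BetaDecomposition, index: str) -> float:
    """Dissimilarity in [0, 1]; NaN when both cells are empty."""
    a, b, c = float(d.a), float(d.b), float(d.c)
    if a + b + c == 0:
        return float("nan")
    if index == "simpson":
        m = min(b, c)
        return m / (a + m) if (a + m) > 0 else 1.0  # one-empty convention
    if index == "sorensen":
        return (b + c) / (2 * a + b + c)
    if index == "jaccard":
        return (b + c) / (a + b + c)
    raise ValueError(f"unknown index {index!r}; expected one of {INDICES}")


def _pairwise_matrix(depth: np.ndarray, shared: np.ndarray, index: str) -> np.ndarray:
    """Vectorized index over all cell pairs from per-cell totals and the
    shared-component matrix (counts for taxonomic, lengths for phylogenetic)."""
    a = shared
    b = depth[:, None] - a
    c = depth[None, :] - a
    m = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        if index == "simpson":
            out = m / (a + m)
        elif index == "sorensen":
            out = (b + c) / (2 * a + b + c)
        elif index == "jaccard":
            out = (b + c) / (a + b + c)
        else:
            raise ValueError(f"unknown index {index!r}")
    both_empty = (depth[:, None] == 0) & (depth[None, :] == 0)
    if index == "simpson":
        one_empty = ((depth[:, None] == 0) | (depth[None, :] == 0)) & ~both_empty
        out = np.where(one_empty & ~np.isfinite(out), 1.0, out)
    out = np.where(both_empty, np.nan, out)
    return out


def _region_groups(cells: list[str], hierarchy: SpatialHierarchy, scope: str):
    if scope == "all":
        return {"<all>": list(range(len(cells)))}
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(cells):
        groups.setdefault(hierarchy.region_of(c), []).append(i)
    return groups


def _level_inputs(
    matrix: CommunityMatrix, level: str, tree: Phylogeny | None
) -> tuple[np.ndarray, "np.ndarray"]:
    """(per-cell total, cells × items weighted presence) for one level."""
    if level == "taxonomic":
        X = matrix.incidence.astype(np.float64).toarray()
        weights = np.ones(X.shape[1])
    elif level == "phylogenetic":
        if tree is None:
            raise ValueError("phylogenetic level requires a tree")
        X = cell_branch_presence(matrix, tree).astype(np.float64).toarray()
        weights = tree.length
    else:
        raise ValueError(f"unknown level {level!r}")
    depth = X @ weights
    return depth, X * weights


def pairwise_dissimilarity(
    matrix: CommunityMatrix,
    hierarchy: SpatialHierarchy,
    index: str = "simpson",
    level: str = "taxonomic",
    tree: Phylogeny | None = None,
    scope: str = "region",
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per region: (cell ids, pairwise dissimilarity matrix)."""
    depth, W = _level_inputs(matrix, level, tree)
    X = (W > 0).astype(float)
    out = {}
    for region, rows in _region_groups(matrix.cells, hierarchy, scope).items():
        ridx = np.array(rows)
        shared = W[ridx] @ X[ridx].T
        out[region] = (
            [matrix.cells[i] for i in rows],
            _pairwise_matrix(depth[ridx], shared, index),
        )
    return out


def region_mean_dissimilarity(
    matrix: CommunityMatrix,
    hierarchy: SpatialHierarchy,
    index: str = "simpson",
    level: str = "taxonomic",
    tree: Phylogeny | None = None,
    scope: str = "region",
    empty_pair: str = "one",
) -> pd.Series:
    """Per cell, unweighted mean dissimilarity to the other cells of its
    level-3 region. Single-cell regions get NaN. ``empty_pair='missing'``
    drops pairs with one empty member instead of scoring them 1."""
    depth, W = _level_inputs(matrix, level, tree)
    X = (W > 0).astype(float)
    values = pd.Series(
        np.nan,
        index=pd.Index(matrix.cells, name="cell_id"),
        name=f"beta_{level}_{index}",
    )
    for region, rows in _region_groups(matrix.cells, hierarchy, scope).items():
        if len(rows) < 2:
            warnings.warn(f"region {region!r} has a single cell; β undefined")
            continue
        ridx = np.array(rows)
        D = _pairwise_matrix(depth[ridx], W[ridx] @ X[ridx].T, index)
        if empty_pair == "missing":
            one_empty = (depth[ridx][:, None] == 0) ^ (depth[ridx][None, :] == 0)
            D = np.where(one_empty, np.nan, D)
        np.fill_diagonal(D, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values.iloc[ridx] = np.nanmean(D, axis=1)
    return values


def ses_phylo_beta(
    matrix: CommunityMatrix,
    tree: Phylogeny,
    hierarchy: SpatialHierarchy,
    n_rand: int = 1000,
    seed: int = 0,
    index: str = "simpson",
    scope: str = "region",
) -> pd.DataFrame:
    """Tip-shuffle z-score of each cell's region-mean phylogenetic
    dissimilarity; missing where the null is degenerate (SD = 0)."""
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    rng = np.random.default_rng(seed)
    observed = region_mean_dissimilarity(
        matrix, hierarchy, index, "phylogenetic", tree, scope
    )
    tip_rows = _species_tip_rows(matrix, tree)
    inc = matrix.incidence.astype(np.int8)
    tbm = tree.tip_branch_matrix
    lengths = tree.length
    groups = _region_groups(matrix.cells, hierarchy, scope)
    null = np.empty((n_rand, len(matrix.cells)))
    for r in range(n_rand):
        perm = rng.permutation(tree.n_tips)
        X = ((inc @ tbm[perm[tip_rows]]) > 0).toarray().astype(float)
        depth = X @ lengths
        W = X * lengths
        vals = np.full(len(matrix.cells), np.nan)
        for rows in groups.values():
            if len(rows) < 2:
                continue
            ridx = np.array(rows)
            D = _pairwise_matrix(depth[ridx], W[ridx] @ X[ridx].T, index)
            np.fill_diagonal(D, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals[ridx] = np.nanmean(D, axis=1)
        null[r] = vals
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed.to_numpy() - null_mean) / null_sd
    z = np.where(np.isclose(null_sd, 0.0), np.nan, z)
    return pd.DataFrame(
        {
            "beta_phylo": observed.to_numpy(),
            "ses_phylo_beta": z,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "n_randomizations": n_rand,
        },
        index=pd.Index(matrix.cells, name="cell_id"),
    )


def delta_beta(
    holo: pd.Series,
    anthro: pd.Series,
    metric: str,
    scenario: str,
    hierarchy: SpatialHierarchy,
) -> pd.DataFrame:
    """Δβ = (β_anthro − β_holo)/β_holo per cell; negative values mean
    homogenization. Missing when β_holo = 0."""
    return change_rows(holo, anthro, metric, scenario, hierarchy)
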