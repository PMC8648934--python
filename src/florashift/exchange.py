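"""Continental donor→recipient exchange of non-native species and
phylogenetic diversity.

A species with origin continent d and naturalized cells in continents
r1, r2 contributes one unit of species flow to (d, r1) and (d, r2).
PD flow of a (d, r) pair is the rooted Faith PD of the full species set
flowing along it (branch-set union, so shared stems are not double-counted
within a flow). Net PD per species exchanged attributes the PD gained by a
recipient continent's Holocene flora to each donor and divides by the
species flow; because simultaneous donors can contribute overlapping
branches, attribution is computed either sequentially in a fixed donor
order or as an exact Shapley average over donor orders.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .community import CommunityMatrix, SpatialHierarchy, SpeciesStatusTable
from .tree import Phylogeny


def _flow_sets(
    status: SpeciesStatusTable, hierarchy: SpatialHierarchy
) -> dict[tuple[str, str], set[str]]:
    """(donor, recipient) → species set, recipients from naturalized cells."""
    flows: dict[tuple[str, str], set[str]] = {}
    for sp, cells in status.naturalized_cells.items():
        d = status.origin_of(sp)
        for r in {hierarchy.continent_of(c) for c in cells}:
            if r != d:
                flows.setdefault((d, r), set()).add(sp)
    return flows


def _empty_matrix(hierarchy: SpatialHierarchy, dtype=float) -> pd.DataFrame:
    conts = hierarchy.continents
    return pd.DataFrame(
        np.zeros((len(conts), len(conts)), dtype=dtype),
        index=pd.Index(conts, name="donor"),
        columns=pd.Index(conts, name="recipient"),
    )


def species_flow_matrix(
    status: SpeciesStatusTable, hierarchy: SpatialHierarchy
) -> pd.DataFrame:
    """Counts of species exchanged donor→recipient (diagonal zero)."""
    M = _empty_matrix(hierarchy, dtype=int)
    for (d, r), spp in _flow_sets(status, hierarchy).items():
        M.loc[d, r] = len(spp)
    return M


def pd_of_species(tree: Phylogeny, species) -> float:
    """Rooted Faith PD (myr) of a species set (union of root paths)."""
    species = list(species)
    if not species:
        return 0.0
    idx = tree.tip_index
    rows = [idx[s] for s in species]
    covered = np.asarray(
        tree.tip_branch_matrix[rows].max(axis=0).todense()
    ).ravel() > 0
    return float(tree.length[covered].sum())


def pd_flow_matrix(
    status: SpeciesStatusTable, hierarchy: SpatialHierarchy, tree: Phylogeny
) -> pd.DataFrame:
    """Summed branch lengths (myr) exchanged donor→recipient."""
    M = _empty_matrix(hierarchy)
    for (d, r), spp in _flow_sets(status, hierarchy).items():
        M.loc[d, r] = pd_of_species(tree, spp)
    return M


def _branch_cover(tree: Phylogeny, species) -> np.ndarray:
    idx = tree.tip_index
    rows = [idx[s] for s in species]
    if not rows:
        return np.zeros(tree.n_nodes, dtype=bool)
    return np.asarray(tree.tip_branch_matrix[rows].max(axis=0).todense()).ravel() > 0


def net_pd_per_species(
    holo: CommunityMatrix,
    status: SpeciesStatusTable,
    hierarchy: SpatialHierarchy,
    tree: Phylogeny,
    mode: str = "sequential",
) -> pd.DataFrame:
    """Per donor→recipient: PD added to the recipient continent's Holocene
    flora by the donor's flow, divided by the number of species exchanged.

    ``mode='sequential'`` processes donors in the hierarchy's continent
    order (marginal gains on top of earlier donors); ``'shapley'`` averages
    the marginal gain over all donor orders exactly. Entries with zero
    species flow are missing (NaN).
    """
    if mode not in ("sequential", "shapley"):
        raise ValueError("mode must be 'sequential' or 'shapley'")
    flows = _flow_sets(status, hierarchy)
    counts = species_flow_matrix(status, hierarchy)
    out = _empty_matrix(hierarchy)
    out.iloc[:, :] = np.nan
    lengths = tree.length
    for r in hierarchy.continents:
        donors = [d for d in hierarchy.continents if (d, r) in flows]
        if not donors:
            continue
        holo_species = set()
        for c in hierarchy.cells_in_continent(r):
            if c in holo._cell_index:
                holo_species |= holo.species_in_cell(c)
        base = _branch_cover(tree, holo_species & tree.tip_set)
        covers = {d: _branch_cover(tree, flows[(d, r)]) for d in donors}
        gains: dict[str, float] = {}
        if mode == "sequential":
            current = base.copy()
            for d in donors:
                new = current | covers[d]
                gains[d] = float(lengths[new & ~current].sum())
                current = new
        else:
            n = len(donors)
            subset_pd = {}
            for k in range(n + 1):
                for T in combinations(donors, k):
                    cov = base.copy()
                    for d in T:
                        cov |= covers[d]
                    subset_pd[frozenset(T)] = float(lengths[cov & ~base].sum())
            for d in donors:
                phi = 0.0
                rest = [x for x in donors if x != d]
                for k in range(len(rest) + 1):
                    w = factorial(k) * factorial(n - k - 1) / factorial(n)
                    for T in combinations(rest, k):
                        T = frozenset(T)
                        phi += w * (subset_pd[T | {d}] - subset_pd[T])
                gains[d] = phi
        for d in donors:
            out.loc[d, r] = gains[d] / counts.loc[d, r]
    return out


def multitree_median(op, trees: list[Phylogeny]) -> pd.DataFrame:
    """Elementwise median of a PD-dependent operation across trees.

    Trees must share an identical tip set; with an even tree count the
    median is the mean of the middle pair.
    """
    if not trees:
        raise ValueError("need at least one tree")
    tips = trees[0].tip_set
    for t in trees[1:]:
        if t.tip_set != tips:
            raise ValueError("trees have different tip sets")
    results = [op(t) for t in trees]
    first = results[0]
    stack = np.stack([np.asarray(r, dtype=float) for r in results])
    med = np.nanmedian(stack, axis=0)
    if isinstance(first, pd.DataFrame):
        return pd.DataFrame(med, index=first.index, columns=first.columns)
    if isinstance(first, pd.Series):
        return pd.Series(med, index=first.index, name=first.name)
    return med


def family_receipts(
    status: SpeciesStatusTable, hierarchy: SpatialHierarchy, continent: str
) -> pd.Series:
    """Counts of naturalized species received by a continent, per family."""
    counts: dict[str, int] = {}
    for sp, cells in status.naturalized_cells.items():
        if status.origin_of(sp) == continent:
            continue
        if any(hierarchy.continent_of(c) == continent for c in cells):
            fam = status.family_of(sp)
            counts[fam] = counts.get(fam, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def family_flow_correlation(
    status: SpeciesStatusTable,
    hierarchy: SpatialHierarchy,
    continent_a: str,
    continent_b: str,
) -> float:
    """Spearman rank correlation (average ranks for ties) between two
    continents' per-family counts of received naturalized species. Missing
    (NaN) when fewer than 3 families have a nonzero total."""
    ra = family_receipts(status, hierarchy, continent_a)
    rb = family_receipts(status, hierarchy, continent_b)
    families = sorted(set(ra.index) | set(rb.index))
    if len(families) < 3:
        return float("nan")
    va = ra.reindex(families, fill_value=0).to_numpy()
    vb = rb.reindex(families, fill_value=0).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input → NaN, by design
        rho = spearmanr(va, vb).statistic
    return float(rho)


def flows_long_format(
    species_flow: pd.DataFrame,
    pd_flow: pd.DataFrame | None = None,
    net_pd: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format (donor, recipient, species_flow[, pd_flow, net_pd_per_species])."""
    rows = []
    for d in species_flow.index:
        for r in species_flow.columns:
            if d == r:
                continue
            row = {"donor": d, "recipient": r, "species_flow": species_flow.loc[d, r]}
            if pd_flow is not None:
                row["pd_flow"] = pd_flow.loc[d, r]
            if net_pd is not None:
                row["net_pd_per_species"] = net_pd.loc[d, r]
            rows.append(row)
    return pd.DataFrame(rows)
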