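"""Per-cell α-diversity: richness, Faith's PD, tip-shuffle SES, and Δα.

Faith's PD is rooted: the branch set of a cell is the union of the
root-to-tip paths of its species, so the path to the root is always
included. The richness-standardized effect size (SES) permutes tip labels
over the whole phylogeny (tree shape and assemblages fixed) and reports
z = (observed − null mean) / null SD with the sample (n−1) SD; cells whose
PD is shuffle-invariant (null SD = 0) get a missing SES, not 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .community import CommunityMatrix, DataValidationError, SpatialHierarchy, change_rows
from .tree import Phylogeny


def richness(matrix: CommunityMatrix) -> pd.Series:
    """Species count per cell."""
    return matrix.richness()


def _species_tip_rows(matrix: CommunityMatrix, tree: Phylogeny) -> np.ndarray:
    idx = tree.tip_index
    try:
        return np.array([idx[s] for s in matrix.species], dtype=np.int64)
    except KeyError as exc:
        raise DataValidationError(f"species {exc} not a tip of the tree") from exc


def cell_branch_presence(
    matrix: CommunityMatrix, tree: Phylogeny, tip_rows: np.ndarray | None = None
) -> sp.csr_matrix:
    """Sparse (cells × tree nodes) indicator of branches spanned per cell."""
    rows = tip_rows if tip_rows is not None else _species_tip_rows(matrix, tree)
    paths = tree.tip_branch_matrix[rows]  # species × nodes
    return (matrix.incidence.astype(np.int8) @ paths) > 0


def faith_pd(matrix: CommunityMatrix, tree: Phylogeny) -> pd.Series:
    """Rooted Faith PD (myr) per cell: summed lengths of the union of
    root-to-tip paths of the cell's species. Empty cells get 0."""
    presence = cell_branch_presence(matrix, tree)
    pd_values = np.asarray(presence @ tree.length).ravel()
    return pd.Series(
        pd_values, index=pd.Index(matrix.cells, name="cell_id"), name="pd"
    )


def ses_pd(
    matrix: CommunityMatrix,
    tree: Phylogeny,
    n_rand: int = 1000,
    seed: int = 0,
    shuffle_over: str = "tree",
) -> pd.DataFrame:
    """Tip-shuffle standardized effect size of PD per cell.

    ``shuffle_over='tree'`` permutes labels over all tips of the phylogeny
    (the default null); ``'observed'`` restricts the permutation to species
    present in the matrix.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    if shuffle_over not in ("tree", "observed"):
        raise ValueError("shuffle_over must be 'tree' or 'observed'")
    rng = np.random.default_rng(seed)
    tip_rows = _species_tip_rows(matrix, tree)
    observed = faith_pd(matrix, tree).to_numpy()
    inc = matrix.incidence.astype(np.int8)
    lengths = tree.length
    tbm = tree.tip_branch_matrix
    null = np.empty((n_rand, len(matrix.cells)))
    for r in range(n_rand):
        if shuffle_over == "tree":
            perm = rng.permutation(tree.n_tips)
            rows = perm[tip_rows]
        else:
            rows = tip_rows[rng.permutation(tip_rows.size)]
        presence = (inc @ tbm[rows]) > 0
        null[r] = np.asarray(presence @ lengths).ravel()
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    z = np.where(np.isclose(null_sd, 0.0), np.nan, z)
    return pd.DataFrame(
        {
            "richness": matrix.richness().to_numpy(),
            "pd": observed,
            "ses_pd": z,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "n_randomizations": n_rand,
        },
        index=pd.Index(matrix.cells, name="cell_id"),
    )


def delta_alpha(
    holo: pd.Series,
    anthro: pd.Series,
    metric: str,
    scenario: str,
    hierarchy: SpatialHierarchy,
) -> pd.DataFrame:
    """Δα = (α_anthro − α_holo)/α_holo per cell; missing when α_holo = 0."""
    return change_rows(holo, anthro, metric, scenario, hierarchy)
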