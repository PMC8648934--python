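"""Rooted dated phylogenies: parsing, validation, and branch-path machinery.

The tree is held as flat parent/length arrays in preorder. Every metric in
the package (Faith PD, phylogenetic turnover, patristic distances) reduces
to operations on each tip's *root path* — the set of branches connecting the
tip to the root — so the central cached object is a sparse tips × branches
indicator matrix. All downstream code is polytomy-safe because it only ever
works with branch sets, never with node degrees.

Branch lengths are in millions of years (myr) throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.sparse as sp


class NewickParseError(ValueError):
    """Malformed newick input."""


class TreeValidationError(ValueError):
    """Structurally valid newick that violates a phylogeny invariant."""


@dataclass
class Phylogeny:
    """Rooted tree with non-negative branch lengths and unique tip labels.

    Attributes
    ----------
    parent : (n_nodes,) int array; parent index in preorder, -1 for the root.
    length : (n_nodes,) float array; length of the branch above each node
        (0.0 for the root, which has no branch).
    tip_nodes : (n_tips,) int array; node indices that are tips, in preorder.
    tip_labels : list of str; labels aligned with ``tip_nodes``.
    """

    parent: np.ndarray
    length: np.ndarray
    tip_nodes: np.ndarray
    tip_labels: list[str]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=float)
        self.tip_nodes = np.asarray(self.tip_nodes, dtype=np.int64)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = self.parent.size
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots.size}")
        if roots[0] != 0:
            raise TreeValidationError("root must be the first node in preorder")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeValidationError("parents must precede children (preorder)")
        if np.any(self.length < 0):
            raise TreeValidationError("negative branch length")
        if not np.any(self.length > 0):
            raise TreeValidationError("tree has no positive branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes[:10]}")

    # -- basic properties ------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_set(self) -> frozenset[str]:
        if "tip_set" not in self._cache:
            self._cache["tip_set"] = frozenset(self.tip_labels)
        return self._cache["tip_set"]

    @property
    def tip_index(self) -> dict[str, int]:
        """label -> position in ``tip_nodes`` / rows of ``tip_branch_matrix``."""
        if "tip_index" not in self._cache:
            self._cache["tip_index"] = {t: i for i, t in enumerate(self.tip_labels)}
        return self._cache["tip_index"]

    @property
    def total_length(self) -> float:
        return float(self.length.sum())

    def ancestors(self, node: int) -> list[int]:
        """Nodes on the path from ``node`` (inclusive) up to the root (inclusive)."""
        path = []
        while node != -1:
            path.append(node)
            node = int(self.parent[node])
        return path

    @property
    def tip_branch_matrix(self) -> sp.csr_matrix:
        """Sparse (n_tips × n_nodes) indicator: node on the tip's root path.

        Column j carries branch length ``length[j]`` (the branch above node
        j); the root column has length 0 so including it is harmless.
        """
        if "tbm" not in self._cache:
            rows, cols = [], []
            for i, node in enumerate(self.tip_nodes):
                for a in self.ancestors(int(node)):
                    rows.append(i)
                    cols.append(a)
            data = np.ones(len(rows), dtype=np.int8)
            self._cache["tbm"] = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_tips, self.n_nodes)
            )
        return self._cache["tbm"]

    @property
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths (myr), aligned with ``tip_labels``."""
        if "depths" not in self._cache:
            self._cache["depths"] = np.asarray(
                self.tip_branch_matrix @ self.length
            ).ravel()
        return self._cache["depths"]

    def patristic_matrix(self) -> np.ndarray:
        """Dense (n_tips × n_tips) patristic distance matrix (myr).

        d(i, j) = depth_i + depth_j − 2 · (length shared on both root paths).
        """
        if "patristic" not in self._cache:
            M = self.tip_branch_matrix.astype(float)
            shared = (M.multiply(self.length) @ M.T).toarray()
            d = self.tip_depths
            D = d[:, None] + d[None, :] - 2.0 * shared
            np.fill_diagonal(D, 0.0)
            self._cache["patristic"] = np.maximum(D, 0.0)
        return self._cache["patristic"]

    def patristic_distance(self, a: str, b: str) -> float:
        ia, ib = self.tip_index[a], self.tip_index[b]
        return float(self.patristic_matrix()[ia, ib])

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.tip_depths
        return bool(d.max() - d.min() <= tol)

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for i in range(1, self.n_nodes):
            children.setdefault(int(self.parent[i]), []).append(i)
        node_label = {int(n): lab for n, lab in zip(self.tip_nodes, self.tip_labels)}

        out = io.StringIO()

        def write(node: int, with_length: bool) -> None:
            kids = children.get(node, [])
            if kids:
                out.write("(")
                for k, kid in enumerate(kids):
                    if k:
                        out.write(",")
                    write(kid, True)
                out.write(")")
            out.write(node_label.get(node, ""))
            if with_length:
                out.write(f":{self.length[node]:.10g}")

        write(0, False)
        out.write(";")
        return out.getvalue()

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=np.int64)
        length = np.zeros(len(nodes), dtype=float)
        tip_nodes, tip_labels = [], []
        for i, nd in enumerate(nodes):
            parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    label = nd.taxon.label if nd.taxon else "<internal>"
                    raise TreeValidationError(
                        f"missing branch length above node {label!r}"
                    )
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeValidationError("unlabeled tip")
                tip_nodes.append(i)
                tip_labels.append(nd.taxon.label)
        return cls(parent, length, np.array(tip_nodes), tip_labels)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted newick string into a :class:`Phylogeny`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def read_newick(path) -> Phylogeny:
    """Read one rooted newick tree (with branch lengths) from ``path``."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise NewickParseError(f"{path}: empty newick file")
    return parse_newick(text)


def read_newick_list(path) -> list[Phylogeny]:
    """Read a multi-tree newick file (one tree per ';'-terminated statement)."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise NewickParseError(f"malformed newick in {path}: {exc}") from exc
    if not trees:
        raise NewickParseError(f"{path}: no trees found")
    return [Phylogeny.from_dendropy(t) for t in trees]


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
        fh.write("\n")
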