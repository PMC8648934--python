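"""Naive reference implementations used as independent oracles.

Everything here works by explicit path-walking and set enumeration on the
tree's parent array — no sparse algebra, no caching — so agreement with
the optimized code is meaningful.
"""

from __future__ import annotations

from florashift.tree import Phylogeny


def root_path_nodes(tree: Phylogeny, species: str) -> set[int]:
    node = int(tree.tip_nodes[tree.tip_index[species]])
    path = set()
    while node != -1:
        path.add(node)
        node = int(tree.parent[node])
    return path


def pd_naive(tree: Phylogeny, species) -> float:
    """Faith PD by enumerating the union of root paths."""
    covered: set[int] = set()
    for s in species:
        covered |= root_path_nodes(tree, s)
    return float(sum(tree.length[n] for n in covered))


def patristic_naive(tree: Phylogeny, a: str, b: str) -> float:
    pa, pb = root_path_nodes(tree, a), root_path_nodes(tree, b)
    sym = (pa - pb) | (pb - pa)
    return float(sum(tree.length[n] for n in sym))


def nnd_naive(tree: Phylogeny, focal: str, pool) -> float:
    return min(patristic_naive(tree, focal, s) for s in pool if s != focal)


def abc_species_naive(x, y) -> tuple[int, int, int]:
    x, y = set(x), set(y)
    return len(x & y), len(x - y), len(y - x)


def abc_phylo_naive(tree: Phylogeny, x, y) -> tuple[float, float, float]:
    bx: set[int] = set()
    by: set[int] = set()
    for s in x:
        bx |= root_path_nodes(tree, s)
    for s in y:
        by |= root_path_nodes(tree, s)
    w = lambda nodes: float(sum(tree.length[n] for n in nodes))
    return w(bx & by), w(bx - by), w(by - bx)


def index_naive(a: float, b: float, c: float, index: str) -> float:
    if a + b + c == 0:
        return float("nan")
    if index == "simpson":
        m = min(b, c)
        return m / (a + m) if a + m > 0 else 1.0
    if index == "sorensen":
        return (b + c) / (2 * a + b + c)
    if index == "jaccard":
        return (b + c) / (a + b + c)
    raise ValueError(index)


def mean_nnd_naive(tree: Phylogeny, focal_set, pool) -> float:
    vals = [
        min(patristic_naive(tree, f, s) for s in pool if s != f) for f in focal_set
    ]
    return sum(vals) / len(vals)
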