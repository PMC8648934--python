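"""Synthetic flora generator.

Produces complete, mutually consistent datasets — dated phylogeny, native
ranges, conservation statuses, naturalizations — with the statistical
structure the downstream analysis assumes:

* an ultrametric birth–death tree conditioned on the number of extant tips;
* contiguous native ranges nested in a TDWG-like two-level spatial
  hierarchy (level-3 regions inside level-1 continents), log-normal range
  sizes;
* a small recently-extinct fraction and IUCN-like category frequencies;
* a naturalized fraction with heavy-tailed (Pareto) invaded-range sizes,
  including a planted "superinvader" subset with extreme ranges, invading
  only continents other than the species' origin;
* an optional phylogenetic-clustering knob (λ): naturalization probability
  decays as exp(−λ·d) with patristic distance d to a randomly drawn
  invasion-seed species, for power studies of the relatedness tests.

Default fractions mirror the composition of the global flora dataset the
analysis is designed around (~0.5% recently extinct, ~5% naturalized of
~2×10⁵ species), scaled to desk-size species counts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from dendropy.model import birthdeath

from ._util import child_rng, child_seed, round_half_up
from .community import (
    CONTINENTS,
    CommunityMatrix,
    DataValidationError,
    SpatialHierarchy,
    SpeciesStatusTable,
)
from .tree import Phylogeny
import pandas as pd

#: Composition of the global study dataset (species counts) that the
#: generator's default fractions are scaled from.
STUDY_COMPOSITION = {
    "native_species": 205_456,
    "recently_extinct": 1_065,
    "naturalized": 10_138,
    "extinction_projections": 150_000,
}


def composition_percentages(composition: dict | None = None) -> dict[str, float]:
    """Naturalized / recently-extinct shares (percent) of the native flora."""
    c = composition or STUDY_COMPOSITION
    n = c["native_species"]
    return {
        "naturalized_percent": 100.0 * c["naturalized"] / n,
        "recently_extinct_percent": 100.0 * c["recently_extinct"] / n,
    }


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic flora; defaults define the standard study design."""

    n_species: int = 200
    birth_rate: float = 1.0  # per myr
    death_rate: float = 0.3  # per myr
    n_continents: int = 5
    regions_per_continent: int = 2
    cells_per_region: int = 10
    native_range_mean: float = 6.0  # cells; log-normal mean
    native_range_sigma: float = 0.75  # log-scale sd
    extinct_fraction: float = 0.005
    category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "LC": 0.55,
            "NT_CD": 0.10,
            "VU": 0.20,
            "EN": 0.10,
            "CR": 0.05,
        }
    )
    naturalized_fraction: float = 0.05
    invaded_range_tail: float = 1.3  # Pareto shape; smaller = heavier tail
    invaded_range_min: float = 4.0  # Pareto scale (cells)
    superinvader_fraction: float = 0.10  # of naturalized species
    phylo_clustering: float = 0.0  # λ ≥ 0; 0 = uniform naturalization
    n_families: int = 10
    cross_continent_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ConfigError("rates must be non-negative")
        if self.death_rate >= self.birth_rate:
            raise ConfigError(
                f"death_rate ({self.death_rate}) must be < birth_rate ({self.birth_rate})"
            )
        for name in (
            "extinct_fraction",
            "naturalized_fraction",
            "superinvader_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("category_weights must sum to 1")
        if self.phylo_clustering < 0:
            raise ConfigError("phylo_clustering must be >= 0")
        if self.n_continents < 1 or self.n_continents > len(CONTINENTS):
            raise ConfigError(f"n_continents must be in [1, {len(CONTINENTS)}]")
        if self.naturalized_fraction > 0 and self.n_continents < 2 and self.cross_continent_only:
            raise ConfigError("cross-continent naturalization needs >= 2 continents")


class SyntheticDataset(NamedTuple):
    tree: Phylogeny
    natives: CommunityMatrix
    status: SpeciesStatusTable
    hierarchy: SpatialHierarchy


# ---------------------------------------------------------------------------
# Stage generators


def build_hierarchy(config: SimulationConfig) -> SpatialHierarchy:
    """Deterministic grid of continents × regions × cells with stable names."""
    cell_region: dict[str, str] = {}
    region_continent: dict[str, str] = {}
    for cont in CONTINENTS[: config.n_continents]:
        tag = cont.replace(" ", "")
        for j in range(config.regions_per_continent):
            region = f"{tag}_r{j + 1}"
            region_continent[region] = cont
            for k in range(config.cells_per_region):
                cell_region[f"{region}_c{k + 1:02d}"] = region
    return SpatialHierarchy(cell_region, region_continent)


def simulate_tree(config: SimulationConfig, seed: int | None = None) -> Phylogeny:
    """Ultrametric birth–death tree conditioned on ``n_species`` extant tips.

    Tips are relabeled S0001… in tree (preorder) order so output is stable
    under a fixed seed.
    """
    config.validate()
    rng = random.Random(child_seed(config.seed if seed is None else seed, 0))
    try:
        dtree = birthdeath.birth_death_tree(
            birth_rate=config.birth_rate,
            death_rate=config.death_rate,
            num_extant_tips=config.n_species,
            rng=rng,
            repeat_until_success=True,
        )
    except Exception as exc:
        raise ConfigError(
            f"birth-death simulation failed at rates "
            f"b={config.birth_rate}, d={config.death_rate}: {exc}"
        ) from exc
    width = max(4, len(str(config.n_species)))
    for i, leaf in enumerate(
        nd for nd in dtree.preorder_node_iter() if nd.is_leaf()
    ):
        leaf.taxon.label = f"S{i + 1:0{width}d}"
    phylo = Phylogeny.from_dendropy(dtree)
    if phylo.n_tips != config.n_species:
        raise ConfigError(
            f"simulated tree has {phylo.n_tips} tips, expected {config.n_species}"
        )
    return phylo


def _lognormal_sizes(rng: np.random.Generator, mean: float, sigma: float, n: int):
    mu = np.log(mean) - 0.5 * sigma**2  # so the continuous mean equals `mean`
    return rng.lognormal(mu, sigma, size=n)


def simulate_native_ranges(
    tree: Phylogeny,
    hierarchy: SpatialHierarchy,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CommunityMatrix:
    """Contiguous native ranges: a block of cells within a home region,
    spilling into adjacent regions of the same continent when larger."""
    config.validate()
    rng = rng if rng is not None else child_rng(config.seed, 1)
    continents = hierarchy.continents
    cont_cells = {c: hierarchy.cells_in_continent(c) for c in continents}
    sizes = _lognormal_sizes(
        rng, config.native_range_mean, config.native_range_sigma, tree.n_tips
    )
    pairs: list[tuple[str, str]] = []
    for sp_label, raw in zip(tree.tip_labels, sizes):
        cont = continents[rng.integers(len(continents))]
        cells = cont_cells[cont]
        size = min(max(round_half_up(raw), 1), len(cells))
        start = int(rng.integers(0, len(cells) - size + 1))
        pairs.extend((cells[start + k], sp_label) for k in range(size))
    return CommunityMatrix.from_pairs(pairs, hierarchy)


def _basal_families(tree: Phylogeny, k: int) -> dict[str, str]:
    """Partition tips into k basal subtrees (split largest clade first)."""
    if k < 1 or k > tree.n_tips:
        raise ConfigError(f"n_families must be in [1, n_tips], got {k}")
    children: dict[int, list[int]] = {}
    for i in range(1, tree.n_nodes):
        children.setdefault(int(tree.parent[i]), []).append(i)
    n_below = np.zeros(tree.n_nodes, dtype=int)
    n_below[tree.tip_nodes] = 1
    for i in range(tree.n_nodes - 1, 0, -1):
        n_below[tree.parent[i]] += n_below[i]
    groups = [tree.root]
    while len(groups) < k:
        splittable = [g for g in groups if g in children]
        if not splittable:
            raise ConfigError("cannot split tree into that many families")
        g = max(splittable, key=lambda x: n_below[x])
        groups.remove(g)
        groups.extend(children[g])
    fam: dict[str, str] = {}
    tip_of_node = {int(n): lab for n, lab in zip(tree.tip_nodes, tree.tip_labels)}
    for gi, g in enumerate(sorted(groups)):
        stack = [g]
        name = f"F{gi + 1:02d}"
        while stack:
            node = stack.pop()
            if node in tip_of_node:
                fam[tip_of_node[node]] = name
            stack.extend(children.get(node, ()))
    return fam


def assign_statuses(
    tree: Phylogeny,
    natives: CommunityMatrix,
    config: SimulationConfig,
    hierarchy: SpatialHierarchy | None = None,
    rng: np.random.Generator | None = None,
) -> SpeciesStatusTable:
    """Flag recently-extinct species, draw IUCN-like categories, assign
    clade-based families, and set each species' origin continent from its
    native range."""
    config.validate()
    if natives.incidence.nnz == 0:
        raise ConfigError("native matrix is empty")
    rng = rng if rng is not None else child_rng(config.seed, 2)
    hierarchy = hierarchy or build_hierarchy(config)
    species = list(tree.tip_labels)
    n_re = round_half_up(config.extinct_fraction * len(species))
    re_set = set(map(str, rng.choice(species, size=n_re, replace=False))) if n_re else set()
    cats = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats])
    draws = rng.choice(cats, size=len(species), p=weights / weights.sum())
    families = _basal_families(tree, config.n_families)
    origin = {}
    for s in species:
        cells = natives.cells_of_species(s)
        origin[s] = hierarchy.continent_of(sorted(cells)[0])
    frame = pd.DataFrame(
        {
            "species_id": species,
            "family": [families[s] for s in species],
            "origin_continent": [origin[s] for s in species],
            "category": [
                "RECENTLY_EXTINCT" if s in re_set else d
                for s, d in zip(species, draws)
            ],
        }
    )
    return SpeciesStatusTable(frame)


def simulate_naturalizations(
    tree: Phylogeny,
    natives: CommunityMatrix,
    status: SpeciesStatusTable,
    hierarchy: SpatialHierarchy,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_planted: bool = False,
):
    """Select naturalizing species and give them invaded cell ranges.

    Selection is uniform over extant species at λ=0; at λ>0 a species'
    selection weight is exp(−λ·d) with d the patristic distance to a
    randomly drawn invasion-seed species. Invaded range sizes (total cells)
    are Pareto-tailed and laid down as contiguous blocks across randomly
    ordered foreign regions (a block never exceeds the region). The planted
    superinvader subset is cosmopolitan: it fills every foreign cell.
    """
    config.validate()
    if status.naturalized_cells:
        raise ConfigError("status table already has naturalized species")
    rng = rng if rng is not None else child_rng(config.seed, 3)
    n_nat = round_half_up(config.naturalized_fraction * config.n_species)
    if n_nat == 0:
        return (status, frozenset()) if return_planted else status
    extant = [s for s in status.species if status.category_of(s) != "RECENTLY_EXTINCT"]
    if n_nat > len(extant):
        raise ConfigError("more naturalized species requested than extant species")
    lam = config.phylo_clustering
    if lam > 0:
        seed_sp = extant[int(rng.integers(len(extant)))]
        D = tree.patristic_matrix()
        idx = tree.tip_index
        d = np.array([D[idx[s], idx[seed_sp]] for s in extant])
        w = np.exp(-lam * d)
        chosen = [str(x) for x in rng.choice(extant, size=n_nat, replace=False, p=w / w.sum())]
    else:
        chosen = [str(x) for x in rng.choice(extant, size=n_nat, replace=False)]

    n_super = round_half_up(config.superinvader_fraction * n_nat)
    order = rng.permutation(len(chosen))
    supers = frozenset(chosen[i] for i in order[:n_super])

    continents = hierarchy.continents
    region_cells = {r: hierarchy.cells_in_region(r) for r in hierarchy.regions}
    nat_cells: dict[str, frozenset[str]] = {}
    for s in chosen:
        origin = status.origin_of(s)
        foreign = (
            [c for c in continents if c != origin]
            if config.cross_continent_only
            else list(continents)
        )
        if not foreign:
            raise ConfigError(f"no foreign cells available for {s}")
        native_cells = natives.cells_of_species(s)
        foreign_regions = [
            r for r in hierarchy.regions if hierarchy.region_continent[r] in foreign
        ]
        avail = {
            r: [x for x in region_cells[r] if x not in native_cells]
            for r in foreign_regions
        }
        pool_size = sum(len(v) for v in avail.values())
        invaded: list[str] = []
        if s in supers:
            for r in foreign_regions:  # cosmopolitan: every foreign cell
                invaded.extend(avail[r])
        else:
            size = round_half_up(
                config.invaded_range_min * (1.0 + rng.pareto(config.invaded_range_tail))
            )
            size = min(max(size, 1), pool_size)
            for r in rng.permutation(foreign_regions):
                if size <= 0:
                    break
                cells = avail[r]
                if not cells:
                    continue
                take = min(size, len(cells))
                start = int(rng.integers(0, len(cells) - take + 1))
                invaded.extend(cells[start : start + take])
                size -= take
        nat_cells[s] = frozenset(invaded)
    updated = status.with_naturalizations(nat_cells)
    return (updated, supers) if return_planted else updated


def generate_dataset(
    config: SimulationConfig, return_planted: bool = False
) -> SyntheticDataset:
    """Full dataset: tree + native ranges + statuses + naturalizations.

    Each stage draws from its own child stream of ``config.seed``, so the
    whole dataset is reproducible and adding a stage never perturbs
    earlier stages.
    """
    config.validate()
    hierarchy = build_hierarchy(config)
    tree = simulate_tree(config)
    natives = simulate_native_ranges(tree, hierarchy, config)
    status = assign_statuses(tree, natives, config, hierarchy)
    out = simulate_naturalizations(
        tree, natives, status, hierarchy, config, return_planted=return_planted
    )
    if return_planted:
        status, planted = out
        return SyntheticDataset(tree, natives, status, hierarchy), planted
    return SyntheticDataset(tree, natives, out, hierarchy)
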