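"""Epoch/scenario construction.

The Holocene flora is the native assemblage of every cell, including
recently extinct species (pre-Columbian baseline). The Anthropocene flora
removes a scenario-specific set of status categories globally and adds the
invaded cells of surviving naturalized species. Six standard scenarios
span "naturalizations only" through "all threatened species lost".

Also houses the fixed 100-year extinction-probability scaling per IUCN-like
category and the superinvader outlier rule (invaded range size above
Q3 + 1.5×IQR within a level-3 region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import iqr_upper_fence
from .community import (
    CommunityMatrix,
    SpatialHierarchy,
    SpeciesStatusTable,
)

HOLOCENE = "HOLOCENE"
ANTHROPOCENE = "ANTHROPOCENE"

#: Expected probability of extinction over 100 years, by category.
EXTINCTION_PROBABILITY = {
    "LC": 0.001,
    "NT_CD": 0.01,
    "VU": 0.1,
    "EN": 0.67,
    "CR": 0.999,
}


def extinction_probability(category: str) -> float:
    try:
        return EXTINCTION_PROBABILITY[category]
    except KeyError:
        raise KeyError(
            f"unknown category {category!r}; expected one of "
            f"{sorted(EXTINCTION_PROBABILITY)}"
        ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    removed_categories: frozenset[str] = frozenset()
    exclude_superinvaders: bool = False
    include_naturalized: bool = True


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec("NO_EXTINCTIONS"),
        ScenarioSpec(
            "NO_SUPERINVASIVES",
            frozenset({"RECENTLY_EXTINCT"}),
            exclude_superinvaders=True,
        ),
        ScenarioSpec("BEST_CASE", frozenset({"RECENTLY_EXTINCT"})),
        ScenarioSpec("BUSINESS_AS_USUAL", frozenset({"RECENTLY_EXTINCT", "CR"})),
        ScenarioSpec(
            "INCREASED_EXTINCTION", frozenset({"RECENTLY_EXTINCT", "CR", "EN"})
        ),
        ScenarioSpec(
            "WORST_CASE", frozenset({"RECENTLY_EXTINCT", "CR", "EN", "VU"})
        ),
    )
}

#: Scenario order used for monotonicity statements.
EXTINCTION_ORDER = ("BEST_CASE", "BUSINESS_AS_USUAL", "INCREASED_EXTINCTION", "WORST_CASE")


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


# ---------------------------------------------------------------------------
# Superinvaders


def detect_superinvaders(
    status: SpeciesStatusTable,
    hierarchy: SpatialHierarchy,
    min_region_group: int = 4,
) -> frozenset[str]:
    """Naturalized species whose invaded range size (cells) within any
    level-3 region exceeds that region's Tukey fence Q3 + 1.5×IQR.

    Regions with fewer than ``min_region_group`` naturalized species are
    skipped (quartiles are unstable on tiny groups). Returns the union of
    flagged species across regions.
    """
    if not status.naturalized_cells:
        warnings.warn("no naturalized species; superinvader set is empty")
        return frozenset()
    per_region: dict[str, dict[str, int]] = {}
    for sp, cells in status.naturalized_cells.items():
        for c in cells:
            reg = hierarchy.region_of(c)
            per_region.setdefault(reg, {})
            per_region[reg][sp] = per_region[reg].get(sp, 0) + 1
    flagged: set[str] = set()
    for reg, sizes in per_region.items():
        if len(sizes) < min_region_group:
            continue
        fence = iqr_upper_fence(list(sizes.values()))
        flagged.update(sp for sp, n in sizes.items() if n > fence)
    return frozenset(flagged)


# ---------------------------------------------------------------------------
# Epoch matrices


def build_epoch_matrix(
    epoch: str,
    scenario: ScenarioSpec | str,
    natives: CommunityMatrix,
    status: SpeciesStatusTable,
    hierarchy: SpatialHierarchy,
    superinvaders: frozenset[str] | None = None,
) -> CommunityMatrix:
    """Community matrix for one epoch under one scenario.

    HOLOCENE: all natives (recently extinct included) in native cells only,
    identical across scenarios. ANTHROPOCENE: natives minus the scenario's
    removed categories (removed from all cells — extinction is species
    level), plus the invaded cells of surviving naturalized species; with
    ``exclude_superinvaders`` the superinvaders' invaded occurrences are
    dropped while their native occurrences are kept.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if epoch == HOLOCENE:
        return CommunityMatrix(natives.cells, natives.species, natives.incidence)
    if epoch != ANTHROPOCENE:
        raise ValueError(f"unknown epoch {epoch!r}")

    removed = status.species_in_category(scenario.removed_categories) if scenario.removed_categories else frozenset()
    pairs = [(c, s) for c, s in natives.to_pairs() if s not in removed]
    if scenario.include_naturalized:
        supers: frozenset[str] = frozenset()
        if scenario.exclude_superinvaders:
            supers = (
                superinvaders
                if superinvaders is not None
                else detect_superinvaders(status, hierarchy)
            )
        for sp, cells in status.naturalized_cells.items():
            if sp in removed or sp in supers:
                continue
            pairs.extend((c, sp) for c in sorted(cells))
    return CommunityMatrix.from_pairs(pairs, hierarchy, cells=natives.cells)


# ---------------------------------------------------------------------------
# Stochastic alternative to the categorical scenarios


def sample_stochastic_extinctions(
    status: SpeciesStatusTable, horizon_draws: int, seed: int
) -> list[frozenset[str]]:
    """Monte-Carlo extinction sets: each extant species is removed
    independently with its category's 100-year extinction probability."""
    rng = np.random.default_rng(seed)
    extant = [s for s in status.species if status.category_of(s) != "RECENTLY_EXTINCT"]
    probs = np.array([extinction_probability(status.category_of(s)) for s in extant])
    out = []
    for _ in range(horizon_draws):
        hits = rng.random(len(extant)) < probs
        out.append(frozenset(s for s, h in zip(extant, hits) if h))
    return out
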