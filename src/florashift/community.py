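"""Tabular domain objects: occurrence matrices, species statuses, spatial
hierarchy, and the per-cell change table.

All interchange is plain delimited text (comma or tab, auto-detected):

* occurrences — long format, header ``cell_id,species_id``, one row per
  presence;
* status — ``species_id,family,origin_continent,category``;
* naturalizations — ``species_id,cell_id`` (recipient cells);
* hierarchy — ``cell_id,region_id,continent_id`` (TDWG-like: level-3
  regions nested in level-1 continents).

Cell identifiers are opaque strings; no coordinate system is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tree import Phylogeny

CONTINENTS = (
    "Africa",
    "Temperate Asia",
    "Tropical Asia",
    "Australasia",
    "Pacific",
    "Europe",
    "North America",
    "South America",
)

CATEGORIES = ("LC", "NT_CD", "VU", "EN", "CR", "RECENTLY_EXTINCT")

CHANGE_COLUMNS = (
    "cell_id",
    "region_id",
    "continent_id",
    "scenario",
    "metric",
    "value_holocene",
    "value_anthropocene",
    "delta",
)


class DataValidationError(ValueError):
    pass


def _read_delimited(path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read comma- or tab-delimited text, sniffing the separator from the header."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Spatial hierarchy


@dataclass(frozen=True)
class SpatialHierarchy:
    """cell → (level-3 region, level-1 continent) mapping."""

    cell_region: dict[str, str]
    region_continent: dict[str, str]

    def __post_init__(self):
        for r in self.cell_region.values():
            if r not in self.region_continent:
                raise DataValidationError(f"region {r!r} has no continent")

    @property
    def cells(self) -> list[str]:
        return list(self.cell_region)

    @property
    def regions(self) -> list[str]:
        return list(self.region_continent)

    @property
    def continents(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.region_continent.values():
            seen.setdefault(c)
        return list(seen)

    def region_of(self, cell: str) -> str:
        return self.cell_region[cell]

    def continent_of(self, cell: str) -> str:
        return self.region_continent[self.cell_region[cell]]

    def cells_in_region(self, region: str) -> list[str]:
        return [c for c, r in self.cell_region.items() if r == region]

    def cells_in_continent(self, continent: str) -> list[str]:
        return [
            c
            for c, r in self.cell_region.items()
            if self.region_continent[r] == continent
        ]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpatialHierarchy":
        dup = df[df.duplicated("cell_id")]
        if len(dup):
            raise DataValidationError(
                f"cells mapped more than once: {sorted(dup.cell_id)[:10]}"
            )
        rc: dict[str, str] = {}
        for region, cont in zip(df.region_id, df.continent_id):
            if rc.setdefault(region, cont) != cont:
                raise DataValidationError(
                    f"region {region!r} mapped to multiple continents"
                )
        return cls(dict(zip(df.cell_id, df.region_id)), rc)

    @classmethod
    def read_csv(cls, path) -> "SpatialHierarchy":
        return cls.from_frame(
            _read_delimited(path, ("cell_id", "region_id", "continent_id"))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cells,
                "region_id": [self.cell_region[c] for c in self.cells],
                "continent_id": [self.continent_of(c) for c in self.cells],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Community matrix


class CommunityMatrix:
    """Boolean sparse cells × species incidence for one epoch/scenario."""

    def __init__(self, cells: list[str], species: list[str], incidence: sp.spmatrix):
        self.cells = list(cells)
        self.species = list(species)
        inc = sp.csr_matrix(incidence, dtype=bool)
        if inc.shape != (len(self.cells), len(self.species)):
            raise DataValidationError(
                f"incidence shape {inc.shape} != ({len(self.cells)}, {len(self.species)})"
            )
        inc.eliminate_zeros()
        self.incidence = inc
        self._cell_index = {c: i for i, c in enumerate(self.cells)}
        self._species_index = {s: i for i, s in enumerate(self.species)}

    # -- construction ----------------------------------------------------

    @classmethod
    def from_pairs(
        cls, pairs, hierarchy: SpatialHierarchy | None = None, cells: list[str] | None = None
    ) -> "CommunityMatrix":
        """Build from an iterable of (cell_id, species_id) presences.

        The cell universe defaults to the hierarchy's cells (keeping empty
        cells in play); species columns are the observed species, sorted.
        """
        pairs = list(pairs)
        if hierarchy is not None:
            unknown = sorted({c for c, _ in pairs if c not in hierarchy.cell_region})
            if unknown:
                raise DataValidationError(
                    f"{len(unknown)} cell(s) not in hierarchy: {unknown[:10]}"
                )
        if cells is None:
            cells = hierarchy.cells if hierarchy is not None else sorted({c for c, _ in pairs})
        species = sorted({s for _, s in pairs})
        ci = {c: i for i, c in enumerate(cells)}
        si = {s: i for i, s in enumerate(species)}
        rows = [ci[c] for c, _ in pairs]
        cols = [si[s] for _, s in pairs]
        inc = sp.csr_matrix(
            (np.ones(len(rows), dtype=bool), (rows, cols)),
            shape=(len(cells), len(species)),
        )
        return cls(cells, species, inc)

    @classmethod
    def read_occurrences(cls, path, hierarchy: SpatialHierarchy) -> "CommunityMatrix":
        df = _read_delimited(path, ("cell_id", "species_id"))
        if df.empty:
            raise DataValidationError(f"{path}: no occurrences")
        return cls.from_pairs(zip(df.cell_id, df.species_id), hierarchy)

    # -- accessors -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    def species_in_cell(self, cell: str) -> frozenset[str]:
        row = self.incidence.getrow(self._cell_index[cell])
        return frozenset(self.species[j] for j in row.indices)

    def cells_of_species(self, species: str) -> frozenset[str]:
        col = self.incidence.getcol(self._species_index[species])
        return frozenset(self.cells[i] for i in col.indices)

    def species_index(self, species: str) -> int:
        return self._species_index[species]

    def richness(self) -> pd.Series:
        counts = np.asarray(self.incidence.sum(axis=1)).ravel()
        return pd.Series(counts, index=pd.Index(self.cells, name="cell_id"), name="richness")

    def to_pairs(self) -> list[tuple[str, str]]:
        coo = self.incidence.tocoo()
        out = [(self.cells[i], self.species[j]) for i, j in zip(coo.row, coo.col)]
        out.sort()
        return out

    def restrict_species(self, keep) -> "CommunityMatrix":
        keep = set(keep)
        cols = [j for j, s in enumerate(self.species) if s in keep]
        return CommunityMatrix(
            self.cells, [self.species[j] for j in cols], self.incidence[:, cols]
        )

    def equals(self, other: "CommunityMatrix") -> bool:
        return (
            self.cells == other.cells
            and self.species == other.species
            and (self.incidence != other.incidence).nnz == 0
        )

    def write_csv(self, path) -> None:
        pd.DataFrame(self.to_pairs(), columns=["cell_id", "species_id"]).to_csv(
            path, index=False
        )


def read_occurrences(path, hierarchy: SpatialHierarchy) -> CommunityMatrix:
    return CommunityMatrix.read_occurrences(path, hierarchy)


# ---------------------------------------------------------------------------
# Species status


@dataclass
class SpeciesStatusTable:
    """Per-species origin, family, IUCN-like category, naturalized cells."""

    frame: pd.DataFrame  # species_id, family, origin_continent, category
    naturalized_cells: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        if df.species_id.duplicated().any():
            dupes = sorted(df.species_id[df.species_id.duplicated()])[:10]
            raise DataValidationError(f"duplicate species in status table: {dupes}")
        bad = set(df.category) - set(CATEGORIES)
        if bad:
            raise DataValidationError(f"unknown categories: {sorted(bad)}")
        self.naturalized_cells = {
            s: frozenset(c) for s, c in self.naturalized_cells.items() if c
        }
        re_nat = [
            s
            for s in self.naturalized_cells
            if self.category_of(s) == "RECENTLY_EXTINCT"
        ]
        if re_nat:
            raise DataValidationError(
                f"recently-extinct species flagged naturalized: {re_nat[:10]}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.frame.species_id)

    @property
    def naturalized_species(self) -> list[str]:
        return [s for s in self.frame.species_id if s in self.naturalized_cells]

    def category_of(self, species: str) -> str:
        return self._col("category")[species]

    def family_of(self, species: str) -> str:
        return self._col("family")[species]

    def origin_of(self, species: str) -> str:
        return self._col("origin_continent")[species]

    def is_naturalized(self, species: str) -> bool:
        return species in self.naturalized_cells

    def species_in_category(self, categories) -> frozenset[str]:
        cats = {categories} if isinstance(categories, str) else set(categories)
        mask = self.frame.category.isin(cats)
        return frozenset(self.frame.species_id[mask])

    def _col(self, name: str) -> dict[str, str]:
        key = f"_map_{name}"
        if not hasattr(self, key):
            object.__setattr__(
                self, key, dict(zip(self.frame.species_id, self.frame[name]))
            )
        return getattr(self, key)

    def with_naturalizations(
        self, naturalized_cells: dict[str, frozenset[str]]
    ) -> "SpeciesStatusTable":
        return SpeciesStatusTable(self.frame.copy(), dict(naturalized_cells))

    # -- I/O -------------------------------------------------------------

    @classmethod
    def read_csv(cls, status_path, naturalization_path=None) -> "SpeciesStatusTable":
        df = _read_delimited(
            status_path, ("species_id", "family", "origin_continent", "category")
        )
        nat: dict[str, set[str]] = {}
        if naturalization_path is not None:
            ndf = _read_delimited(naturalization_path, ("species_id", "cell_id"))
            for s, c in zip(ndf.species_id, ndf.cell_id):
                nat.setdefault(s, set()).add(c)
        return cls(df, {s: frozenset(c) for s, c in nat.items()})

    def write_csv(self, status_path, naturalization_path=None) -> None:
        self.frame.to_csv(status_path, index=False)
        if naturalization_path is not None:
            rows = [
                (s, c)
                for s in self.frame.species_id
                for c in sorted(self.naturalized_cells.get(s, ()))
            ]
            pd.DataFrame(rows, columns=["species_id", "cell_id"]).to_csv(
                naturalization_path, index=False
            )


# ---------------------------------------------------------------------------
# Change table


def change_rows(
    holo: pd.Series,
    anthro: pd.Series,
    metric: str,
    scenario: str,
    hierarchy: SpatialHierarchy,
) -> pd.DataFrame:
    """Per-cell relative change Δ = (v_anthro − v_holo)/v_holo.

    Rows where the Holocene value is zero or missing get delta = NaN
    (flagged missing rather than infinite).
    """
    if set(holo.index) != set(anthro.index):
        raise DataValidationError("cell universes differ between epochs")
    anthro = anthro.reindex(holo.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (anthro - holo) / holo
    delta = delta.where((holo > 0) & holo.notna() & anthro.notna())
    return pd.DataFrame(
        {
            "cell_id": holo.index,
            "region_id": [hierarchy.region_of(c) for c in holo.index],
            "continent_id": [hierarchy.continent_of(c) for c in holo.index],
            "scenario": scenario,
            "metric": metric,
            "value_holocene": holo.values,
            "value_anthropocene": anthro.values,
            "delta": delta.values,
        },
        columns=list(CHANGE_COLUMNS),
    )


def write_change_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(CHANGE_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Whole-dataset validation


@dataclass
class ValidationReport:
    fatal: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def raise_if_fatal(self) -> None:
        if self.fatal:
            raise DataValidationError(
                f"{len(self.fatal)} fatal issue(s); first 10: {self.fatal[:10]}"
            )


def validate_dataset(
    tree: Phylogeny,
    natives: CommunityMatrix,
    status: SpeciesStatusTable,
    hierarchy: SpatialHierarchy,
) -> ValidationReport:
    """Cross-check the four inputs; fatal issues abort the pipeline."""
    fatal: list[str] = []
    warnings: list[str] = []

    tips = tree.tip_set
    off_tree = [s for s in natives.species if s not in tips]
    if off_tree:
        fatal.append(
            f"{len(off_tree)} matrix species missing from tree: {off_tree[:10]}"
        )
    known = set(status.species)
    no_status = [s for s in natives.species if s not in known]
    if no_status:
        fatal.append(f"{len(no_status)} matrix species lack status rows: {no_status[:10]}")

    bad_cells = [c for c in natives.cells if c not in hierarchy.cell_region]
    if bad_cells:
        fatal.append(f"{len(bad_cells)} matrix cells not in hierarchy: {bad_cells[:10]}")

    for s, cells in status.naturalized_cells.items():
        missing = sorted(c for c in cells if c not in hierarchy.cell_region)
        if missing:
            fatal.append(f"naturalized cells of {s} not in hierarchy: {missing[:10]}")
        if s in natives._species_index:
            overlap = cells & natives.cells_of_species(s)
            if overlap:
                fatal.append(
                    f"naturalized cells of {s} overlap its native range: {sorted(overlap)[:10]}"
                )

    unused_tips = sorted(tips - set(natives.species))
    if unused_tips:
        warnings.append(f"{len(unused_tips)} tree tips never occur: {unused_tips[:10]}")
    occ = set(natives.species)
    idle = [s for s in status.species if s not in occ]
    if idle:
        warnings.append(f"{len(idle)} status rows without occurrences: {idle[:10]}")

    return ValidationReport(fatal, warnings)
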