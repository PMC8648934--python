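import numpy as np
import pandas as pd
import pytest

from florashift.community import (
    CommunityMatrix,
    SpatialHierarchy,
    SpeciesStatusTable,
)
from florashift.exchange import (
    family_flow_correlation,
    family_receipts,
    multitree_median,
    net_pd_per_species,
    pd_flow_matrix,
    pd_of_species,
    species_flow_matrix,
)
from florashift.tree import parse_newick

from .oracles import pd_naive


def _hier():
    return SpatialHierarchy(
        {"as1": "AS_r1", "na1": "NA_r1", "eu1": "EU_r1"},
        {"AS_r1": "Temperate Asia", "NA_r1": "North America", "EU_r1": "Europe"},
    )


def _status(rows, nat):
    frame = pd.DataFrame(
        rows, columns=["species_id", "family", "origin_continent", "category"]
    )
    return SpeciesStatusTable(frame, nat)


class TestSpeciesFlow:
    def test_single_recipient(self):
        status = _status(
            [("X", "F1", "Temperate Asia", "LC")], {"X": frozenset({"na1"})}
        )
        M = species_flow_matrix(status, _hier())
        assert M.loc["Temperate Asia", "North America"] == 1
        assert M.to_numpy().sum() == 1

    def test_multi_recipient_counts_once_per_continent(self):
        status = _status(
            [("X", "F1", "Temperate Asia", "LC")],
            {"X": frozenset({"na1", "eu1"})},
        )
        M = species_flow_matrix(status, _hier())
        assert M.loc["Temperate Asia", "North America"] == 1
        assert M.loc["Temperate Asia", "Europe"] == 1
        assert M.to_numpy().sum() == 2

    def test_no_naturalized_zero_matrix(self):
        status = _status([("X", "F1", "Europe", "LC")], {})
        assert species_flow_matrix(status, _hier()).to_numpy().sum() == 0

    def test_diagonal_zero_and_column_sums(self, default_dataset):
        tree, natives, status, hierarchy = default_dataset
        M = species_flow_matrix(status, hierarchy)
        assert np.all(np.diag(M.to_numpy()) == 0)
        for r in hierarchy.continents:
            direct = sum(
                1
                for s, cells in status.naturalized_cells.items()
                if any(hierarchy.continent_of(c) == r for c in cells)
                and status.origin_of(s) != r
            )
            assert M[r].sum() == direct


class TestPDFlow:
    def test_singleton_flow_equals_root_path(self, small_tree):
        status = _status(
            [("C", "F1", "Temperate Asia", "LC")], {"C": frozenset({"na1"})}
        )
        M = pd_flow_matrix(status, _hier(), small_tree)
        assert M.loc["Temperate Asia", "North America"] == pytest.approx(2.0)

    def test_shared_stem_not_double_counted(self, small_tree):
        status = _status(
            [
                ("A", "F1", "Temperate Asia", "LC"),
                ("B", "F1", "Temperate Asia", "LC"),
            ],
            {"A": frozenset({"na1"}), "B": frozenset({"na1"})},
        )
        M = pd_flow_matrix(status, _hier(), small_tree)
        joint = M.loc["Temperate Asia", "North America"]
        assert joint == pytest.approx(3.0)  # A + B edges + one shared stem
        indiv = sum(pd_of_species(small_tree, [s]) for s in "AB")
        assert joint < indiv

    def test_matches_brute_force(self, small_tree):
        assert pd_of_species(small_tree, ["A", "C"]) == pytest.approx(
            pd_naive(small_tree, ["A", "C"])
        )


class TestNetPD:
    def _inputs(self, small_tree):
        hier = _hier()
        natives = CommunityMatrix.from_pairs([("na1", "A")], hier)
        return hier, natives

    def test_new_branches_per_species(self, small_tree):
        """C flowing into a continent holding only A adds C's 2 myr edge
        plus nothing shared; ΔPD/1 species."""
        hier, natives = self._inputs(small_tree)
        status = _status(
            [("C", "F1", "Temperate Asia", "LC")], {"C": frozenset({"na1"})}
        )
        M = net_pd_per_species(natives, status, hier, small_tree)
        assert M.loc["Temperate Asia", "North America"] == pytest.approx(2.0)

    def test_fully_shared_branches_give_zero(self):
        """A flow spanning only branches the recipient already has adds 0."""
        star = parse_newick("(A:1,B:1,C:1);")
        hier = _hier()
        natives = CommunityMatrix.from_pairs([("na1", "A"), ("na1", "B")], hier)
        status = _status(
            [("B", "F1", "Temperate Asia", "LC")], {"B": frozenset({"na1"})}
        )
        # B is already native in the recipient: its root path adds nothing
        M = net_pd_per_species(natives, status, hier, star)
        assert M.loc["Temperate Asia", "North America"] == pytest.approx(0.0)

    def test_zero_flow_missing(self, small_tree):
        hier, natives = self._inputs(small_tree)
        status = _status([("C", "F1", "Temperate Asia", "LC")], {})
        M = net_pd_per_species(natives, status, hier, small_tree)
        assert M.isna().all().all()

    def test_shapley_matches_sequential_for_single_donor(self, small_tree):
        hier, natives = self._inputs(small_tree)
        status = _status(
            [("C", "F1", "Temperate Asia", "LC")], {"C": frozenset({"na1"})}
        )
        a = net_pd_per_species(natives, status, hier, small_tree, mode="sequential")
        b = net_pd_per_species(natives, status, hier, small_tree, mode="shapley")
        pd.testing.assert_frame_equal(a, b)

    def test_shapley_conserves_total_gain(self, small_tree):
        """Donor attributions sum to the recipient's total PD gain in both
        modes; Shapley splits shared stems instead of crediting the first."""
        hier = _hier()
        natives = CommunityMatrix.from_pairs([("na1", "C")], hier)
        status = _status(
            [
                ("A", "F1", "Temperate Asia", "LC"),
                ("B", "F1", "Europe", "LC"),
            ],
            {"A": frozenset({"na1"}), "B": frozenset({"na1"})},
        )
        total_gain = pd_of_species(small_tree, ["A", "B", "C"]) - pd_of_species(
            small_tree, ["C"]
        )
        for mode in ("sequential", "shapley"):
            M = net_pd_per_species(natives, status, hier, small_tree, mode=mode)
            got = (
                M.loc["Temperate Asia", "North America"]
                + M.loc["Europe", "North America"]
            )
            assert got == pytest.approx(total_gain)


class TestMultitreeMedian:
    def test_identity_and_median_conventions(self, small_tree):
        op = lambda t: pd.DataFrame({"v": [t.total_length]})
        assert multitree_median(op, [small_tree] * 3).v[0] == pytest.approx(5.0)
        vals = iter([1.0, 2.0, 30.0])
        op2 = lambda t: pd.DataFrame({"v": [next(vals)]})
        assert multitree_median(op2, [small_tree] * 3).v[0] == 2.0
        vals4 = iter([1.0, 2.0, 3.0, 4.0])
        op4 = lambda t: pd.DataFrame({"v": [next(vals4)]})
        assert multitree_median(op4, [small_tree] * 4).v[0] == 2.5

    def test_tip_set_mismatch_rejected(self, small_tree):
        other = parse_newick("(A:1,B:1,D:1);")
        with pytest.raises(ValueError):
            multitree_median(lambda t: pd.DataFrame(), [small_tree, other])


class TestFamilyCorrelation:
    def _status(self, fam_counts_a, fam_counts_b):
        rows, nat, i = [], {}, 0
        for fam, (na, nb) in {**fam_counts_a, **fam_counts_b} and {
            f: (fam_counts_a.get(f, 0), fam_counts_b.get(f, 0))
            for f in set(fam_counts_a) | set(fam_counts_b)
        }.items():
            for cont, n in (("North America", na), ("Europe", nb)):
                cell = "na1" if cont == "North America" else "eu1"
                for _ in range(n):
                    sp = f"S{i}"
                    i += 1
                    rows.append((sp, fam, "Temperate Asia", "LC"))
                    nat[sp] = frozenset({cell})
        return _status(rows, nat)

    def test_identical_vectors(self):
        s = self._status({"F1": 2, "F2": 3, "F3": 1}, {"F1": 2, "F2": 3, "F3": 1})
        r = family_flow_correlation(s, _hier(), "North America", "Europe")
        assert r == pytest.approx(1.0)

    def test_monotone_vectors(self):
        s = self._status({"F1": 1, "F2": 2, "F3": 3}, {"F1": 2, "F2": 4, "F3": 6})
        r = family_flow_correlation(s, _hier(), "North America", "Europe")
        assert r == pytest.approx(1.0)

    def test_reversed_ranks(self):
        s = self._status({"F1": 1, "F2": 2, "F3": 3}, {"F1": 3, "F2": 2, "F3": 1})
        r = family_flow_correlation(s, _hier(), "North America", "Europe")
        assert r == pytest.approx(-1.0)

    def test_too_few_families_missing(self):
        s = self._status({"F1": 1}, {"F1": 2})
        assert np.isnan(family_flow_correlation(s, _hier(), "North America", "Europe"))

    def test_receipts_exclude_own_exports(self, default_dataset):
        tree, natives, status, hierarchy = default_dataset
        for cont in hierarchy.continents[:2]:
            rec = family_receipts(status, hierarchy, cont)
            assert (rec >= 0).all()
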