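import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from florashift.beta import (
    BetaDecomposition,
    abc_phylo,
    abc_species,
    beta_index,
    delta_beta,
    region_mean_dissimilarity,
    ses_phylo_beta,
)
from florashift.community import CommunityMatrix, SpatialHierarchy
from florashift.tree import parse_newick

from .conftest import random_instance
from .oracles import abc_phylo_naive, abc_species_naive, index_naive


class TestDecompositions:
    def test_species_hand_example(self):
        d = abc_species({"A", "B", "C"}, {"A", "B", "D"})
        assert (d.a, d.b, d.c) == (2, 1, 1)

    def test_species_identical_and_disjoint(self):
        same = abc_species({"A", "B"}, {"A", "B"})
        assert (same.b, same.c) == (0, 0)
        assert abc_species({"A"}, {"B"}).a == 0

    def test_phylo_hand_example(self, small_tree):
        d = abc_phylo({"A", "B"}, {"A", "C"}, small_tree)
        assert d.a == pytest.approx(2.0)  # A edge + AB stem
        assert d.b == pytest.approx(1.0)  # B edge
        assert d.c == pytest.approx(2.0)  # C edge

    def test_phylo_star_tree_reduces_to_species_counts(self):
        star = parse_newick("(A:2,B:2,C:2,D:2);")
        dp = abc_phylo({"A", "B"}, {"B", "C", "D"}, star)
        ds = abc_species({"A", "B"}, {"B", "C", "D"})
        assert (dp.a, dp.b, dp.c) == (2 * ds.a, 2 * ds.b, 2 * ds.c)


class TestIndices:
    def test_hand_arithmetic(self):
        d = BetaDecomposition(2, 1, 1)
        assert beta_index(d, "simpson") == pytest.approx(1 / 3)
        assert beta_index(d, "sorensen") == pytest.approx(1 / 3)
        assert beta_index(d, "jaccard") == pytest.approx(1 / 2)

    @pytest.mark.parametrize("index", ["simpson", "sorensen", "jaccard"])
    def test_identical_cells_give_zero(self, index):
        assert beta_index(BetaDecomposition(3, 0, 0), index) == 0.0

    @pytest.mark.parametrize("index", ["simpson", "jaccard"])
    def test_disjoint_cells_give_one(self, index):
        assert beta_index(BetaDecomposition(0, 2, 3), index) == 1.0

    def test_both_empty_is_missing(self):
        assert np.isnan(beta_index(BetaDecomposition(0, 0, 0), "simpson"))

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    def test_index_ordering_and_bounds(self, a, b, c):
        """simpson ≤ sorensen ≤ jaccard, all within [0, 1]."""
        if a + b + c == 0:
            return
        d = BetaDecomposition(a, b, c)
        vals = [beta_index(d, i) for i in ("simpson", "sorensen", "jaccard")]
        assert 0 <= vals[0] <= vals[1] <= vals[2] <= 1

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_symmetry(self, a, b, c):
        for index in ("simpson", "sorensen", "jaccard"):
            v1 = beta_index(BetaDecomposition(a, b, c), index)
            v2 = beta_index(BetaDecomposition(a, c, b), index)
            assert v1 == v2 or (np.isnan(v1) and np.isnan(v2))


class TestOracleEquivalence:
    def test_decompositions_and_indices_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            tree, cells = random_instance(rng)
            for i in range(len(cells)):
                for j in range(i + 1, len(cells)):
                    ds = abc_species(cells[i], cells[j])
                    assert (ds.a, ds.b, ds.c) == abc_species_naive(cells[i], cells[j])
                    dp = abc_phylo(cells[i], cells[j], tree)
                    ref = abc_phylo_naive(tree, cells[i], cells[j])
                    assert (dp.a, dp.b, dp.c) == pytest.approx(ref)
                    for index in ("simpson", "sorensen", "jaccard"):
                        assert beta_index(dp, index) == pytest.approx(
                            index_naive(*ref, index)
                        )


class TestRegionMean:
    def _matrix(self, spec, hier):
        return CommunityMatrix.from_pairs(
            [(c, s) for c, spp in spec.items() for s in spp], hier
        )

    def test_two_cell_region_symmetry(self):
        hier = SpatialHierarchy({"x": "r1", "y": "r1"}, {"r1": "Africa"})
        m = self._matrix({"x": "ABC", "y": "ABD"}, hier)
        v = region_mean_dissimilarity(m, hier, "simpson")
        assert v["x"] == v["y"] == pytest.approx(1 / 3)

    def test_three_cell_mean(self):
        hier = SpatialHierarchy({c: "r1" for c in "xyz"}, {"r1": "Africa"})
        # xy: simpson 1/3; xz: 1; yz: 1  (hand-checked)
        m = self._matrix({"x": "AB", "y": "AC", "z": "D"}, hier)
        v = region_mean_dissimilarity(m, hier, "simpson")
        assert v["x"] == pytest.approx((1 / 2 + 1) / 2)
        assert v["z"] == pytest.approx(1.0)

    def test_single_cell_region_missing(self, toy_hierarchy):
        m = self._matrix({"c1": "A", "c2": "B", "c3": "C"}, toy_hierarchy)
        with pytest.warns(UserWarning, match="single cell"):
            v = region_mean_dissimilarity(m, toy_hierarchy, "simpson")
        assert np.isnan(v["c3"])  # r2 has one cell

    def test_adding_shared_species_homogenizes(self, default_dataset):
        """A species added to every cell of a region can only lower Simpson
        means and strictly lowers Sorensen/Jaccard means."""
        tree, natives, status, hier = default_dataset
        region = hier.regions[0]
        extra = [(c, "ZZZ") for c in hier.cells_in_region(region)]
        enriched = CommunityMatrix.from_pairs(natives.to_pairs() + extra, hier)
        cells = hier.cells_in_region(region)
        for index in ("simpson", "sorensen", "jaccard"):
            before = region_mean_dissimilarity(natives, hier, index)[cells]
            after = region_mean_dissimilarity(enriched, hier, index)[cells]
            if index == "simpson":
                assert (after <= before + 1e-12).all()
            else:
                assert (after < before).all()


class TestSesPhyloBeta:
    def test_star_tree_shuffle_invariant(self):
        star = parse_newick("(A:1,B:1,C:1,D:1);")
        hier = SpatialHierarchy({"x": "r1", "y": "r1"}, {"r1": "Africa"})
        m = CommunityMatrix.from_pairs(
            [("x", "A"), ("x", "B"), ("y", "C")], hier
        )
        res = ses_phylo_beta(m, star, hier, n_rand=30, seed=0)
        assert res.ses_phylo_beta.isna().all()

    def test_seed_determinism(self, small_tree):
        hier = SpatialHierarchy({"x": "r1", "y": "r1"}, {"r1": "Africa"})
        m = CommunityMatrix.from_pairs([("x", "A"), ("y", "C")], hier)
        a = ses_phylo_beta(m, small_tree, hier, n_rand=20, seed=5)
        b = ses_phylo_beta(m, small_tree, hier, n_rand=20, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestDeltaBeta:
    def test_homogenization_sign(self, toy_hierarchy):
        holo = pd.Series({"c1": 0.5, "c2": 0.5, "c3": 0.0})
        anthro = pd.Series({"c1": 0.4, "c2": 0.5, "c3": 0.1})
        out = delta_beta(holo, anthro, "beta_tax", "BEST_CASE", toy_hierarchy)
        d = dict(zip(out.cell_id, out.delta))
        assert d["c1"] == pytest.approx(-0.2)
        assert d["c2"] == 0.0
        assert np.isnan(d["c3"])
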