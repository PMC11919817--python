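import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import distance as ssd

from microgp import dissimilarity as dd
from microgp.containers import AbundanceTable
from microgp.simulate import simulate_tree
from oracles import unifrac_oracle

VEC = st.lists(
    st.floats(min_value=0, max_value=10, allow_nan=False, width=32),
    min_size=2, max_size=12,
)


class TestJaccard:
    def test_identical_presence_sets(self):
        assert dd.jaccard([1, 2, 0], [5, 1, 0]) == 0.0

    def test_disjoint_sets(self):
        assert dd.jaccard([1, 0], [0, 3]) == 1.0

    def test_hand_worked_overlap(self):
        # presence {t1,t2} vs {t2,t3}: 1 - 1/3
        assert dd.jaccard([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dd.jaccard([0, 0], [0, 0])

    @given(a=VEC, b=VEC)
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_on_presence_vectors(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if not (a > 0).any() and not (b > 0).any():
            return
        expected = ssd.jaccard(a > 0, b > 0)
        assert dd.jaccard(a, b) == pytest.approx(expected, abs=1e-12)


class TestBrayCurtis:
    def test_identity(self):
        assert dd.bray_curtis([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_no_shared_mass(self):
        assert dd.bray_curtis([1, 0], [0, 1]) == 1.0

    def test_hand_worked(self):
        assert dd.bray_curtis([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.25)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dd.bray_curtis([0, 0], [0, 0])

    @given(a=VEC, b=VEC)
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if a.sum() + b.sum() == 0:
            return
        assert dd.bray_curtis(a, b) == pytest.approx(ssd.braycurtis(a, b), abs=1e-12)


class TestBranchProfile:
    def test_hand_subtree_sums(self, worked_tree):
        # sample with all mass on A; edge order follows tree traversal
        vec = np.zeros(3)
        vec[worked_tree.leaf_names.index("A")] = 1.0
        prof = dd.branch_profile(worked_tree, vec)
        by_leafset = {
            frozenset(np.array(worked_tree.leaf_names)[row]): a
            for row, a in zip(worked_tree.descendants, prof.abundances)
        }
        assert by_leafset[frozenset({"A"})] == 1.0
        assert by_leafset[frozenset({"B"})] == 0.0
        assert by_leafset[frozenset({"A", "B"})] == 1.0
        assert by_leafset[frozenset({"C"})] == 0.0

    def test_all_zero_sample(self, worked_tree):
        prof = dd.branch_profile(worked_tree, np.zeros(3))
        assert not prof.presence.any()

    def test_full_community_presence_on_every_edge(self, worked_tree):
        prof = dd.branch_profile(worked_tree, np.full(3, 1 / 3))
        assert prof.presence.all()

    def test_length_mismatch_rejected(self, worked_tree):
        with pytest.raises(ValueError, match="length"):
            dd.branch_profile(worked_tree, np.ones(5))


def _vec(tree, mass: dict):
    v = np.zeros(tree.n_leaves)
    for name, x in mass.items():
        v[tree.leaf_names.index(name)] = x
    return v


class TestUniFracWorkedExamples:
    def test_unweighted_all_branches(self, worked_tree):
        a, b = _vec(worked_tree, {"A": 1.0}), _vec(worked_tree, {"C": 1.0})
        assert dd.unweighted_unifrac(worked_tree, a, b, "all_branches") == pytest.approx(0.8)

    def test_unweighted_union_branches(self, worked_tree):
        a, b = _vec(worked_tree, {"A": 1.0}), _vec(worked_tree, {"C": 1.0})
        assert dd.unweighted_unifrac(worked_tree, a, b, "union_branches") == pytest.approx(1.0)

    def test_weighted_disjoint_pair(self, worked_tree):
        a, b = _vec(worked_tree, {"A": 1.0}), _vec(worked_tree, {"C": 1.0})
        assert dd.weighted_unifrac(worked_tree, a, b) == pytest.approx(1.0)

    def test_weighted_sibling_pair_shares_internal_edge(self, worked_tree):
        a, b = _vec(worked_tree, {"A": 1.0}), _vec(worked_tree, {"B": 1.0})
        assert dd.weighted_unifrac(worked_tree, a, b) == pytest.approx(0.5)

    def test_identical_profiles_zero(self, worked_tree):
        a = _vec(worked_tree, {"A": 0.5, "C": 0.5})
        assert dd.unweighted_unifrac(worked_tree, a, a) == 0.0
        assert dd.weighted_unifrac(worked_tree, a, a) == 0.0

    def test_both_empty_rejected(self, worked_tree):
        z = np.zeros(3)
        with pytest.raises(ValueError):
            dd.unweighted_unifrac(worked_tree, z, z)
        with pytest.raises(ValueError):
            dd.weighted_unifrac(worked_tree, z, z)


class TestUniFracOracle:
    """Randomized equivalence against the leaf-enumeration oracle."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_trees_and_profiles(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_leaves = int(rng.integers(3, 13))
        tree = simulate_tree(n_leaves, seed=2000 + seed)
        newick = tree.to_newick()
        for _ in range(5):
            a = rng.random(n_leaves) * (rng.random(n_leaves) < 0.6)
            b = rng.random(n_leaves) * (rng.random(n_leaves) < 0.6)
            if not a.any():
                a[rng.integers(n_leaves)] = 0.5
            if not b.any():
                b[rng.integers(n_leaves)] = 0.5
            a, b = a / a.sum(), b / b.sum()
            da = dict(zip(tree.leaf_names, a))
            db = dict(zip(tree.leaf_names, b))
            for denom in ("all_branches", "union_branches"):
                assert dd.unweighted_unifrac(tree, a, b, denom) == pytest.approx(
                    unifrac_oracle(newick, da, db, weighted=False, denominator=denom),
                    abs=1e-10,
                )
            assert dd.weighted_unifrac(tree, a, b) == pytest.approx(
                unifrac_oracle(newick, da, db, weighted=True), abs=1e-10
            )


class TestDistanceMatrix:
    def test_degenerate_single_sample(self):
        t = AbundanceTable(["s1"], ["a", "b"], np.array([[0.5, 0.5]]), is_relative=True)
        dm = dd.distance_matrix(t, "bray_curtis")
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0.0

    def test_matrix_matches_pairwise_calls(self, toy_table):
        dm = dd.distance_matrix(toy_table, "jaccard")
        for i in range(3):
            for j in range(i + 1, 3):
                assert dm.values[i, j] == pytest.approx(
                    dd.jaccard(toy_table.values[i], toy_table.values[j])
                )

    def test_symmetry_and_zero_diagonal(self, synthetic_dataset):
        for dm in synthetic_dataset["distances"].values():
            np.testing.assert_array_equal(dm.values, dm.values.T)
            np.testing.assert_array_equal(np.diag(dm.values), 0.0)
            assert dm.values.min() >= 0 and dm.values.max() <= 1 + 1e-12

    def test_missing_tree_rejected(self, toy_table):
        with pytest.raises(ValueError, match="tree"):
            dd.distance_matrix(toy_table, "weighted_unifrac")

    def test_unifrac_matrix_matches_pairwise(self, worked_tree, toy_table):
        from microgp.io import to_relative

        rel = to_relative(toy_table)
        dm = dd.distance_matrix(rel, "weighted_unifrac", tree=worked_tree)
        order = [rel.taxon_ids.index(n) for n in worked_tree.leaf_names]
        vals = rel.values[:, order]
        for i in range(3):
            for j in range(i + 1, 3):
                assert dm.values[i, j] == pytest.approx(
                    dd.weighted_unifrac(worked_tree, vals[i], vals[j]), abs=1e-12
                )


class TestInvariants:
    def test_scale_invariance_of_counts(self, worked_tree):
        """Scaling one sample's raw counts before normalization changes nothing."""
        from microgp.io import to_relative

        counts = AbundanceTable(
            ["s1", "s2"], ["A", "B", "C"], np.array([[5.0, 3.0, 0.0], [1.0, 0.0, 6.0]])
        )
        scaled = AbundanceTable(
            ["s1", "s2"], ["A", "B", "C"], np.array([[50.0, 30.0, 0.0], [1.0, 0.0, 6.0]])
        )
        for metric in dd.METRICS:
            tree = worked_tree if metric.endswith("unifrac") else None
            d1 = dd.distance_matrix(to_relative(counts), metric, tree=tree).values[0, 1]
            d2 = dd.distance_matrix(to_relative(scaled), metric, tree=tree).values[0, 1]
            assert d1 == pytest.approx(d2, abs=1e-12)

    def test_all_branches_le_union_branches(self, synthetic_dataset):
        from microgp.io import align_tree_and_table

        rel = synthetic_dataset["relative"]
        tree, _ = align_tree_and_table(synthetic_dataset["tree"], rel, "intersect")
        d_all = dd.distance_matrix(rel, "unweighted_unifrac", tree, "all_branches")
        d_union = dd.distance_matrix(rel, "unweighted_unifrac", tree, "union_branches")
        assert np.all(d_all.values <= d_union.values + 1e-12)
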