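import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from littersuccession.diversity import (
    kruskal_wallis,
    mantel,
    pcoa,
    permanova,
    permanova_pairwise,
    shannon,
    unifrac_distance_matrix,
    unweighted_unifrac,
)
from littersuccession.errors import InputError, ParameterError
from littersuccession.io import FeatureTable
from littersuccession.synth import simulate_tree


class TestShannon:
    @pytest.mark.parametrize(
        "counts, base, expected",
        [([5, 5], 2, 1.0), ([10, 0, 0], 2, 0.0), ([4, 3, 2, 1], "e", 1.27985)],
    )
    def test_worked_examples(self, counts, base, expected):
        assert shannon(counts, base=base) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            shannon([0, 0, 0])

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=2, max_size=12))
    def test_uniform_maximizes_entropy_for_fixed_richness(self, counts):
        n = len(counts)
        assert shannon(counts) <= shannon([1] * n) + 1e-12


def _brute_force_unifrac(tree, set_a, set_b):
    """Independent oracle: recursive subtree-tip enumeration per branch."""

    def tips_below(node):
        if node.is_tip():
            return {node.name}
        out = set()
        for child in node.children:
            out |= tips_below(child)
        return out

    observed = unique = 0.0
    for node in tree.traverse(include_self=False):
        below = tips_below(node)
        in_a = bool(below & set_a)
        in_b = bool(below & set_b)
        if in_a or in_b:
            observed += node.length or 0.0
        if in_a != in_b:
            unique += node.length or 0.0
    return unique / observed if observed else 0.0


class TestUnifrac:
    def test_worked_example(self, four_leaf_tree):
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"A", "C"}) == pytest.approx(0.6)

    def test_identity_and_total_divergence(self, four_leaf_tree):
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"A", "B"}) == 0.0
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"C", "D"}) == 1.0

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(42)
        checked = 0
        for tree_seed in range(10):
            tree = simulate_tree(10, seed=tree_seed)
            leaves = [t.name for t in tree.tips()]
            for _ in range(10):
                a = set(rng.choice(leaves, rng.integers(1, 9), replace=False))
                b = set(rng.choice(leaves, rng.integers(1, 9), replace=False))
                expected = _brute_force_unifrac(tree, a, b)
                assert unweighted_unifrac(tree, a, b) == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked == 100

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        tree = simulate_tree(12, seed=7)
        leaves = [t.name for t in tree.tips()]
        for _ in range(20):
            a = set(rng.choice(leaves, 4, replace=False))
            b = set(rng.choice(leaves, 5, replace=False))
            d_ab = unweighted_unifrac(tree, a, b)
            assert d_ab == unweighted_unifrac(tree, b, a)
            assert 0.0 <= d_ab <= 1.0

    def test_distance_matrix_agrees_with_pairwise_calls(self, four_leaf_tree):
        counts = np.array([[3, 0], [1, 0], [0, 2], [0, 5]])
        table = FeatureTable(("A", "B", "C", "D"), ("s1", "s2"), counts)
        dm = unifrac_distance_matrix(table, four_leaf_tree)
        assert dm["s1", "s2"] == pytest.approx(
            unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"C", "D"})
        )

    def test_empty_presence_rejected(self, four_leaf_tree):
        with pytest.raises(InputError):
            unweighted_unifrac(four_leaf_tree, set(), {"A"})


class TestPcoa:
    def test_collinear_points_load_on_one_axis(self):
        points = np.array([[0.0], [1.0], [3.0]])
        dm = squareform(pdist(points))
        result = pcoa(dm)
        assert result.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(8, 3))
        dm = squareform(pdist(points))
        coords = pcoa(dm).coordinates.to_numpy()
        np.testing.assert_allclose(squareform(pdist(coords)), dm, atol=1e-8)

    def test_non_euclidean_matrix_reports_negative_eigenvalue(self):
        dm = np.array(
            [[0, 4, 1, 1], [4, 0, 1, 1], [1, 1, 0, 4], [1, 1, 4, 0]], dtype=float
        )  # violates the triangle inequality
        result = pcoa(dm)
        assert result.eigenvalues.min() < -1e-8

    def test_asymmetric_input_rejected(self):
        with pytest.raises(InputError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


def _brute_force_permanova_p(dist, labels):
    """Exhaustive oracle with explicit double-loop sums of squares."""
    n = len(labels)

    def pseudo_f(lab):
        groups = sorted(set(lab))
        ss_t = sum(dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g in groups:
            members = [i for i in range(n) if lab[i] == g]
            ss_w += sum(
                dist[i, j] ** 2 for i in members for j in members if i < j
            ) / len(members)
        ss_a = ss_t - ss_w
        return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))

    f_obs = pseudo_f(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if pseudo_f([labels[i] for i in perm]) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def test_well_separated_groups_reach_minimal_p(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(50, 0.1, (6, 2))])
        dm = squareform(pdist(x))
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert res["p"] == pytest.approx(1 / 100)

    def test_exhaustive_matches_brute_force_at_n6(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 2))
        dm = squareform(pdist(x))
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, labels, exhaustive=True)
        assert res["p"] == pytest.approx(_brute_force_permanova_p(dm, labels), abs=1e-12)

    def test_pseudo_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3))
        x[6:] += 1.0
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_pairwise_table_and_adjustment(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(i * 5, 1, (5, 2)) for i in range(3)])
        dm = squareform(pdist(x))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        table = permanova_pairwise(dm, labels, n_perm=99, seed=0, p_adjust="BH")
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["p"] - 1e-12).all()

    def test_small_group_pair_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 2))
        dm = squareform(pdist(x))
        with pytest.warns(UserWarning, match="skipped"):
            table = permanova_pairwise(dm, ["a", "a", "b", "b", "c"], n_perm=99, seed=0)
        assert set(map(tuple, table[["group_1", "group_2"]].values)) == {("a", "b")}


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_h(self):
        h, _ = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        assert h == pytest.approx(27 / 7)

    def test_group_order_invariance(self):
        h1, p1 = kruskal_wallis([[1, 5, 2], [7, 8], [3, 3, 9]])
        h2, p2 = kruskal_wallis([[3, 3, 9], [1, 5, 2], [7, 8]])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_all_constant_returns_h0_p1(self):
        assert kruskal_wallis([[4, 4], [4, 4, 4]]) == (0.0, 1.0)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        dm = squareform(pdist(rng.normal(size=(10, 3))))
        r, p = mantel(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        dm = squareform(pdist(rng.normal(size=(10, 3))))
        r, _ = mantel(dm, 3.0 * dm + 1.0 - np.diag(np.full(10, 1.0)), n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_p_values_approximately_uniform(self):
        from scipy.stats import kstest

        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            d1 = squareform(pdist(rng.normal(size=(12, 3))))
            d2 = squareform(pdist(rng.normal(size=(12, 3))))
            ps.append(mantel(d1, d2, n_perm=199, seed=seed)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_matrix_flagged(self):
        dm = np.ones((5, 5)) - np.eye(5)
        flat = np.zeros((5, 5))
        with pytest.warns(UserWarning, match="undefined"):
            r, p = mantel(dm, flat, n_perm=99)
        assert np.isnan(r) and np.isnan(p)
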