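"""Phylogenetic covariance, squared-change parsimony and multivariate K.

The independent oracles here deliberately use different computational
routes from the implementation: explicit path enumeration for the
covariance, an edge-list least-squares design for ancestral states, and a
literal eigen-decomposition transcription of the univariate K formula.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from phylanchor.landmark_io import read_newick_string
from phylanchor.phylo_signal import (
    k_mult,
    k_mult_test,
    phylo_covariance,
    scp_reconstruct,
    tree_length_test,
)
from phylanchor.synthetic import simulate_bm_traits, simulate_tree

from conftest import random_yule_tree


class TestPhyloCovariance:
    def test_worked_example(self, three_taxon_tree):
        c = phylo_covariance(three_taxon_tree)
        np.testing.assert_allclose(
            c.loc[["A", "B", "C"], ["A", "B", "C"]].to_numpy(),
            [[2, 1, 0], [1, 2, 0], [0, 0, 2]],
        )

    def test_star_tree_identity(self, star_tree):
        c = phylo_covariance(star_tree)
        np.testing.assert_allclose(c.to_numpy(), np.eye(5))

    def test_matches_path_enumeration(self, rng):
        """Shared root-to-tip path length computed by explicitly walking
        dendropy node paths."""
        for _ in range(5):
            tree = random_yule_tree(rng, 7)
            c = phylo_covariance(tree)
            dt = tree.dendropy_tree
            leaves = list(dt.leaf_node_iter())
            for la in leaves:
                for lb in leaves:
                    anc_a = set()
                    node = la
                    while node is not None:
                        anc_a.add(id(node))
                        node = node.parent_node
                    # walk from lb up; shared path = depth of deepest common ancestor
                    node = lb
                    while id(node) not in anc_a:
                        node = node.parent_node
                    depth = 0.0
                    while node.parent_node is not None:
                        depth += node.edge.length
                        node = node.parent_node
                    assert c.loc[la.taxon.label, lb.taxon.label] == pytest.approx(
                        depth, abs=1e-10
                    )

    def test_positive_semidefinite(self, rng):
        tree = random_yule_tree(rng, 10)
        eigs = np.linalg.eigvalsh(phylo_covariance(tree).to_numpy())
        assert eigs.min() > -1e-10

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_newick_string("((A:1,B:-1):1,C:2);")


class TestScpReconstruct:
    def test_star_tree_root_is_mean(self):
        tree = read_newick_string("(A:1,B:1,C:1);")
        m = scp_reconstruct(
            tree, np.array([[0.0], [1.0], [2.0]]), tip_labels=["A", "B", "C"]
        )
        assert m.node_coordinates[-1, 0] == pytest.approx(1.0, abs=1e-10)
        assert m.tree_length == pytest.approx(2.0, abs=1e-10)
        # brute-force 1-D check over the root value
        grid = np.linspace(-1, 3, 4001)
        lengths = ((grid[:, None] - np.array([0.0, 1.0, 2.0])) ** 2).sum(axis=1)
        assert m.tree_length <= lengths.min() + 1e-9

    def test_identical_tips(self, rng):
        tree = random_yule_tree(rng, 6)
        data = np.tile([3.0, -1.0], (6, 1))
        m = scp_reconstruct(tree, data)
        np.testing.assert_allclose(m.node_coordinates, np.tile([3.0, -1.0], (m.node_coordinates.shape[0], 1)))
        assert m.tree_length == pytest.approx(0.0, abs=1e-12)

    def test_tips_fixed_at_data(self, rng):
        tree = random_yule_tree(rng, 8)
        data = rng.normal(size=(8, 3))
        m = scp_reconstruct(tree, data)
        np.testing.assert_array_equal(m.tip_coordinates(), data)

    def test_tree_length_equals_branch_change_sum(self, rng):
        tree = random_yule_tree(rng, 8)
        m = scp_reconstruct(tree, rng.normal(size=(8, 2)))
        assert m.tree_length == pytest.approx(m.branch_changes.sum(), abs=1e-12)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_edge_list_least_squares(self, rng, weighted):
        """Oracle: build the per-edge weighted difference design matrix and
        solve for internal values with lstsq — an independent construction
        of the same optimum."""
        for _ in range(5):
            tree = random_yule_tree(rng, 8)
            data = rng.normal(size=(8, 2))
            m = scp_reconstruct(tree, data, weighted=weighted)
            arr = tree.as_arrays()
            tips = arr.tip_indices
            internals = np.where(~arr.is_tip)[0]
            col = {int(v): j for j, v in enumerate(internals)}
            rows, rhs = [], []
            for child in range(arr.n_nodes):
                par = arr.parent[child]
                if par < 0:
                    continue
                w = 1.0 / np.sqrt(arr.length[child]) if weighted else 1.0
                row = np.zeros(len(internals))
                b = np.zeros(2)
                for node, sign in ((par, 1.0), (child, -1.0)):
                    if node in col:
                        row[col[node]] += sign * w
                    else:
                        ti = int(np.where(tips == node)[0][0])
                        b -= sign * w * data[ti]
                rows.append(row)
                rhs.append(b)
            sol = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)[0]
            np.testing.assert_allclose(
                m.node_coordinates[internals], sol, atol=1e-8
            )

    def test_weighted_equals_numeric_minimum(self, rng):
        """Direct scipy minimization of the weighted criterion agrees."""
        tree = random_yule_tree(rng, 5)
        data = rng.normal(size=(5, 1))
        m = scp_reconstruct(tree, data, weighted=True)
        arr = tree.as_arrays()
        internals = np.where(~arr.is_tip)[0]
        tips = arr.tip_indices

        def crit(x_int):
            vals = np.zeros(arr.n_nodes)
            vals[tips] = data[:, 0]
            vals[internals] = x_int
            return sum(
                (vals[arr.parent[c]] - vals[c]) ** 2 / arr.length[c]
                for c in range(arr.n_nodes)
                if arr.parent[c] >= 0
            )

        res = minimize(crit, np.zeros(len(internals)), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(
            m.node_coordinates[internals, 0], res.x, atol=1e-6
        )

    def test_zero_length_edge_epsilon(self):
        tree = read_newick_string("((A:0,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="epsilon"):
            m = scp_reconstruct(tree, np.array([[0.0], [1.0], [2.0]]), tip_labels=["A", "B", "C"])
        assert np.isfinite(m.tree_length)


class TestKMult:
    def test_three_taxon_exact_value(self, three_taxon_tree):
        k = k_mult(
            three_taxon_tree, np.array([[0.0], [1.0], [2.0]]), tip_labels=["A", "B", "C"]
        )
        assert k == pytest.approx(101.0 / 96.0, abs=1e-10)

    def test_star_tree_is_exactly_one(self, rng):
        for bl in (1.0, 0.5, 3.0):
            inner = ",".join(f"t{i}:{bl}" for i in range(6))
            tree = read_newick_string(f"({inner});")
            data = rng.normal(size=(6, 4))
            assert k_mult(tree, data) == pytest.approx(1.0, abs=1e-10)

    def test_scale_and_rotation_invariance(self, rng):
        tree = random_yule_tree(rng, 8)
        data = rng.normal(size=(8, 5))
        k0 = k_mult(tree, data)
        assert k_mult(tree, data * 7.3) == pytest.approx(k0, abs=1e-10)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert k_mult(tree, data @ q) == pytest.approx(k0, abs=1e-10)

    def test_matches_univariate_blomberg_k(self, rng):
        """p = 1 reduces to Blomberg's K, transcribed independently via the
        eigen-decomposition of C."""
        for _ in range(50):
            tree = random_yule_tree(rng, int(rng.integers(6, 13)))
            n = tree.n_tips
            y = rng.normal(size=n)
            k = k_mult(tree, y.reshape(-1, 1))
            c = phylo_covariance(tree).to_numpy()
            w, v = np.linalg.eigh(c)
            c_inv = v @ np.diag(1.0 / w) @ v.T
            ones = np.ones(n)
            a = (ones @ c_inv @ y) / (ones @ c_inv @ ones)
            resid = y - a
            mse0 = resid @ resid / (n - 1)
            mse = resid @ c_inv @ resid / (n - 1)
            expected = (np.trace(c) - n / (ones @ c_inv @ ones)) / (n - 1)
            oracle = (mse0 / mse) / expected
            assert k == pytest.approx(oracle, abs=1e-10)


class TestPermutationTests:
    def test_strong_signal_small_p(self):
        """Traits equal to tip depths on a ladder tree: maximal signal."""
        tree = simulate_tree(10, mode="ladder", seed=0)
        arr = tree.as_arrays()
        # cumulative root-to-tip position index as a maximally treelike trait
        depth = np.zeros(arr.n_nodes)
        for i in range(arr.n_nodes - 1, -1, -1):
            p = arr.parent[i]
            depth[i] = arr.length[i] + (depth[p] if p >= 0 else 0)
        trait = np.arange(10, dtype=float).reshape(-1, 1)
        res = tree_length_test(tree, trait, n_permutations=999, seed=42)
        assert res.p_value <= 0.05
        res_k = k_mult_test(tree, trait, n_permutations=999, seed=42)
        assert res_k.p_value <= 0.05

    def test_identical_data_convention(self, rng):
        """All-identical tips: observed length 0 and every permutation ties,
        so the documented lower-tail +1 convention returns p = 1."""
        tree = random_yule_tree(rng, 6)
        res = tree_length_test(tree, np.ones((6, 2)), n_permutations=99, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-15)
        assert res.p_value == pytest.approx(1.0)

    def test_determinism(self, rng):
        tree = random_yule_tree(rng, 8)
        data = rng.normal(size=(8, 3))
        r1 = tree_length_test(tree, data, n_permutations=199, seed=7)
        r2 = tree_length_test(tree, data, n_permutations=199, seed=7)
        np.testing.assert_array_equal(r1.permuted, r2.permuted)
        assert r1.p_value == r2.p_value
        k1 = k_mult_test(tree, data, n_permutations=199, seed=7)
        k2 = k_mult_test(tree, data, n_permutations=199, seed=7)
        np.testing.assert_array_equal(k1.permuted, k2.permuted)

    def test_p_value_consistent_with_distribution(self, rng):
        tree = random_yule_tree(rng, 8)
        data = rng.normal(size=(8, 3))
        res = tree_length_test(tree, data, n_permutations=199, seed=3)
        assert res.p_value == (1 + np.sum(res.permuted <= res.observed)) / 200
        resk = k_mult_test(tree, data, n_permutations=199, seed=3)
        assert resk.p_value == (1 + np.sum(resk.permuted >= resk.observed)) / 200

    def test_bm_power(self):
        """K test detects Brownian signal on a 10-tip tree in most replicates."""
        tree = simulate_tree(10, mode="yule", seed=13)
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            y = simulate_bm_traits(tree, p=5, rate=1.0, rng=rng)
            res = k_mult_test(tree, y, n_permutations=199, seed=int(rng.integers(2**31)))
            hits += res.p_value <= 0.05
        assert hits / n_rep > 0.5

    def test_invalid_permutation_count(self, rng):
        tree = random_yule_tree(rng, 5)
        with pytest.raises(ValueError):
            tree_length_test(tree, rng.normal(size=(5, 2)), n_permutations=0)


def test_mean_k_near_one_under_bm_small():
    """Quick own-null calibration on a 32-tip tree (the full 500-replicate
    64-tip check lives in the acceptance suite)."""
    tree = simulate_tree(32, mode="yule", seed=8)
    rng = np.random.default_rng(8)
    ks = [k_mult(tree, simulate_bm_traits(tree, p=10, rate=1.0, rng=rng)) for _ in range(100)]
    assert 0.9 < np.mean(ks) < 1.1
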