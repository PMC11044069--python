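"""Phylogenetic signal statistics for multivariate (shape) data.

Two complementary tests are provided.

*Squared-change parsimony mapping.* Internal-node positions are chosen to
minimise the summed squared change along branches (optionally weighted by
the inverse branch length, in which case the estimates coincide with the
maximum-likelihood ancestral states under Brownian motion). The mapped
"tree length" — the total summed squared change — is compared with its
distribution when the tip data are permuted across the tree: phylogenetic
signal makes the observed mapping shorter than permuted ones, so the test
is lower-tailed.

*Multivariate K.* The multivariate generalization of Blomberg's K: the
ratio of the observed mean squared deviation from the phylogenetic mean
to its Brownian-expected value under the tree covariance C, equal to 1
when trait covariance among tips exactly follows Brownian motion on the
tree. Significance comes from an upper-tailed permutation of rows across
tips.

Both tests use the +1 permutation convention
p = (1 + #{permuted at least as extreme}) / (1 + N), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmark_io import PhyloTree

__all__ = [
    "PhylomorphospaceMap",
    "SignalTestResult",
    "phylo_covariance",
    "scp_reconstruct",
    "tree_length_test",
    "k_mult",
    "k_mult_test",
]


def phylo_covariance(tree: PhyloTree) -> pd.DataFrame:
    """Brownian-motion tip covariance structure of a rooted tree.

    Entry (i, j) is the shared root-to-tip path length of tips i and j;
    the diagonal holds root-to-tip depths. Returned as a DataFrame indexed
    by tip label in tree order.
    """
    arr = tree.as_arrays()
    n_nodes = arr.n_nodes
    depth = np.zeros(n_nodes)
    # root is last in postorder; walk preorder (reverse postorder)
    for i in range(n_nodes - 1, -1, -1):
        p = arr.parent[i]
        depth[i] = arr.length[i] + (depth[p] if p >= 0 else 0.0)

    tips = arr.tip_indices
    n = len(tips)
    # ancestor sets per tip for shared-path computation
    anc: list[dict[int, float]] = []
    for t in tips:
        path: dict[int, float] = {}
        node = t
        while node >= 0:
            path[node] = depth[node]
            node = arr.parent[node]
        anc.append(path)
    c = np.zeros((n, n))
    for a in range(n):
        c[a, a] = depth[tips[a]]
        for b in range(a + 1, n):
            shared = max(
                (d for node, d in anc[a].items() if node in anc[b]), default=0.0
            )
            c[a, b] = c[b, a] = shared
    return pd.DataFrame(c, index=arr.tip_labels, columns=arr.tip_labels)


@dataclass
class PhylomorphospaceMap:
    """Squared-change-parsimony mapping of tip data onto a tree.

    ``node_coordinates`` holds every node's d-dimensional position in
    postorder node index order (tips fixed at the input data);
    ``branch_changes`` the per-edge squared-change contribution (edge
    identified by its child node index); ``tree_length`` their sum.
    """

    node_coordinates: np.ndarray
    branch_changes: np.ndarray
    tree_length: float
    tip_labels: list[str]
    tip_index: np.ndarray
    parent: np.ndarray

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) node index pairs."""
        return [(int(p), i) for i, p in enumerate(self.parent) if p >= 0]

    def tip_coordinates(self) -> np.ndarray:
        return self.node_coordinates[self.tip_index]


class _ScpSolver:
    """Precomputed linear solve for squared-change parsimony on one tree.

    For a fixed tree the optimal internal-node values are linear in the
    tip data, so the mapped tree length is a quadratic form in the tips:
    tree_length = tr(X' M X) with M = B'B, where B maps tip values to
    per-edge changes at the optimum. Precomputing B makes permutation
    tests cheap.
    """

    def __init__(self, tree: PhyloTree, weighted: bool = True, epsilon: float = 1e-12):
        arr = tree.as_arrays()
        self.arr = arr
        n_nodes = arr.n_nodes
        tips = arr.tip_indices
        internals = np.where(~arr.is_tip)[0]
        self.tips = tips
        self.internals = internals
        edges = [(arr.parent[i], i) for i in range(n_nodes) if arr.parent[i] >= 0]
        self.edges = edges
        w = np.ones(len(edges))
        if weighted:
            lengths = np.array([arr.length[c] for _, c in edges])
            if np.any(lengths <= 0):
                import warnings

                warnings.warn(
                    f"zero-length edge with weighted reconstruction; substituting epsilon={epsilon:g}",
                    UserWarning,
                    stacklevel=3,
                )
                lengths = np.where(lengths <= 0, epsilon, lengths)
            w = 1.0 / lengths
        # weighted graph Laplacian over all nodes
        lap = np.zeros((n_nodes, n_nodes))
        for (p, c), wi in zip(edges, w):
            lap[p, p] += wi
            lap[c, c] += wi
            lap[p, c] -= wi
            lap[c, p] -= wi
        lii = lap[np.ix_(internals, internals)]
        lit = lap[np.ix_(internals, tips)]
        # internal values = A @ tip values at the optimum
        self.a_matrix = -np.linalg.solve(lii, lit) if len(internals) else np.zeros((0, len(tips)))
        # edge-change operator on tip values: change_e = (N x_t)_parent - (N x_t)_child
        n_map = np.zeros((n_nodes, len(tips)))
        n_map[tips, np.arange(len(tips))] = 1.0
        if len(internals):
            n_map[internals] = self.a_matrix
        b = np.zeros((len(edges), len(tips)))
        for e, (p, c) in enumerate(edges):
            b[e] = n_map[p] - n_map[c]
        self.b_matrix = b
        self.n_map = n_map

    def tree_length(self, tip_data: np.ndarray) -> float:
        """Unweighted summed squared change at the optimum for tip_data (n, d)."""
        changes = self.b_matrix @ tip_data
        return float(np.sum(changes**2))

    def reconstruct(self, tip_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nodes = self.n_map @ tip_data
        changes = self.b_matrix @ tip_data
        return nodes, np.sum(changes**2, axis=1)


def _tip_data_in_tree_order(
    tree: PhyloTree, tip_data: np.ndarray, tip_labels
) -> tuple[np.ndarray, list[str]]:
    data = np.atleast_2d(np.asarray(tip_data, float))
    if data.shape[0] == 1 and tree.n_tips > 1 and data.shape[1] == tree.n_tips:
        data = data.T
    arr_labels = tree.as_arrays().tip_labels
    if tip_labels is None:
        if data.shape[0] != tree.n_tips:
            raise ValueError("tip_data rows must equal number of tips")
        return data, arr_labels
    labels = list(tip_labels)
    if set(labels) != set(arr_labels):
        raise ValueError(
            f"tip label mismatch: {sorted(set(labels) ^ set(arr_labels))}"
        )
    order = [labels.index(lbl) for lbl in arr_labels]
    return data[order], arr_labels


def scp_reconstruct(
    tree: PhyloTree,
    tip_data: np.ndarray,
    weighted: bool = True,
    tip_labels=None,
) -> PhylomorphospaceMap:
    """Map tip data onto the tree by squared-change parsimony.

    Internal-node coordinates minimise the summed squared Euclidean change
    along edges, each edge's contribution divided by its length when
    ``weighted`` (the Brownian-motion maximum-likelihood ancestral
    states). The reported ``tree_length`` is the plain (unweighted) sum of
    squared changes at that optimum, in squared units of the input space.
    """
    tree = tree.edge_lengths_or_default()
    data, labels = _tip_data_in_tree_order(tree, tip_data, tip_labels)
    solver = _ScpSolver(tree, weighted=weighted)
    nodes, per_edge = solver.reconstruct(data)
    changes = np.zeros(solver.arr.n_nodes)
    for (p, c), sq in zip(solver.edges, per_edge):
        changes[c] = sq
    return PhylomorphospaceMap(
        node_coordinates=nodes,
        branch_changes=changes,
        tree_length=float(per_edge.sum()),
        tip_labels=labels,
        tip_index=solver.tips,
        parent=solver.arr.parent,
    )


@dataclass
class SignalTestResult:
    """Permutation test of phylogenetic signal.

    ``permuted`` holds the full permutation distribution (for histogram
    export); ``p_value`` follows the +1 convention for the documented tail
    (lower for tree length, upper for K).
    """

    statistic_name: str
    observed: float
    permuted: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    tail: str

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "tail": self.tail,
            "seed": self.seed,
        }


def tree_length_test(
    tree: PhyloTree,
    tip_data: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    weighted: bool = True,
    tip_labels=None,
) -> SignalTestResult:
    """Permutation test of phylogenetic signal via mapped tree length.

    The observed statistic is the squared-change-parsimony tree length;
    each permutation reassigns whole data rows across the tips (jointly
    over all dimensions) and recomputes the length. Signal makes the
    observed mapping shorter than permuted ones, so
    p = (1 + #{permuted <= observed}) / (1 + N).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    tree = tree.edge_lengths_or_default()
    data, _ = _tip_data_in_tree_order(tree, tip_data, tip_labels)
    solver = _ScpSolver(tree, weighted=weighted)
    observed = solver.tree_length(data)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    n = data.shape[0]
    for i in range(n_permutations):
        permuted[i] = solver.tree_length(data[rng.permutation(n)])
    p = (1 + int(np.sum(permuted <= observed))) / (1 + n_permutations)
    return SignalTestResult(
        statistic_name="tree_length",
        observed=observed,
        permuted=permuted,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        tail="lower",
    )


def _k_mult_from_parts(
    y: np.ndarray, c_inv: np.ndarray, trace_c: float, ones_cinv: np.ndarray, s_ones: float
) -> float:
    n = y.shape[0]
    a = (ones_cinv @ y) / s_ones  # phylogenetic mean, (p,)
    yc = y - a
    num = float(np.sum(yc**2))
    den = float(np.einsum("ij,ik,kj->", yc, c_inv, yc))
    expected = (trace_c - n / s_ones) / (n - 1)
    if den == 0:
        return 0.0
    return (num / den) / expected


def k_mult(tree: PhyloTree, tip_data: np.ndarray, tip_labels=None) -> float:
    """Multivariate K statistic of phylogenetic signal.

    With C the Brownian tip covariance and a the GLS (phylogenetic) mean,
    K is the ratio of tr[(Y-1a)'(Y-1a)] to tr[(Y-1a)'C^{-1}(Y-1a)],
    scaled by its Brownian expectation (tr C - n / (1'C^{-1}1)) / (n - 1).
    K = 1 when the data's covariance among tips matches Brownian motion on
    the tree; K > 1 indicates stronger, K < 1 weaker phylogenetic
    structuring. Reduces to Blomberg's K for a single trait.
    """
    tree = tree.edge_lengths_or_default()
    data, labels = _tip_data_in_tree_order(tree, tip_data, tip_labels)
    n = data.shape[0]
    if n < 3:
        raise ValueError("K requires at least 3 tips")
    c = phylo_covariance(tree).to_numpy()
    try:
        c_inv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; consider adding a small epsilon to zero branch lengths"
        ) from exc
    ones_cinv = c_inv.sum(axis=0)
    s_ones = float(ones_cinv.sum())
    return _k_mult_from_parts(data, c_inv, float(np.trace(c)), ones_cinv, s_ones)


def k_mult_test(
    tree: PhyloTree,
    tip_data: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    tip_labels=None,
) -> SignalTestResult:
    """Randomization test for the multivariate K statistic.

    Data rows are permuted across tips; the test is upper-tailed
    (signal inflates K): p = (1 + #{permuted K >= observed}) / (1 + N).
    The full permuted distribution is returned for histogram export.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    tree = tree.edge_lengths_or_default()
    data, _ = _tip_data_in_tree_order(tree, tip_data, tip_labels)
    n = data.shape[0]
    if n < 3:
        raise ValueError("K requires at least 3 tips")
    c = phylo_covariance(tree).to_numpy()
    c_inv = np.linalg.inv(c)
    ones_cinv = c_inv.sum(axis=0)
    s_ones = float(ones_cinv.sum())
    trace_c = float(np.trace(c))
    observed = _k_mult_from_parts(data, c_inv, trace_c, ones_cinv, s_ones)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted[i] = _k_mult_from_parts(
            data[rng.permutation(n)], c_inv, trace_c, ones_cinv, s_ones
        )
    p = (1 + int(np.sum(permuted >= observed))) / (1 + n_permutations)
    return SignalTestResult(
        statistic_name="k_mult",
        observed=observed,
        permuted=permuted,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        tail="upper",
    )
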