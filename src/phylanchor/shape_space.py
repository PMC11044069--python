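"""Shape principal components and allometry.

Shape variation is summarised by a PCA of the covariance matrix of the
superimposed (Procrustes) coordinates. Allometry — the dependence of shape
on size — is assessed by multivariate regression of the shape variables on
log centroid size; because species data are not independent samples, the
same regression can be run on phylogenetic independent contrasts, which
are uncorrelated under Brownian motion. Residuals from the ordinary
regression give size-corrected shapes for downstream mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gpa import ProcrustesAlignment
from .landmark_io import PhyloTree

__all__ = [
    "ShapeSpace",
    "AllometryFit",
    "shape_pca",
    "regress_shape_on_size",
    "independent_contrasts",
    "allometry_with_pic",
    "size_correct",
]


@dataclass
class ShapeSpace:
    """Principal components of shape variation.

    ``eigenvalues`` are non-increasing variances of the components (sum
    equals the total Procrustes variance); ``scores`` the (n, d) specimen
    coordinates in component space (zero column means, diagonal
    covariance); ``loadings`` the (d, k, 2) shape direction of each
    component; ``grand_mean`` the (k, 2) mean shape the data were centred
    on.
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    grand_mean: np.ndarray
    specimen_ids: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def variance_table(self):
        """Eigenvalue / % variance / cumulative % table as a DataFrame."""
        import pandas as pd

        cum = np.cumsum(self.percent_variance)
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.n_components)],
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
                "cumulative_percent": cum,
            }
        )


def shape_pca(alignment: ProcrustesAlignment | np.ndarray, specimen_ids=None) -> ShapeSpace:
    """PCA of the covariance matrix of flattened Procrustes coordinates.

    Accepts a :class:`ProcrustesAlignment` or a raw ``(n, 2k)`` matrix of
    shape variables. At most ``n - 1`` components are retained (the rank
    bound of the sample covariance); eigenvalues use the n - 1 denominator.
    """
    if isinstance(alignment, ProcrustesAlignment):
        flat = alignment.flattened()
        ids = alignment.specimen_ids
    else:
        flat = np.asarray(alignment, float)
        ids = list(specimen_ids) if specimen_ids is not None else [f"specimen_{i + 1}" for i in range(len(flat))]
    n, p = flat.shape
    if n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    mean = flat.mean(axis=0)
    centred = flat - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eig = s**2 / (n - 1)
    d = min(n - 1, p)
    eig = eig[:d]
    scores = (u[:, :d] * s[:d])
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    k = p // 2
    loadings = vt[:d].reshape(d, k, 2)
    return ShapeSpace(
        eigenvalues=eig,
        percent_variance=pct,
        scores=scores,
        loadings=loadings,
        grand_mean=mean.reshape(k, 2),
        specimen_ids=ids,
    )


@dataclass
class AllometryFit:
    """Multivariate regression of shape on log centroid size.

    ``coefficient_vector`` is the per-coordinate slope on logCS;
    ``percent_predicted`` the share of total shape variation the
    regression explains; ``p_value`` a permutation probability;
    ``residual_shapes`` the size-corrected shape variables;
    ``mode`` is ``"ordinary"`` or ``"pic"``.
    """

    coefficient_vector: np.ndarray
    percent_predicted: float
    p_value: float
    residual_shapes: np.ndarray
    mode: str
    n_permutations: int
    seed: int | None


def _percent_predicted(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Through-the-origin regression of y (n x p) on z (n,): returns
    (percent predicted, slope vector, predicted matrix)."""
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("predictor has zero variance")
    beta = (z @ y) / denom  # (p,)
    pred = np.outer(z, beta)
    ss_tot = float(np.sum(y**2))
    ss_pred = float(np.sum(pred**2))
    pct = 100.0 * ss_pred / ss_tot if ss_tot > 0 else 0.0
    return pct, beta, pred


def regress_shape_on_size(
    shapes: np.ndarray,
    log_cs: np.ndarray,
    centered: bool = True,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> AllometryFit:
    """Multivariate regression of shape variables on log centroid size.

    With ``centered=True`` (the convention for species data) both sides
    are mean-centred before the through-the-origin fit, so the slope is
    the usual allometric vector and the intercept is absorbed by the mean
    shape. ``percent_predicted`` is 100 x (predicted SS) / (total SS) of
    the (centred) shape variables. The p-value permutes the logCS values
    across specimens, with the +1 convention
    p = (1 + #{permuted % >= observed %}) / (1 + N).
    """
    shapes = np.asarray(shapes, float)
    log_cs = np.asarray(log_cs, float)
    n = shapes.shape[0]
    if n < 3:
        raise ValueError("regression needs at least 3 specimens")
    if log_cs.shape != (n,):
        raise ValueError("log_cs must have one value per specimen")
    if np.allclose(log_cs, log_cs[0]):
        raise ValueError("predictor (logCS) is constant: zero variance")
    if centered:
        z = log_cs - log_cs.mean()
        y = shapes - shapes.mean(axis=0)
    else:
        z = log_cs
        y = shapes
    pct, beta, pred = _percent_predicted(z, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        pct_p, _, _ = _percent_predicted(zp, y)
        if pct_p >= pct:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)
    residuals = shapes - pred
    return AllometryFit(
        coefficient_vector=beta,
        percent_predicted=pct,
        p_value=p_value,
        residual_shapes=residuals,
        mode="ordinary",
        n_permutations=n_permutations,
        seed=seed,
    )


def independent_contrasts(tree: PhyloTree, traits: np.ndarray, tip_labels=None) -> np.ndarray:
    """Felsenstein's phylogenetic independent contrasts.

    ``traits`` is an (n, p) matrix whose rows follow ``tip_labels`` (or the
    tree's own tip order if omitted). Pruning proceeds from the tips: at a
    node joining daughters with values x1, x2 on (extended) branches
    v1, v2, the standardized contrast is (x1 - x2) / sqrt(v1 + v2), the
    node value the branch-length-weighted average of the daughters, and
    the node's own branch is extended by v1 v2 / (v1 + v2). Polytomies are
    resolved arbitrarily with zero-length internal edges (with a warning);
    the result is (n - 1, p) contrasts in postorder.
    """
    traits = np.atleast_2d(np.asarray(traits, float))
    if traits.shape[0] == 1 and tree.n_tips > 1:
        traits = traits.T
    labels = list(tip_labels) if tip_labels is not None else list(tree.tip_labels)
    if traits.shape[0] != len(labels):
        raise ValueError("traits rows must match tip labels")
    missing = set(labels) ^ set(tree.tip_labels)
    if missing:
        raise ValueError(f"tip label mismatch between tree and traits: {sorted(missing)}")
    tree = tree.edge_lengths_or_default()
    arr = tree.as_arrays()
    order = [labels.index(lbl) for lbl in arr.tip_labels]
    children = arr.children()
    if any(len(children[i]) > 2 for i in range(arr.n_nodes)):
        warnings.warn(
            "tree contains polytomies; resolved arbitrarily with zero-length edges",
            UserWarning,
            stacklevel=2,
        )

    p = traits.shape[1]
    value = np.zeros((arr.n_nodes, p))
    vlen = arr.length.astype(float).copy()
    tip_iter = iter(order)
    contrasts: list[np.ndarray] = []
    for i in range(arr.n_nodes):  # postorder
        ch = children[i]
        if not ch:
            value[i] = traits[next(tip_iter)]
            continue
        # fold a polytomy pairwise (zero-length virtual edges between folds)
        cur = ch[0]
        cur_val, cur_v = value[cur], vlen[cur]
        for nxt in ch[1:]:
            v1, v2 = cur_v, vlen[nxt]
            if v1 + v2 == 0:
                raise ValueError(
                    "zero-length terminal pair; add a small epsilon to branch lengths"
                )
            contrasts.append((cur_val - value[nxt]) / np.sqrt(v1 + v2))
            cur_val = (cur_val / v1 + value[nxt] / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 else (
                cur_val if v2 > 0 else value[nxt]
            )
            cur_v = v1 * v2 / (v1 + v2)
        value[i] = cur_val
        vlen[i] = vlen[i] + cur_v
    return np.vstack(contrasts)


def allometry_with_pic(
    tree: PhyloTree,
    shapes: np.ndarray,
    log_cs: np.ndarray,
    tip_labels=None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> AllometryFit:
    """Allometry regression on phylogenetic independent contrasts.

    Contrasts of the shape variables are regressed through the origin on
    contrasts of logCS — no centring, since contrasts already have zero
    expectation. The permutation null permutes contrast rows jointly and
    flips their signs at random (contrasts have arbitrary sign), keeping
    the shape contrasts fixed.
    """
    shapes = np.asarray(shapes, float)
    log_cs = np.asarray(log_cs, float)
    cy = independent_contrasts(tree, shapes, tip_labels=tip_labels)
    cz = independent_contrasts(tree, log_cs.reshape(-1, 1), tip_labels=tip_labels)[:, 0]
    if len(cz) == 1:
        warnings.warn(
            "only one contrast (2-taxon tree): the regression is degenerate",
            UserWarning,
            stacklevel=2,
        )
    if np.allclose(cz, 0):
        raise ValueError("all logCS contrasts are zero: predictor has zero variance")
    pct, beta, pred = _percent_predicted(cz, cy)
    rng = np.random.default_rng(seed)
    exceed = 0
    m = len(cz)
    for _ in range(n_permutations):
        zp = rng.permutation(cz) * rng.choice([-1.0, 1.0], size=m)
        pct_p, _, _ = _percent_predicted(zp, cy)
        if pct_p >= pct:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)
    return AllometryFit(
        coefficient_vector=beta,
        percent_predicted=pct,
        p_value=p_value,
        residual_shapes=cy - pred,
        mode="pic",
        n_permutations=n_permutations,
        seed=seed,
    )


def size_correct(shapes: np.ndarray, fit: AllometryFit) -> np.ndarray:
    """Size-corrected shape variables: the regression residuals re-centred
    on the grand mean of the input shapes, so PCA and phylogenetic mapping
    apply to them unchanged."""
    shapes = np.asarray(shapes, float)
    if fit.residual_shapes.shape != shapes.shape:
        raise ValueError(
            f"fit was computed on shapes of shape {fit.residual_shapes.shape}, got {shapes.shape}"
        )
    res = fit.residual_shapes
    return res - res.mean(axis=0) + shapes.mean(axis=0)
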