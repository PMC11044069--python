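"""Generalized Procrustes superimposition with sliding semilandmarks.

The superimposition removes position, scale and orientation: every
configuration is centred, scaled to unit centroid size and rotated to the
running consensus, which is recomputed (and renormalised to unit centroid
size) until it stabilises. Semilandmarks may additionally slide along the
chord direction defined by their neighbouring points, minimising either the
bending energy of the thin-plate spline from the consensus or the squared
Procrustes distance to it; sliding passes are interleaved with full GPA
rounds.

Centroid size is the square root of the summed squared distances of all
points from their centroid — homogeneous of degree one in scale, so log
centroid size is the conventional size variable for allometry. A
compatibility switch (``sqrt=False``) returns the un-rooted sum for
workflows that define centroid size without the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration, SliderTable

__all__ = [
    "ProcrustesAlignment",
    "centroid_size",
    "align_pair",
    "generalized_procrustes",
    "slide_semilandmarks",
    "procrustes_distance",
    "bending_energy_matrix",
]


def centroid_size(config: LandmarkConfiguration | np.ndarray, sqrt: bool = True) -> float:
    """Centroid size of a configuration.

    sqrt(sum of squared distances of every point from the centroid). With
    ``sqrt=False`` the un-rooted sum is returned instead (some software
    reports centroid size without the square root; the rooted form is the
    default because it scales linearly with the configuration).
    """
    coords = config.coordinates if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    ss = float(np.sum(centred**2))
    if ss == 0.0:
        warnings.warn("degenerate configuration: all points coincide", UserWarning, stacklevel=2)
        return 0.0
    return float(np.sqrt(ss)) if sqrt else ss


@dataclass
class PairFit:
    """Record of a pairwise Procrustes fit."""

    aligned: np.ndarray
    rotation: np.ndarray  # 2x2 orthogonal matrix applied to the moving shape
    scale: float  # scale applied to the centred moving shape
    translation: np.ndarray  # centroid of the moving shape that was removed
    residual: float  # sum of squared differences to the centred reference

    @property
    def angle(self) -> float:
        """Recovered rotation angle in radians (positive = counter-clockwise)."""
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))


def align_pair(
    moving: np.ndarray,
    reference: np.ndarray,
    allow_reflection: bool = False,
) -> PairFit:
    """Full Procrustes fit of ``moving`` onto ``reference``.

    Both shapes are centred; ``moving`` is scaled to unit centroid size and
    rotated by the optimal orthogonal transform (from the SVD of the
    cross-covariance) minimising the summed squared distance to the centred
    reference. Reflections are excluded unless ``allow_reflection``;
    anchors are chiral, so the default refuses to mirror them.
    """
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)
    if moving.shape != reference.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {reference.shape}")
    mu_m = moving.mean(axis=0)
    x = moving - mu_m
    y = reference - reference.mean(axis=0)
    cs_m = np.sqrt(np.sum(x**2))
    if cs_m == 0 or np.sum(y**2) == 0:
        raise ValueError("degenerate shape: zero centroid size")
    x = x / cs_m
    u, s, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection or d > 0:
        rot = u @ vt
    else:
        # flip the smallest singular direction to stay in SO(2)
        flip = np.diag([1.0, d])
        rot = u @ flip @ vt
    aligned = x @ rot
    residual = float(np.sum((aligned - y) ** 2))
    return PairFit(aligned=aligned, rotation=rot, scale=1.0 / cs_m, translation=mu_m, residual=residual)


@dataclass
class ProcrustesAlignment:
    """Result of generalized Procrustes analysis.

    ``aligned`` holds the superimposed unit-centroid-size shapes
    ``(n, k, 2)``; ``consensus`` the unit-centroid-size mean shape;
    ``centroid_sizes`` the pre-scaling centroid size of every specimen.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    iterations: int
    converged: bool
    point_roles: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """Aligned shapes as an ``(n, 2k)`` matrix (x1 y1 x2 y2 ...)."""
        return self.aligned.reshape(self.n, -1)

    def procrustes_variance(self) -> float:
        """Total shape variance: sum of squared deviations from the sample
        mean of aligned shapes, divided by n - 1."""
        flat = self.flattened()
        centred = flat - flat.mean(axis=0)
        return float(np.sum(centred**2) / (self.n - 1))

    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)


def _as_coord_arrays(configs: Sequence) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    if isinstance(configs[0], LandmarkConfiguration):
        coords = np.stack([c.coordinates for c in configs])
        ids = [c.specimen_id for c in configs]
        roles = configs[0].point_roles
    else:
        coords = np.stack([np.asarray(c, float) for c in configs])
        ids = [f"specimen_{i + 1}" for i in range(len(configs))]
        roles = None
    return coords, ids, roles


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration] | Sequence[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesAlignment:
    """Iterative generalized Procrustes superimposition.

    All configurations are centred and scaled to unit centroid size; each
    round rotates every configuration to the current consensus, recomputes
    the consensus as the mean of the aligned shapes and renormalises it to
    unit centroid size, until the root-mean-square change of the consensus
    falls below ``tol`` or ``max_iter`` rounds have run.
    """
    coords, ids, roles = _as_coord_arrays(configs)
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("generalized Procrustes needs at least 2 configurations")
    if len({c.shape for c in coords}) != 1:
        raise ValueError("all configurations must share the same number of points")

    css = np.array([centroid_size(c) for c in coords])
    if np.any(css == 0):
        raise ValueError("degenerate configuration with zero centroid size")
    centred = coords - coords.mean(axis=1, keepdims=True)
    shapes = centred / css[:, None, None]

    consensus = shapes[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = align_pair(shapes[i], consensus).aligned
        new_consensus = shapes.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        # remove the neutral rotation mode: pin the new consensus to the old
        new_consensus = align_pair(new_consensus, consensus).aligned
        rms = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if rms < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last RMS change above {tol:g})",
            UserWarning,
            stacklevel=2,
        )
    return ProcrustesAlignment(
        consensus=consensus,
        aligned=shapes,
        centroid_sizes=css,
        specimen_ids=ids,
        iterations=iterations,
        converged=converged,
        point_roles=roles,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two superimposed shapes."""
    return float(np.sqrt(np.sum((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


# ---------------------------------------------------------------------------
# Sliding semilandmarks
# ---------------------------------------------------------------------------


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix L_k of the thin-plate spline on ``reference``.

    The k x k upper-left block of the inverse of the bordered TPS system;
    applying it as a quadratic form to target x (and y) coordinates gives
    the bending energy of the interpolating spline from the reference. It
    annihilates affine transformations of the reference.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = np.where(d > 0, d**2 * np.log(d), 0.0)
    p = np.column_stack([np.ones(k), ref])
    system = np.zeros((k + 3, k + 3))
    system[:k, :k] = kern
    system[:k, k:] = p
    system[k:, :k] = p.T
    inv = np.linalg.inv(system)
    lk = inv[:k, :k]
    return (lk + lk.T) / 2.0


def _sliding_criterion_value(
    shape: np.ndarray, consensus: np.ndarray, criterion: str, lk: np.ndarray | None
) -> float:
    if criterion == "procrustes_distance":
        return float(np.sum((shape - consensus) ** 2))
    assert lk is not None
    return float(shape[:, 0] @ lk @ shape[:, 0] + shape[:, 1] @ lk @ shape[:, 1])


def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    sliders: SliderTable,
    criterion: str,
    lk: np.ndarray | None,
) -> np.ndarray:
    """Slide one specimen's semilandmarks along their chord tangents."""
    k = shape.shape[0]
    triples = sliders.triples
    tangents = np.zeros((len(triples), 2))
    keep = np.ones(len(triples), dtype=bool)
    for j, (b, s, a) in enumerate(triples):
        chord = shape[a] - shape[b]
        norm = np.linalg.norm(chord)
        if norm == 0:
            warnings.warn(
                f"slider {s}: degenerate tangent (before == after); skipped",
                UserWarning,
                stacklevel=3,
            )
            keep[j] = False
            continue
        tangents[j] = chord / norm
    triples = triples[keep]
    tangents = tangents[keep]
    m = len(triples)
    if m == 0:
        return shape
    out = shape.copy()
    if criterion == "procrustes_distance":
        # independent orthogonal projections onto each tangent line
        for (b, s, a), t in zip(triples, tangents):
            out[s] = shape[s] + t * float(t @ (consensus[s] - shape[s]))
        return out
    # bending energy: displacements couple through L_k; solve the joint
    # normal equations  (sum_dim T_dim' L T_dim) d = -sum_dim T_dim' L y_dim
    assert lk is not None
    slider_idx = triples[:, 1]
    tx = np.zeros((k, m))
    ty = np.zeros((k, m))
    tx[slider_idx, np.arange(m)] = tangents[:, 0]
    ty[slider_idx, np.arange(m)] = tangents[:, 1]
    lhs = tx.T @ lk @ tx + ty.T @ lk @ ty
    rhs = -(tx.T @ lk @ shape[:, 0] + ty.T @ lk @ shape[:, 1])
    d = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    out[slider_idx, 0] += tangents[:, 0] * d
    out[slider_idx, 1] += tangents[:, 1] * d
    return out


def slide_semilandmarks(
    alignment: ProcrustesAlignment,
    sliders: SliderTable,
    criterion: str = "bending_energy",
    outer_iter: int = 5,
    tol: float = 1e-8,
) -> ProcrustesAlignment:
    """Interleave semilandmark sliding with Procrustes superimposition.

    Each pass slides every specimen's semilandmarks along the chord
    direction of their (before, after) neighbours, minimising either the
    thin-plate-spline bending energy from the consensus or the squared
    Procrustes distance to it, then re-runs GPA; passes repeat up to
    ``outer_iter`` times or until the consensus stops moving. Sliding is
    unconstrained along the tangent line (no clamping to the chord).
    """
    if criterion not in ("bending_energy", "procrustes_distance"):
        raise ValueError(f"unknown sliding criterion {criterion!r}")
    if len(sliders) == 0:
        return alignment
    current = alignment
    for _ in range(outer_iter):
        consensus = current.consensus
        lk = bending_energy_matrix(consensus) if criterion == "bending_energy" else None
        slid = np.stack(
            [_slide_one(current.aligned[i], consensus, sliders, criterion, lk) for i in range(current.n)]
        )
        refit = generalized_procrustes(list(slid), tol=tol)
        refit = replace(
            refit,
            centroid_sizes=current.centroid_sizes,
            specimen_ids=current.specimen_ids,
            point_roles=current.point_roles,
        )
        shift = np.sqrt(np.mean((refit.consensus - current.consensus) ** 2))
        current = refit
        if shift < tol:
            break
    return current
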