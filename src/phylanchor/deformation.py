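"""Thin-plate-spline deformations and phylomorphospace exports.

A thin-plate spline interpolates the mapping from a reference landmark
configuration to a target exactly, decomposing it into an affine part and
a non-affine part built from the kernel U(r) = r^2 log r. The determinant
of the warp's Jacobian measures local area change: factors above 1 are
expansion, between 0 and 1 contraction; plotted on a diverging colour
scale centred at 1 they make the classic deformation grids. The Jacobian
is evaluated analytically from the spline coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landmark_io import PhyloTree
from .phylo_signal import PhylomorphospaceMap
from .shape_space import ShapeSpace

__all__ = [
    "TpsWarp",
    "DeformationGrid",
    "fit_tps_warp",
    "warp_points",
    "jacobian_grid",
    "plot_deformation_grid",
    "export_phylomorphospace",
]


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r > 0, r**2 * np.log(r), 0.0)


@dataclass
class TpsWarp:
    """An interpolating 2-D thin-plate spline from reference to target.

    ``affine_part`` is 2x3 (columns: constant, x, y coefficients per
    output dimension); ``nonaffine_weights`` is k x 2 (kernel weights per
    output dimension); ``bending_energy`` is the integral bending energy
    W'KW summed over the two output dimensions, zero iff the warp is
    affine.
    """

    reference: np.ndarray
    affine_part: np.ndarray
    nonaffine_weights: np.ndarray
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return warp_points(self, points)


def fit_tps_warp(reference: np.ndarray, target: np.ndarray) -> TpsWarp:
    """Fit the thin-plate spline carrying ``reference`` exactly onto ``target``.

    Solves the standard bordered linear system [[K, P], [P', 0]] with
    kernel U(r) = r^2 log r and P = [1, x, y]; the side conditions make
    the kernel weights orthogonal to affine trends, so the bending energy
    is finite and zero exactly for affine maps.
    """
    ref = np.asarray(reference, float)
    tgt = np.asarray(target, float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference and target must be matching (k, 2) arrays")
    k = ref.shape[0]
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    # collinearity check via rank of [1, x, y]
    p = np.column_stack([np.ones(k), ref])
    if np.linalg.matrix_rank(p) < 3:
        raise ValueError("reference landmarks are collinear: TPS system singular")
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    kern = _tps_kernel(d)
    system = np.zeros((k + 3, k + 3))
    system[:k, :k] = kern
    system[:k, k:] = p
    system[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    sol = np.linalg.solve(system, rhs)
    weights = sol[:k]  # (k, 2)
    affine = sol[k:].T  # (2, 3)
    be = float(np.einsum("id,ij,jd->", weights, kern, weights))
    return TpsWarp(
        reference=ref,
        affine_part=affine,
        nonaffine_weights=weights,
        bending_energy=max(be, 0.0),
    )


def warp_points(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Apply the warp to an (m, 2) array of points."""
    pts = np.atleast_2d(np.asarray(points, float))
    d = np.linalg.norm(pts[:, None, :] - warp.reference[None, :, :], axis=-1)
    u = _tps_kernel(d)  # (m, k)
    p = np.column_stack([np.ones(len(pts)), pts])  # (m, 3)
    return p @ warp.affine_part.T + u @ warp.nonaffine_weights


def warp_jacobian(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Analytic 2x2 Jacobian of the warp at each point, shape (m, 2, 2).

    dU/dx = (x - xi)(2 log r + 1) and likewise in y; the affine part
    contributes its linear coefficients directly.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    diff = pts[:, None, :] - warp.reference[None, :, :]  # (m, k, 2)
    r2 = np.sum(diff**2, axis=-1)  # (m, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(r2 > 0, np.log(r2) + 1.0, 0.0)  # 2 log r + 1
    grad_u = diff * g[..., None]  # (m, k, 2): d U_i / d (x, y)
    jac = np.empty((len(pts), 2, 2))
    # output dim d, input dim e: J[d,e] = A[d, 1+e] + sum_i w[i,d] gradU[i,e]
    jac[:, :, :] = warp.affine_part[None, :, 1:]
    jac += np.einsum("id,mie->mde", warp.nonaffine_weights, grad_u)
    return jac


@dataclass
class DeformationGrid:
    """Jacobian expansion factors of a warp on a rectangular lattice."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    jacobian_factors: np.ndarray  # (res_y, res_x) determinant per grid point

    @property
    def resolution(self) -> tuple[int, int]:
        return self.jacobian_factors.shape


def _default_bbox(reference: np.ndarray, pad: float = 0.10) -> tuple[float, float, float, float]:
    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    span = hi - lo
    lo = lo - pad * span
    hi = hi + pad * span
    return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])


def jacobian_grid(
    warp: TpsWarp,
    resolution: int = 24,
    bbox: tuple[float, float, float, float] | None = None,
) -> DeformationGrid:
    """Evaluate Jacobian determinants of the warp on a regular lattice.

    ``bbox`` is (xmin, ymin, xmax, ymax); by default the reference's
    bounding box padded by 10%. Factors > 1 mean local expansion, < 1
    contraction.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    if bbox is None:
        bbox = _default_bbox(warp.reference)
    xmin, ymin, xmax, ymax = bbox
    xs = np.linspace(xmin, xmax, resolution)
    ys = np.linspace(ymin, ymax, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    jac = warp_jacobian(warp, pts)
    det = np.linalg.det(jac).reshape(resolution, resolution)
    return DeformationGrid(grid_x=gx, grid_y=gy, jacobian_factors=det)


def plot_deformation_grid(
    warp: TpsWarp,
    target: np.ndarray | None = None,
    resolution: int = 24,
    clip: tuple[float, float] = (0.5, 2.0),
    ax=None,
    path: str | Path | None = None,
):
    """Deformation grid with colour-scaled Jacobian expansion factors.

    The reference lattice is warped and drawn, coloured by the local
    Jacobian determinant on a diverging scale centred at 1 (red above 1:
    expansion; blue below: contraction), clipped at ``clip``.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    grid = jacobian_grid(warp, resolution=resolution)
    pts = np.column_stack([grid.grid_x.ravel(), grid.grid_y.ravel()])
    warped = warp_points(warp, pts)
    wx = warped[:, 0].reshape(grid.grid_x.shape)
    wy = warped[:, 1].reshape(grid.grid_y.shape)
    factors = np.clip(grid.jacobian_factors, clip[0], clip[1])

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5, 5))
    norm = TwoSlopeNorm(vmin=clip[0], vcenter=1.0, vmax=clip[1])
    mesh = ax.pcolormesh(wx, wy, factors, cmap="RdBu_r", norm=norm, shading="gouraud")
    for i in range(wx.shape[0]):
        ax.plot(wx[i], wy[i], color="0.4", lw=0.4)
    for j in range(wx.shape[1]):
        ax.plot(wx[:, j], wy[:, j], color="0.4", lw=0.4)
    tgt = target if target is not None else warp_points(warp, warp.reference)
    ax.plot(tgt[:, 0], tgt[:, 1], "k.", ms=3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if own_fig:
        fig.colorbar(mesh, ax=ax, label="Jacobian expansion factor")
        if path is not None:
            fig.savefig(path, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig
    return mesh


def export_phylomorphospace(
    space: ShapeSpace,
    pmap: PhylomorphospaceMap,
    tree: PhyloTree,
    path: str | Path,
    components: tuple[int, int] = (0, 1),
    write_figure: bool = True,
):
    """Write phylomorphospace plot (SVG) and companion CSVs.

    Tips are plotted at their component scores, internal nodes at their
    squared-change-parsimony estimates, and every tree edge as a straight
    segment. The node coordinates and edge list are also written as CSV
    (`<path>_nodes.csv`, `<path>_edges.csv`) so the plot can be
    regenerated without re-running the analysis. With one-dimensional
    data the plot falls back to a gradient along that axis (taxa spread
    on the y axis for legibility).
    """
    import pandas as pd

    path = Path(path)
    coords = pmap.node_coordinates
    d = coords.shape[1]
    n_nodes = coords.shape[0]
    is_tip = np.zeros(n_nodes, dtype=bool)
    is_tip[pmap.tip_index] = True
    labels = [""] * n_nodes
    for idx, lbl in zip(pmap.tip_index, pmap.tip_labels):
        labels[idx] = lbl

    nodes_df = pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "is_tip": is_tip,
            "label": labels,
            **{f"axis{j + 1}": coords[:, j] for j in range(d)},
        }
    )
    edges_df = pd.DataFrame(pmap.edges(), columns=["parent", "child"])
    nodes_path = path.with_name(path.stem + "_nodes.csv")
    edges_path = path.with_name(path.stem + "_edges.csv")
    nodes_df.to_csv(nodes_path, index=False)
    edges_df.to_csv(edges_path, index=False)

    if write_figure:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        if d >= 2:
            cx, cy = components
            xy = coords[:, [cx, cy]]
            ax.set_xlabel(f"PC{cx + 1}")
            ax.set_ylabel(f"PC{cy + 1}")
        else:
            # 1-D gradient: spread nodes vertically by index for visibility
            xy = np.column_stack([coords[:, 0], np.arange(n_nodes, dtype=float)])
            ax.set_xlabel("axis 1")
            ax.set_yticks([])
        for p, c in pmap.edges():
            ax.plot(xy[[p, c], 0], xy[[p, c], 1], "-", color="0.6", lw=1)
        ax.plot(xy[~is_tip, 0], xy[~is_tip, 1], "o", color="0.5", ms=4, label="ancestral node")
        ax.plot(xy[is_tip, 0], xy[is_tip, 1], "o", color="tab:red", ms=6, label="species")
        for idx in pmap.tip_index:
            ax.annotate(labels[idx], xy[idx], fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
    return nodes_df, edges_df
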