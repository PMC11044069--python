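"""Synthetic anchor-like landmark datasets with controlled signal.

The generator emulates the structure of the real data the pipeline
consumes: one 83-point configuration (5 fixed landmarks + 5 curve groups
of semilandmarks) per species, a rooted ultrametric 10-taxon tree, slider
triples from curve adjacency, and a truth record of the generating
parameters. Shape variation is produced in an explicit deviation basis —
free motion of the fixed landmarks plus smooth outline-normal motion of
the semilandmarks, orthogonal to the similarity transforms (translation,
rotation, scaling) of the template — as the sum of a Brownian-motion
component on the tree, an i.i.d. non-phylogenetic component, and an
allometric deformation proportional to log centroid size; each
configuration is then rigidly perturbed (random rotation, translation and
scale) before being written as raw digitization coordinates, so a correct
superimposition must undo the perturbation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .landmark_io import (
    LandmarkConfiguration,
    PhyloTree,
    SliderTable,
    auto_sliders,
    write_newick,
    write_sliders,
    write_tps,
)

__all__ = [
    "SyntheticSpec",
    "simulate_tree",
    "simulate_bm_traits",
    "make_template_anchor",
    "simulate_anchor_configs",
    "simulate_anchor_dataset",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic anchor dataset.

    Defaults follow the structure of the study system: 10 species, one
    configuration each, 83 points per anchor (5 fixed landmarks plus 5
    semilandmark groups of 6-29 points), Brownian shape evolution on an
    ultrametric tree. ``allometry_fraction`` is the share of total shape
    variation attributable to logCS (calibrated exactly per dataset);
    ``noise_fraction`` the non-phylogenetic share of the remaining shape
    variance. ``bm_rate`` is the Brownian variance per unit branch length
    per tangent dimension; sizes are drawn log-uniformly from
    ``size_range``.
    """

    n_taxa: int = 10
    n_fixed: int = 5
    slm_group_sizes: tuple[int, ...] = (29, 20, 12, 11, 6)
    bm_rate: float = 1e-4
    allometry_fraction: float = 0.0
    noise_fraction: float = 0.0
    size_range: tuple[float, float] = (150.0, 600.0)
    tree_mode: str = "yule"
    anchor_class: str = "unspecified"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allometry_fraction <= 1.0:
            raise ValueError("allometry_fraction must be in [0, 1]")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.allometry_fraction >= 1.0 and self.noise_fraction > 0:
            raise ValueError("allometry_fraction = 1 leaves no variance for other components")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if min(self.size_range) <= 0 or self.size_range[0] >= self.size_range[1]:
            raise ValueError("size_range must be positive and increasing")

    @property
    def total_points(self) -> int:
        return self.n_fixed + sum(self.slm_group_sizes)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _labels(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def _tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree(
        dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    )


class _SimNode:
    """Minimal mutable node for tree construction."""

    __slots__ = ("children", "label", "born", "split", "height")

    def __init__(self, label: str | None = None, born: float = 0.0):
        self.children: list[_SimNode] = []
        self.label = label
        self.born = born
        self.split: float | None = None
        self.height = 0.0

    def newick(self, parent_end: float | None, horizon: float) -> str:
        """Render with edge lengths from split/horizon times."""
        end = self.split if self.children else horizon
        if self.children:
            inner = ",".join(c.newick(end, horizon) for c in self.children)
            body = f"({inner})"
        else:
            body = self.label or ""
        if parent_end is None:
            return body
        return f"{body}:{end - parent_end:.12g}"


def _balanced_tree(labels: list[str]) -> str:
    """As-balanced-as-possible topology, ultrametric with total depth 1.

    Internal node heights are one unit per level (leaf = 0), rescaled so
    the root sits at depth 1; edges span the height difference.
    """

    def build(lbls: list[str]) -> _SimNode:
        node = _SimNode()
        if len(lbls) == 1:
            node.label = lbls[0]
            return node
        half = (len(lbls) + 1) // 2
        node.children = [build(lbls[:half]), build(lbls[half:])]
        node.height = max(c.height for c in node.children) + 1.0
        return node

    root = build(labels)
    scale = root.height

    def render(node: _SimNode, parent_height: float | None) -> str:
        h = node.height / scale
        if node.children:
            body = "(" + ",".join(render(c, h) for c in node.children) + ")"
        else:
            body = node.label
        if parent_height is None:
            return body
        return f"{body}:{parent_height - h:.12g}"

    return render(root, None) + ";"


def _ladder_tree(labels: list[str]) -> str:
    """Pectinate (caterpillar) topology, ultrametric with total depth 1."""
    n = len(labels)
    step = 1.0 / (n - 1)
    sub = f"({labels[-1]}:{step:.12g},{labels[-2]}:{step:.12g})"
    h = step
    for i in range(n - 3, -1, -1):
        join = h + step
        sub = f"({sub}:{step:.12g},{labels[i]}:{join:.12g})"
        h = join
    return sub + ";"


def simulate_tree(
    n_taxa: int, mode: str = "yule", seed: int | None = None, birth_rate: float = 1.0
) -> PhyloTree:
    """Simulate a rooted ultrametric tree with positive branch lengths.

    Modes: ``star`` (one internal node, unit pendant edges), ``balanced``
    (even splits, total depth 1), ``ladder`` (pectinate, total depth 1),
    ``yule`` (pure birth: exponential waiting times at rate
    ``birth_rate`` x lineage count, a uniformly chosen lineage splits at
    each event, and all surviving tips extend to the present, so the tree
    is ultrametric). Deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    labels = _labels(n_taxa)
    if mode == "star":
        inner = ",".join(f"{lbl}:1" for lbl in labels)
        return _tree_from_newick(f"({inner});")
    if mode == "balanced":
        return _tree_from_newick(_balanced_tree(labels))
    if mode == "ladder":
        return _tree_from_newick(_ladder_tree(labels))
    if mode == "yule":
        rng = np.random.default_rng(seed)
        root = _SimNode(born=0.0)
        root.split = 0.0  # the root splits immediately: no stem edge
        c1, c2 = _SimNode(born=0.0), _SimNode(born=0.0)
        root.children = [c1, c2]
        active = [c1, c2]
        t = 0.0
        while len(active) < n_taxa:
            k = len(active)
            t += rng.exponential(1.0 / (birth_rate * k))
            node = active.pop(int(rng.integers(k)))
            node.split = t
            kids = [_SimNode(born=t), _SimNode(born=t)]
            node.children = kids
            active.extend(kids)
        horizon = t + rng.exponential(1.0 / (birth_rate * n_taxa))
        for lbl, node in zip(labels, active):
            node.label = lbl
        return _tree_from_newick(root.newick(None, horizon) + ";")
    raise ValueError(f"unknown tree mode {mode!r}")


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------


def simulate_bm_traits(
    tree: PhyloTree, p: int, rate: float = 1.0, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Independent Brownian motion per dimension on the tree.

    The root sits at 0; each edge adds a zero-mean normal increment with
    variance ``rate`` x edge length. Returns tip values (n, p) in the
    order of ``tree.as_arrays().tip_labels`` — the tip covariance per
    dimension is ``rate`` x the Brownian covariance of the tree.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = tree.as_arrays()
    values = np.zeros((arr.n_nodes, p))
    for i in range(arr.n_nodes - 1, -1, -1):  # preorder
        par = arr.parent[i]
        if par < 0:
            continue
        sd = np.sqrt(rate * arr.length[i])
        values[i] = values[par] + rng.normal(0.0, 1.0, size=p) * sd
    return values[arr.tip_indices]


# ---------------------------------------------------------------------------
# Template anchor
# ---------------------------------------------------------------------------


def _arc_points(p0: np.ndarray, p1: np.ndarray, bulge: float, m: int) -> np.ndarray:
    """``m`` interior points on the circular arc from p0 to p1.

    ``bulge`` is the sagitta as a fraction of the chord (sign sets the
    side). Points are placed at equal angular steps, so consecutive chord
    lengths within the arc are equal. ``bulge == 0`` degenerates to equal
    steps on the straight chord.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if m <= 0:
        return np.empty((0, 2))
    if abs(bulge) < 1e-12:
        ts = np.linspace(0, 1, m + 2)[1:-1]
        return p0 + np.outer(ts, p1 - p0)
    chord = np.linalg.norm(p1 - p0)
    sag = bulge * chord
    radius = (chord**2 / 4 + sag**2) / (2 * abs(sag))
    mid = (p0 + p1) / 2
    normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]]) / chord
    center = mid + np.sign(sag) * (radius - abs(sag)) * (-normal)
    a0 = np.arctan2(p0[1] - center[1], p0[0] - center[0])
    a1 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
    # choose the arc passing through the bulge side (the minor arc)
    sweep = (a1 - a0 + np.pi) % (2 * np.pi) - np.pi
    angles = a0 + sweep * np.linspace(0, 1, m + 2)[1:-1]
    return center + radius * np.column_stack([np.cos(angles), np.sin(angles)])


# fixed landmark geometry of the template hook (unit-scale sketch):
# inner-root tip, outer-root tip, root/shaft junction, shaft midpoint, point tip
_TEMPLATE_LMS = np.array(
    [
        [-0.45, 0.95],  # inner-root tip
        [0.40, 1.00],  # outer-root tip
        [0.05, 0.55],  # root/shaft junction
        [-0.05, 0.00],  # shaft midpoint (outline waypoint)
        [0.55, -0.70],  # point tip (recurved hook apex)
    ]
)
# arcs run between consecutive landmarks, closing the outline; bulges give
# the hook its curvature (sign = side of the chord)
_TEMPLATE_BULGES = (0.12, -0.18, 0.10, 0.25, -0.30)


def make_template_anchor(spec: SyntheticSpec | None = None) -> tuple[LandmarkConfiguration, SliderTable]:
    """Anchor-like template outline with fixed landmarks and semilandmarks.

    Five fixed landmarks at biologically analogous positions (inner-root
    tip, outer-root tip, root/shaft junction, shaft midpoint, point tip)
    joined by circular arcs carrying the semilandmark groups; within each
    group points sit at equal angular steps, so consecutive chords are
    equal. Slider triples follow arc adjacency.
    """
    if spec is None:
        spec = SyntheticSpec()
    if spec.n_fixed != len(_TEMPLATE_LMS):
        raise ValueError(f"template supports exactly {len(_TEMPLATE_LMS)} fixed landmarks")
    n_groups = len(spec.slm_group_sizes)
    lms = _TEMPLATE_LMS
    pairs = [(i, (i + 1) % spec.n_fixed) for i in range(spec.n_fixed)]
    if n_groups > len(pairs):
        raise ValueError("more semilandmark groups than landmark pairs")
    bulges = (_TEMPLATE_BULGES * ((n_groups // len(_TEMPLATE_BULGES)) + 1))[:n_groups]
    groups = [
        _arc_points(lms[a], lms[b], bulges[g], spec.slm_group_sizes[g])
        for g, (a, b) in enumerate(pairs[:n_groups])
    ]
    coords = np.vstack([lms] + groups)
    roles = np.array(
        ["fixed"] * spec.n_fixed + ["semilandmark"] * sum(spec.slm_group_sizes), dtype=object
    )
    config = LandmarkConfiguration(
        specimen_id="template",
        coordinates=coords,
        point_roles=roles,
        anchor_class=spec.anchor_class,
        semilandmark_groups=tuple(spec.slm_group_sizes),
    )
    # sliders: within-group neighbours; arc ends slide against their fixed
    # landmark endpoints, which coordinate order does not make adjacent, so
    # build them explicitly from the arc structure
    triples: list[tuple[int, int, int]] = []
    start = spec.n_fixed
    for g, (a, b) in enumerate(pairs[:n_groups]):
        size = spec.slm_group_sizes[g]
        for j in range(size):
            idx = start + j
            before = idx - 1 if j > 0 else a
            after = idx + 1 if j < size - 1 else b
            triples.append((before, idx, after))
        start += size
    return config, SliderTable(np.array(triples, dtype=int))


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Generating parameters and latent values of a synthetic dataset."""

    spec: SyntheticSpec
    centroid_sizes: np.ndarray
    log_cs_centered: np.ndarray
    allometry_scale: float
    tree_newick: str
    taxa: list[str]
    tangent_bm: np.ndarray = field(repr=False, default=None)
    tangent_noise: np.ndarray = field(repr=False, default=None)
    tangent_dev: np.ndarray = field(repr=False, default=None)  # final deviations incl. allometry

    def to_json(self) -> str:
        d = {
            "spec": {
                "n_taxa": self.spec.n_taxa,
                "n_fixed": self.spec.n_fixed,
                "slm_group_sizes": list(self.spec.slm_group_sizes),
                "bm_rate": self.spec.bm_rate,
                "allometry_fraction": self.spec.allometry_fraction,
                "noise_fraction": self.spec.noise_fraction,
                "size_range": list(self.spec.size_range),
                "tree_mode": self.spec.tree_mode,
                "anchor_class": self.spec.anchor_class,
                "seed": self.spec.seed,
            },
            "taxa": self.taxa,
            "centroid_sizes": self.centroid_sizes.tolist(),
            "allometry_scale": self.allometry_scale,
            "tree_newick": self.tree_newick,
        }
        return json.dumps(d, indent=2)


def simulate_anchor_configs(
    spec: SyntheticSpec,
) -> tuple[list[LandmarkConfiguration], SliderTable, PhyloTree, SyntheticTruth]:
    """Generate one rigidly perturbed configuration per taxon, in memory.

    Shape deviations are drawn in the template's shape-deviation basis —
    the span of free fixed-landmark motions and outline-normal
    semilandmark motions, orthogonal to the similarity transforms of the
    template. Restricting semilandmark motion to the outline normal
    mirrors what semilandmarks measure: their position along the curve is
    arbitrary (and is what sliding removes), so putting generated signal
    there would be unrecoverable by construction. Deviations combine a
    Brownian component on the simulated tree and an i.i.d. component,
    rescaled so their realized variances split
    (1 - noise_fraction) : noise_fraction; an allometric deformation
    along a fixed smooth direction is added with a per-dataset scale
    solved in closed form so that the through-the-origin regression of
    the generated data on centred logCS explains exactly
    ``allometry_fraction`` of their total variance. Each configuration is
    then randomly rotated, translated and scaled to its target centroid
    size.
    """
    rng = np.random.default_rng(spec.seed)
    template, sliders = make_template_anchor(spec)
    k = template.k
    tmpl_centred = template.coordinates - template.coordinates.mean(axis=0)
    tmpl_unit = tmpl_centred / np.sqrt(np.sum(tmpl_centred**2))
    flat0 = tmpl_unit.ravel()
    basis = _deviation_basis(tmpl_unit, template, sliders)
    q = basis.shape[1]

    tree = simulate_tree(spec.n_taxa, mode=spec.tree_mode, seed=int(rng.integers(2**31 - 1)))
    taxa = tree.as_arrays().tip_labels
    n = spec.n_taxa

    # non-allometric tangent components, rescaled to realized shares
    bm = simulate_bm_traits(tree, p=q, rate=spec.bm_rate, rng=rng)
    noise = rng.normal(0.0, np.sqrt(spec.bm_rate), size=(n, q))
    v_bm = float(np.sum((bm - bm.mean(axis=0)) ** 2))
    v_noise = float(np.sum((noise - noise.mean(axis=0)) ** 2))
    nf = spec.noise_fraction
    if nf == 0.0:
        noise[:] = 0.0
    elif nf == 1.0:
        bm[:] = 0.0
        if v_noise > 0:
            noise *= np.sqrt(v_bm / v_noise) if v_bm > 0 else 1.0
    else:
        if v_bm > 0 and v_noise > 0:
            noise *= np.sqrt((v_bm * nf / (1.0 - nf)) / v_noise)
    dev = bm + noise

    # sizes and the allometric component
    lo, hi = spec.size_range
    cs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    z = np.log(cs) - np.log(cs).mean()
    direction = _smooth_tangent_direction(basis, k)
    scale_allo = 0.0
    if spec.allometry_fraction > 0:
        # make the non-allometric deviations exactly size-orthogonal, so the
        # allometric share is controlled by one closed-form scale
        zz = float(z @ z)
        dev = dev - np.outer(z, (z @ (dev - dev.mean(axis=0))) / zz)
        scale_allo = _calibrate_allometry(dev, z, spec.allometry_fraction)
    dev = dev + np.outer(z * scale_allo, direction)

    configs: list[LandmarkConfiguration] = []
    for i, taxon in enumerate(taxa):
        shape_flat = flat0 + basis @ dev[i]
        shape = shape_flat.reshape(k, 2)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = rng.uniform(-100, 100, size=2)
        shape = shape - shape.mean(axis=0)
        shape = shape / np.sqrt(np.sum(shape**2))  # exact unit CS after the deviation
        coords = (shape @ rot.T) * cs[i] + shift
        configs.append(
            LandmarkConfiguration(
                specimen_id=taxon,
                coordinates=coords,
                point_roles=template.point_roles.copy(),
                anchor_class=spec.anchor_class,
                semilandmark_groups=template.semilandmark_groups,
            )
        )
    truth = SyntheticTruth(
        spec=spec,
        centroid_sizes=cs,
        log_cs_centered=z,
        allometry_scale=scale_allo,
        tree_newick=tree.newick(),
        taxa=list(taxa),
        tangent_bm=bm,
        tangent_noise=noise,
        tangent_dev=dev,
    )
    return configs, sliders, tree, truth


def _deviation_basis(
    shape: np.ndarray,
    template: LandmarkConfiguration,
    sliders: SliderTable,
    modes_per_arc: int = 4,
) -> np.ndarray:
    """Orthonormal basis (2k x q) of admissible shape deviations.

    Columns span free (x, y) motions of the fixed landmarks plus smooth
    outline-normal motions of the semilandmarks — per arc, the first
    ``modes_per_arc`` cosine profiles applied along the local normals
    (perpendicular to each slider's neighbour chord) — with the four
    similarity directions (translation x/y, rotation, scaling) projected
    out. Smoothness matters twice over: interspecific shape differences
    are smooth deformations, and rough per-point deviations would be
    dominated by exactly the arbitrary along-curve variation that sliding
    is designed to remove.
    """
    k = shape.shape[0]
    normals = {}
    for b, s, a in sliders.triples:
        chord = shape[a] - shape[b]
        normal = np.array([-chord[1], chord[0]])
        normals[int(s)] = normal / np.linalg.norm(normal)
    dirs: list[np.ndarray] = []
    for i in np.where(template.point_roles == "fixed")[0]:
        for axis in range(2):
            v = np.zeros(2 * k)
            v[2 * i + axis] = 1.0
            dirs.append(v)
    start = template.n_fixed
    for size in template.semilandmark_groups:
        idx = np.arange(start, start + size)
        t = (np.arange(size) + 1.0) / (size + 1.0)
        for j in range(min(modes_per_arc, size)):
            profile = np.cos(j * np.pi * t)
            v = np.zeros(2 * k)
            for p, w in zip(idx, profile):
                v[2 * p : 2 * p + 2] = w * normals[int(p)]
            dirs.append(v)
        start += size
    d = np.column_stack(dirs)
    # similarity directions at the (centred, unit-size) template
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-shape[:, 1], shape[:, 0]]).ravel()
    scale = shape.ravel()
    sim = np.linalg.qr(np.column_stack([tx, ty, rot, scale]))[0]
    d = d - sim @ (sim.T @ d)
    u, s_vals, _ = np.linalg.svd(d, full_matrices=False)
    rank = int(np.sum(s_vals > 1e-10 * s_vals[0]))
    return u[:, :rank]


def _smooth_tangent_direction(basis: np.ndarray, k: int) -> np.ndarray:
    """A fixed, smooth unit deformation direction in the tangent space.

    A low-frequency bending pattern (quadratic in point index, acting on
    y), projected into the tangent basis — deterministic so the allometric
    axis is comparable across datasets.
    """
    t = np.linspace(-1, 1, k)
    raw = np.zeros(2 * k)
    raw[1::2] = t**2 - (t**2).mean()
    raw[0::2] = 0.3 * t
    coef = basis.T @ raw  # tangent-basis coordinates of the pattern
    return coef / np.linalg.norm(coef)


def _calibrate_allometry(dev: np.ndarray, z: np.ndarray, fraction: float) -> float:
    """Scale s so regressing (dev + s z v') on z explains ``fraction``.

    Requires ``dev`` to be size-orthogonal (its centred columns orthogonal
    to z), which the generator arranges: the predicted sum of squares is
    then exactly s^2 z'z, so s = sqrt(f/(1-f) * ||dev_c||^2 / z'z).
    """
    dev_c = dev - dev.mean(axis=0)
    zz = float(z @ z)
    b2 = float(np.sum(dev_c**2))
    return float(np.sqrt(fraction / (1.0 - fraction) * b2 / zz))


def simulate_anchor_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write a complete synthetic dataset: TPS + sliders + Newick + truth JSON.

    Returns a manifest of the written paths. Byte-identical output for
    identical specs (including seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs, sliders, tree, truth = simulate_anchor_configs(spec)
    tps_path = out / "anchors.tps"
    slider_path = out / "sliders.txt"
    tree_path = out / "tree.nwk"
    truth_path = out / "truth.json"
    write_tps(configs, tps_path)
    write_sliders(sliders, slider_path)
    write_newick(tree, tree_path)
    truth_path.write_text(truth.to_json() + "\n")
    return {
        "tps": str(tps_path),
        "sliders": str(slider_path),
        "tree": str(tree_path),
        "truth": str(truth_path),
    }
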