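"""Readers and writers for the file formats the pipeline touches.

Landmark configurations travel as TPS files (the dialect written by tpsDig:
``LM=`` blocks for fixed landmarks, optional ``CURVES=``/``POINTS=`` blocks
for semilandmark curves, plus ``ID=``, ``IMAGE=`` and ``SCALE=`` lines).
Slider definitions are whitespace- or comma-separated before/slider/after
index triples, and phylogenies are Newick trees parsed with dendropy.

Internally everything is 0-based; readers accept ``index_base`` to absorb
1-based files. Stored y coordinates are used as-is (no implicit flip), and
``SCALE=`` is recorded but only applied to coordinates on explicit request,
because TPS dialects disagree on whether it is pre-applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "SliderTable",
    "PhyloTree",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_sliders",
    "write_sliders",
    "auto_sliders",
    "read_newick",
    "write_newick",
]


class TPSParseError(ValueError):
    """Raised when a TPS or slider file cannot be parsed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's 2-D landmark configuration.

    Parameters
    ----------
    specimen_id:
        Identifier, typically a species name matching a tree tip label.
    coordinates:
        ``(k, 2)`` array of ``(x, y)`` points in digitization units. The
        fixed landmarks come first, followed by the semilandmark curve
        groups in file order.
    point_roles:
        Length-``k`` array of strings, each ``"fixed"`` or
        ``"semilandmark"``.
    anchor_class:
        ``"ventral"``, ``"dorsal"`` or ``"unspecified"``.
    scale:
        Optional physical units per digitization unit (``SCALE=`` line);
        never applied implicitly.
    semilandmark_groups:
        Sizes of the consecutive semilandmark curve groups (the
        ``POINTS=`` blocks); their sum equals the number of semilandmark
        roles.
    """

    specimen_id: str
    coordinates: np.ndarray
    point_roles: np.ndarray
    anchor_class: str = "unspecified"
    scale: float | None = None
    semilandmark_groups: tuple[int, ...] = ()
    image: str | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be a (k, 2) array")
        k = self.coordinates.shape[0]
        if k < 3:
            raise ValueError(f"need at least 3 points, got {k}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        self.point_roles = np.asarray(self.point_roles, dtype=object)
        if self.point_roles.shape != (k,):
            raise ValueError("point_roles length must equal number of points")
        bad = set(self.point_roles) - {"fixed", "semilandmark"}
        if bad:
            raise ValueError(f"unknown point roles: {sorted(bad)}")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.anchor_class not in ("ventral", "dorsal", "unspecified"):
            raise ValueError(f"unknown anchor_class {self.anchor_class!r}")
        n_semi = int(np.sum(self.point_roles == "semilandmark"))
        if not self.semilandmark_groups and n_semi:
            self.semilandmark_groups = (n_semi,)
        if sum(self.semilandmark_groups) != n_semi:
            raise ValueError("semilandmark_groups must sum to the number of semilandmarks")

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_fixed(self) -> int:
        return int(np.sum(self.point_roles == "fixed"))

    def scaled_coordinates(self) -> np.ndarray:
        """Coordinates with the ``SCALE=`` factor applied (if present)."""
        if self.scale is None:
            return self.coordinates.copy()
        return self.coordinates * self.scale


@dataclass
class SliderTable:
    """Before/slider/after index triples defining semilandmark tangents.

    Indices are 0-based positions into a landmark configuration. Each
    slider index may appear at most once; within a triple all three
    indices are distinct.
    """

    triples: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=int).reshape(-1, 3)
        sliders = self.triples[:, 1]
        if len(np.unique(sliders)) != len(sliders):
            dup = sliders[np.where(np.bincount(sliders) > 1)[0][0]] if len(sliders) else None
            raise ValueError(f"duplicate slider index {dup}")
        for row in self.triples:
            if len(set(row.tolist())) != 3:
                raise ValueError(f"indices within a triple must be distinct: {row.tolist()}")

    def __len__(self) -> int:
        return self.triples.shape[0]

    def validate_against(self, config: LandmarkConfiguration) -> None:
        """Check all indices are in range and slider points are semilandmarks."""
        if len(self) == 0:
            return
        if self.triples.min() < 0 or self.triples.max() >= config.k:
            raise ValueError("slider indices out of range for configuration")
        roles = config.point_roles[self.triples[:, 1]]
        if np.any(roles != "semilandmark"):
            bad = self.triples[roles != "semilandmark", 1].tolist()
            raise ValueError(f"slider indices must be semilandmarks: {bad}")


class PhyloTree:
    """A rooted phylogeny with (optional) branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` adding the bookkeeping the
    comparative methods need: a fixed tip-label order, arrays of parent
    pointers and edge lengths, and an explicit, never-silent fallback to
    unit branch lengths when the input tree carries none.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            seen: set[str] = set()
            dup = next(t for t in tips if t in seen or seen.add(t))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate tip label {dup!r}")
        self.tip_labels: list[str] = tips
        lengths = [e.length for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        self.has_branch_lengths = all(l is not None for l in lengths) and len(lengths) > 0
        if any(l is not None and l < 0 for l in lengths):
            raise ValueError("negative branch length in tree")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def edge_lengths_or_default(self, default: float = 1.0) -> "PhyloTree":
        """Return a copy with unit branch lengths if the tree has none.

        The substitution is loud: a warning is emitted, because mapped tree
        lengths and covariances then carry arbitrary units.
        """
        if self.has_branch_lengths:
            return self
        warnings.warn(
            "tree has no branch lengths; substituting unit lengths on every edge",
            UserWarning,
            stacklevel=2,
        )
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = default
        return PhyloTree(clone)

    def as_arrays(self) -> "TreeArrays":
        """Flatten to postorder arrays for numeric work (requires lengths)."""
        if not self.has_branch_lengths:
            raise ValueError(
                "tree has no branch lengths; call edge_lengths_or_default() first"
            )
        return TreeArrays.from_dendropy(self._tree)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips}, branch_lengths={self.has_branch_lengths})"


@dataclass
class TreeArrays:
    """Postorder array view of a rooted tree.

    ``parent[i]`` is the index of node i's parent (-1 at the root),
    ``length[i]`` the length of the edge above node i, ``is_tip[i]`` flags
    leaves, and ``tip_labels`` names tips in index order. Node indices are
    assigned in postorder, so the root is the last index.
    """

    parent: np.ndarray
    length: np.ndarray
    is_tip: np.ndarray
    tip_labels: list[str]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeArrays":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        length = np.zeros(n)
        is_tip = np.zeros(n, dtype=bool)
        tip_labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = float(nd.edge.length if nd.edge.length is not None else 0.0)
            if nd.is_leaf():
                is_tip[i] = True
                tip_labels.append(nd.taxon.label)
        return cls(parent=parent, length=length, is_tip=is_tip, tip_labels=tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_indices(self) -> np.ndarray:
        return np.where(self.is_tip)[0]

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def _parse_point(line: str, lineno: int) -> tuple[float, float]:
    parts = line.replace(",", " ").split()
    if len(parts) != 2:
        raise TPSParseError(f"line {lineno}: expected 'x y', got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TPSParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    One configuration per ``LM=`` record. Curve points from
    ``CURVES=``/``POINTS=`` blocks are appended after the fixed landmarks
    and flagged as semilandmarks; coordinate order is preserved and y is
    kept exactly as stored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n = 0, len(lines)
    record_no = 0
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"line {i + 1}: expected LM= record start, got {line!r}")
        record_no += 1
        try:
            n_fixed = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"line {i + 1}: bad LM= count {line!r}") from exc
        i += 1
        fixed_pts: list[tuple[float, float]] = []
        while len(fixed_pts) < n_fixed:
            if i >= n or "=" in lines[i]:
                raise TPSParseError(
                    f"record {record_no}: LM={n_fixed} but only "
                    f"{len(fixed_pts)} coordinate lines found"
                )
            if lines[i].strip():
                fixed_pts.append(_parse_point(lines[i].strip(), i + 1))
            i += 1
        groups: list[list[tuple[float, float]]] = []
        specimen_id = f"specimen_{record_no}"
        image: str | None = None
        scale: float | None = None
        n_curves_declared: int | None = None
        while i < n:
            raw = lines[i].strip()
            if not raw:
                i += 1
                continue
            upper = raw.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("CURVES="):
                n_curves_declared = int(raw.split("=", 1)[1])
                i += 1
            elif upper.startswith("POINTS="):
                m = int(raw.split("=", 1)[1])
                i += 1
                pts: list[tuple[float, float]] = []
                while len(pts) < m:
                    if i >= n or "=" in lines[i]:
                        raise TPSParseError(
                            f"record {record_no}: POINTS={m} but only "
                            f"{len(pts)} coordinate lines found"
                        )
                    if lines[i].strip():
                        pts.append(_parse_point(lines[i].strip(), i + 1))
                    i += 1
                groups.append(pts)
            elif upper.startswith("ID="):
                specimen_id = raw.split("=", 1)[1].strip()
                i += 1
            elif upper.startswith("IMAGE="):
                image = raw.split("=", 1)[1].strip()
                i += 1
            elif upper.startswith("SCALE="):
                scale = float(raw.split("=", 1)[1])
                i += 1
            else:
                raise TPSParseError(f"line {i + 1}: unexpected content {raw!r}")
        if n_curves_declared is not None and n_curves_declared != len(groups):
            raise TPSParseError(
                f"record {record_no}: CURVES={n_curves_declared} but "
                f"{len(groups)} POINTS blocks found"
            )
        coords = np.array(fixed_pts + [p for g in groups for p in g], dtype=float)
        roles = np.array(
            ["fixed"] * n_fixed + ["semilandmark"] * sum(len(g) for g in groups),
            dtype=object,
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                coordinates=coords,
                point_roles=roles,
                scale=scale,
                image=image,
                semilandmark_groups=tuple(len(g) for g in groups),
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file readable by :func:`read_tps`."""
    if not configs:
        raise ValueError("write_tps requires at least one configuration")
    buf = io.StringIO()
    for cfg in configs:
        n_fixed = cfg.n_fixed
        buf.write(f"LM={n_fixed}\n")
        for x, y in cfg.coordinates[:n_fixed]:
            buf.write(f"{x:.12g} {y:.12g}\n")
        if cfg.semilandmark_groups:
            buf.write(f"CURVES={len(cfg.semilandmark_groups)}\n")
            start = n_fixed
            for size in cfg.semilandmark_groups:
                buf.write(f"POINTS={size}\n")
                for x, y in cfg.coordinates[start : start + size]:
                    buf.write(f"{x:.12g} {y:.12g}\n")
                start += size
        if cfg.image is not None:
            buf.write(f"IMAGE={cfg.image}\n")
        buf.write(f"ID={cfg.specimen_id}\n")
        if cfg.scale is not None:
            buf.write(f"SCALE={cfg.scale:.12g}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Sliders
# ---------------------------------------------------------------------------


def read_sliders(path: str | Path, index_base: int = 0) -> SliderTable:
    """Read before/slider/after triples, one per line.

    Values may be separated by whitespace or commas; a non-numeric first
    line is treated as a header. ``index_base`` (0 or 1) states the file's
    indexing convention; the returned table is always 0-based.
    """
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    lines = Path(path).read_text().splitlines()
    triples: list[list[int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [int(p) for p in parts]
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise TPSParseError(f"line {lineno}: non-integer slider entry {line!r}")
        if len(vals) != 3:
            raise TPSParseError(f"line {lineno}: expected 3 indices, got {len(vals)}")
        converted = [v - index_base for v in vals]
        if min(converted) < 0:
            raise TPSParseError(f"line {lineno}: index out of range after base conversion")
        triples.append(converted)
    try:
        return SliderTable(np.array(triples, dtype=int).reshape(-1, 3))
    except ValueError as exc:
        raise TPSParseError(str(exc)) from exc


def write_sliders(table: SliderTable, path: str | Path, index_base: int = 0) -> None:
    """Write a slider table as before/slider/after lines."""
    lines = ["before slider after"]
    for b, s, a in table.triples:
        lines.append(f"{b + index_base} {s + index_base} {a + index_base}")
    Path(path).write_text("\n".join(lines) + "\n")


def auto_sliders(config: LandmarkConfiguration) -> SliderTable:
    """Derive slider triples from the curve-group structure of a configuration.

    Within each semilandmark group, consecutive points slide against their
    immediate neighbours; the group's first and last semilandmarks use the
    flanking points in coordinate order (normally the adjacent fixed
    landmarks when curves run between landmark pairs, otherwise the
    neighbouring curve points).
    """
    triples: list[tuple[int, int, int]] = []
    start = config.n_fixed
    for size in config.semilandmark_groups:
        for j in range(size):
            idx = start + j
            before = idx - 1 if j > 0 else _nearest_other(config, idx, -1)
            after = idx + 1 if j < size - 1 else _nearest_other(config, idx, +1)
            triples.append((before, idx, after))
        start += size
    return SliderTable(np.array(triples, dtype=int).reshape(-1, 3))


def _nearest_other(config: LandmarkConfiguration, idx: int, direction: int) -> int:
    """Nearest fixed landmark to the group end point at ``idx`` (spatially)."""
    fixed = np.where(config.point_roles == "fixed")[0]
    d = np.linalg.norm(config.coordinates[fixed] - config.coordinates[idx], axis=1)
    return int(fixed[np.argmin(d)])


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> PhyloTree:
    """Read a single rooted Newick tree; support values are retained."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse Newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def read_newick_string(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience for tests and synthetic data)."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")
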