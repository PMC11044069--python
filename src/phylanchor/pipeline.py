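"""End-to-end orchestration of the anchor-morphometrics workflow.

``run_analysis`` chains the full analysis for one anchor class: read
landmarks, sliders and tree; generalized Procrustes superimposition with
semilandmark sliding; centroid sizes; shape PCA; allometry regression
(ordinary and on independent contrasts); size correction and PCA of the
residuals; squared-change-parsimony tree-length permutation tests on the
leading shape PCs, the size-corrected PCs and logCS; multivariate-K
randomization tests on the full shape variables, the size-corrected
variables and logCS; and phylomorphospace / deformation-grid exports. All
randomness flows from one configured seed through deterministic per-test
streams, and the JSON report is byte-stable for a fixed config.

``replicate_study`` wraps ``run_analysis`` for externally supplied
ventral/dorsal datasets and prints the computed statistics next to a
reference table of published values with relative deviations.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deformation import export_phylomorphospace, fit_tps_warp, plot_deformation_grid
from .gpa import generalized_procrustes, slide_semilandmarks
from .landmark_io import (
    PhyloTree,
    SliderTable,
    read_newick,
    read_sliders,
    read_tps,
)
from .phylo_signal import k_mult_test, scp_reconstruct, tree_length_test
from .shape_space import (
    allometry_with_pic,
    regress_shape_on_size,
    shape_pca,
    size_correct,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "replicate_study"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (one anchor class)."""

    tps: str
    tree: str
    sliders: str | None = None
    anchor_class: str = "unspecified"
    output_dir: str = "phylanchor_out"
    sliding_criterion: str = "bending_energy"
    cs_sqrt: bool = True
    apply_scale: bool = False
    flip_y: bool = False
    n_perm_tree: int = 10_000
    n_perm_k: int = 999
    pcs_for_mapping: int = 2
    seed: int = 0
    write_figures: bool = True
    slider_index_base: int = 0

    def __post_init__(self) -> None:
        if self.n_perm_tree < 99 or self.n_perm_k < 99:
            raise ValueError("permutation counts must be at least 99")
        if self.pcs_for_mapping < 1:
            raise ValueError("pcs_for_mapping must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Machine-readable summary of one analysis run."""

    anchor_class: str
    n_specimens: int
    n_points: int
    pca_percent_variance: list[float]
    pca_percent_variance_size_corrected: list[float]
    allometry: dict
    allometry_pic: dict
    tree_length_tests: dict
    k_mult_tests: dict
    seed: int
    config_hash: str
    file_manifest: dict
    schema_version: int = REPORT_SCHEMA_VERSION
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-test seed streams from the pipeline seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def _signal_block(result) -> dict:
    return {
        "observed": float(result.observed),
        "p_value": float(result.p_value),
        "n_permutations": result.n_permutations,
        "tail": result.tail,
        "seed": result.seed,
    }


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full workflow described by ``config``.

    Any stage failure aborts with the stage name; outputs written before
    the failure are flagged in ``<output_dir>/INCOMPLETE``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("analysis in progress or aborted\n")
    stage = "setup"
    t0 = time.time()
    log: list[str] = []

    def _log(msg: str) -> None:
        log.append(f"[{time.time() - t0:8.2f}s] {msg}")

    try:
        stage = "read inputs"
        configs = read_tps(config.tps)
        if config.apply_scale:
            for c in configs:
                c.coordinates = c.scaled_coordinates()
        if config.flip_y:
            for c in configs:
                c.coordinates = c.coordinates * np.array([1.0, -1.0])
        sliders = (
            read_sliders(config.sliders, index_base=config.slider_index_base)
            if config.sliders
            else SliderTable()
        )
        if len(sliders):
            sliders.validate_against(configs[0])
        tree = read_newick(config.tree)
        ids = [c.specimen_id for c in configs]
        missing = set(ids) ^ set(tree.tip_labels)
        if missing:
            raise ValueError(f"specimen ids and tree tips disagree: {sorted(missing)}")
        _log(f"read {len(configs)} configurations of {configs[0].k} points; tree with {tree.n_tips} tips")

        stage = "generalized Procrustes analysis"
        alignment = generalized_procrustes(configs)
        if len(sliders):
            stage = "semilandmark sliding"
            alignment = slide_semilandmarks(alignment, sliders, criterion=config.sliding_criterion)
        _log(f"GPA converged={alignment.converged} after {alignment.iterations} iterations")

        stage = "centroid size"
        cs = alignment.centroid_sizes if config.cs_sqrt else alignment.centroid_sizes**2
        log_cs = np.log(cs)
        pd.DataFrame({"specimen": ids, "centroid_size": cs, "log_cs": log_cs}).to_csv(
            out / "centroid_sizes.csv", index=False
        )

        stage = "shape PCA"
        space = shape_pca(alignment)
        space.variance_table().to_csv(out / "pca_variance.csv", index=False)
        pd.DataFrame(
            space.scores,
            index=pd.Index(ids, name="specimen"),
            columns=[f"PC{i + 1}" for i in range(space.scores.shape[1])],
        ).to_csv(out / "pca_scores.csv")
        shapes = alignment.flattened()

        seeds = _derived_seeds(config.seed, 10)

        stage = "allometry regression"
        fit = regress_shape_on_size(
            shapes, log_cs, n_permutations=config.n_perm_tree, seed=seeds[0]
        )
        stage = "allometry regression (independent contrasts)"
        fit_pic = allometry_with_pic(
            tree, shapes, log_cs, tip_labels=ids, n_permutations=config.n_perm_tree, seed=seeds[1]
        )

        stage = "size correction"
        corrected = size_correct(shapes, fit)
        space_corr = shape_pca(corrected, specimen_ids=ids)

        stage = "tree-length permutation tests"
        d = config.pcs_for_mapping
        tl_shape = tree_length_test(
            tree, space.scores[:, :d], n_permutations=config.n_perm_tree,
            seed=seeds[2], tip_labels=ids,
        )
        tl_corr = tree_length_test(
            tree, space_corr.scores[:, :d], n_permutations=config.n_perm_tree,
            seed=seeds[3], tip_labels=ids,
        )
        tl_size = tree_length_test(
            tree, log_cs.reshape(-1, 1), n_permutations=config.n_perm_tree,
            seed=seeds[4], tip_labels=ids,
        )

        stage = "multivariate K randomization tests"
        k_shape = k_mult_test(
            tree, shapes, n_permutations=config.n_perm_k, seed=seeds[5], tip_labels=ids
        )
        k_corr = k_mult_test(
            tree, corrected, n_permutations=config.n_perm_k, seed=seeds[6], tip_labels=ids
        )
        k_size = k_mult_test(
            tree, log_cs.reshape(-1, 1), n_permutations=config.n_perm_k,
            seed=seeds[7], tip_labels=ids,
        )
        for name, res in [
            ("tree_length_shape", tl_shape),
            ("tree_length_size_corrected", tl_corr),
            ("tree_length_logcs", tl_size),
            ("k_mult_shape", k_shape),
            ("k_mult_size_corrected", k_corr),
            ("k_mult_logcs", k_size),
        ]:
            pd.DataFrame({"permuted": res.permuted}).to_csv(
                out / f"perm_{name}.csv", index=False
            )

        stage = "phylomorphospace export"
        pmap = scp_reconstruct(tree, space.scores[:, :d], tip_labels=ids)
        export_phylomorphospace(
            space, pmap, tree, out / "phylomorphospace.svg", write_figure=config.write_figures
        )
        pmap_size = scp_reconstruct(tree, log_cs.reshape(-1, 1), tip_labels=ids)
        export_phylomorphospace(
            space, pmap_size, tree, out / "size_gradient.svg", write_figure=config.write_figures
        )

        if config.write_figures:
            stage = "deformation grids"
            for i, sid in enumerate(ids):
                warp = fit_tps_warp(alignment.consensus, alignment.aligned[i])
                plot_deformation_grid(
                    warp, target=alignment.aligned[i],
                    path=out / f"deformation_{sid}.svg",
                )

        stage = "report"
        manifest = {
            "tps": _sha256(config.tps),
            "tree": _sha256(config.tree),
        }
        if config.sliders:
            manifest["sliders"] = _sha256(config.sliders)
        report = AnalysisReport(
            anchor_class=config.anchor_class,
            n_specimens=len(ids),
            n_points=configs[0].k,
            pca_percent_variance=[float(v) for v in space.percent_variance],
            pca_percent_variance_size_corrected=[float(v) for v in space_corr.percent_variance],
            allometry={
                "percent_predicted": float(fit.percent_predicted),
                "p_value": float(fit.p_value),
                "n_permutations": fit.n_permutations,
                "seed": fit.seed,
            },
            allometry_pic={
                "percent_predicted": float(fit_pic.percent_predicted),
                "p_value": float(fit_pic.p_value),
                "n_permutations": fit_pic.n_permutations,
                "seed": fit_pic.seed,
            },
            tree_length_tests={
                "shape_pcs": _signal_block(tl_shape),
                "size_corrected_pcs": _signal_block(tl_corr),
                "log_cs": _signal_block(tl_size),
            },
            k_mult_tests={
                "shape": _signal_block(k_shape),
                "size_corrected_shape": _signal_block(k_corr),
                "log_cs": _signal_block(k_size),
            },
            seed=config.seed,
            config_hash=config.config_hash(),
            file_manifest=manifest,
        )
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "run.log").write_text("\n".join(log) + "\n")
        (out / "INCOMPLETE").unlink()
        return report
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Replication harness
# ---------------------------------------------------------------------------

# Published statistics for the ventral (VA) and dorsal (DA) anchor datasets
# of the original study; used only for side-by-side comparison.
REFERENCE_VALUES: list[tuple[str, str, str, float]] = [
    ("ventral", "pca_pc1_pc2_percent", "PC1+PC2 % of shape variation", 78.5),
    ("dorsal", "pca_pc1_pc2_percent", "PC1+PC2 % of shape variation", 78.3),
    ("ventral", "tree_length_shape", "mapped tree length (shape PCs)", 0.249),
    ("dorsal", "tree_length_shape", "mapped tree length (shape PCs)", 0.187),
    ("ventral", "k_mult_shape", "K_mult (shape)", 0.78),
    ("dorsal", "k_mult_shape", "K_mult (shape)", 1.1),
    ("dorsal", "allometry_percent", "% shape variation from logCS", 29.7),
    ("ventral", "k_mult_size_corrected", "K_mult (size-corrected shape)", 0.72),
    ("dorsal", "k_mult_size_corrected", "K_mult (size-corrected shape)", 0.98),
    ("ventral", "tree_length_logcs", "mapped tree length (logCS)", 0.34),
    ("dorsal", "tree_length_logcs", "mapped tree length (logCS)", 0.62),
    ("ventral", "k_mult_logcs", "K_mult (logCS)", 0.99),
]


def _extract_stat(report: AnalysisReport, key: str) -> float:
    if key == "pca_pc1_pc2_percent":
        return float(sum(report.pca_percent_variance[:2]))
    if key == "allometry_percent":
        return float(report.allometry["percent_predicted"])
    if key.startswith("tree_length"):
        sub = {"tree_length_shape": "shape_pcs", "tree_length_logcs": "log_cs"}[key]
        return float(report.tree_length_tests[sub]["observed"])
    sub = {
        "k_mult_shape": "shape",
        "k_mult_size_corrected": "size_corrected_shape",
        "k_mult_logcs": "log_cs",
    }[key]
    return float(report.k_mult_tests[sub]["observed"])


def replicate_study(
    data_dir: str | Path,
    tree_file: str | Path,
    output_dir: str | Path = "replication_out",
    seed: int = 0,
    shuffle_tips: bool = False,
    n_perm_tree: int = 10_000,
    n_perm_k: int = 999,
) -> tuple[dict[str, AnalysisReport], pd.DataFrame]:
    """Run the workflow on the deposited ventral/dorsal datasets.

    ``data_dir`` must contain ``ventral.tps`` and ``dorsal.tps`` (with
    optional ``ventral_sliders.txt`` / ``dorsal_sliders.txt``); the tree
    is supplied separately, typically transcribed from the published
    phylogeny — mapped tree lengths and K values depend on its branch
    lengths, which the publication does not print, so deviations on those
    rows are reported, not asserted. ``shuffle_tips`` deliberately
    scrambles the specimen-to-tip assignment as a negative control.
    Returns per-class reports and the 12-row comparison table.
    """
    data_dir = Path(data_dir)
    tree_file = Path(tree_file)
    if not tree_file.exists():
        raise FileNotFoundError(f"tree file {tree_file} not found")
    reports: dict[str, AnalysisReport] = {}
    for anchor_class in ("ventral", "dorsal"):
        tps = data_dir / f"{anchor_class}.tps"
        if not tps.exists():
            raise FileNotFoundError(
                f"{tps} not found; download datasets 1-2 from "
                "https://zenodo.org/records/10412631 and save them as "
                "ventral.tps / dorsal.tps"
            )
        configs = read_tps(tps)
        cs = np.array([float(np.sqrt(np.sum((c.coordinates - c.coordinates.mean(0)) ** 2))) for c in configs])
        if cs.max() / cs.min() - 1.0 < 1e-6:
            raise ValueError(
                f"{tps} appears to hold already-superimposed coordinates "
                "(every configuration has the same centroid size), so log "
                "centroid size is degenerate; supply the raw digitized "
                "coordinates, or re-attach sizes before replicating the "
                "allometry and size-signal statistics"
            )
        sliders = data_dir / f"{anchor_class}_sliders.txt"
        tree_path = tree_file
        if shuffle_tips:
            tree_path = Path(output_dir) / f"shuffled_tree_{anchor_class}.nwk"
            tree_path.parent.mkdir(parents=True, exist_ok=True)
            _write_shuffled_tree(tree_file, tree_path, seed)
        cfg = AnalysisConfig(
            tps=str(tps),
            tree=str(tree_path),
            sliders=str(sliders) if sliders.exists() else None,
            anchor_class=anchor_class,
            output_dir=str(Path(output_dir) / anchor_class),
            n_perm_tree=n_perm_tree,
            n_perm_k=n_perm_k,
            seed=seed,
            write_figures=False,
        )
        reports[anchor_class] = run_analysis(cfg)

    rows = []
    for anchor_class, key, desc, published in REFERENCE_VALUES:
        computed = _extract_stat(reports[anchor_class], key)
        rows.append(
            {
                "anchor": anchor_class,
                "statistic": desc,
                "published": published,
                "computed": computed,
                "relative_deviation": (computed - published) / published,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(Path(output_dir) / "comparison.csv", index=False)
    return reports, table


def _write_shuffled_tree(src: Path, dst: Path, seed: int) -> None:
    tree = read_newick(src)
    rng = np.random.default_rng(seed)
    labels = list(tree.tip_labels)
    shuffled = list(rng.permutation(labels))
    clone = tree.dendropy_tree.clone(depth=1)
    mapping = dict(zip(labels, shuffled))
    for leaf in clone.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    dst.write_text(clone.as_string(schema="newick", suppress_rooting=True))
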