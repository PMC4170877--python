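"""End-to-end run: features -> PCA -> partial bootstrap -> polygons ->
centroids -> dual dendrograms -> dimensionality report.

All randomness flows from the single config seed. Outputs are plain CSV /
JSON / Newick files with fixed names in the output directory, and a run log
recording the seed and the effective replicate count, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg
from .bootstrap import (
    BootstrapCloud,
    EigenvalueBands,
    make_resample_plan,
    partial_bootstrap_scores,
    replicate_eigenvalues,
)
from .cluster import (
    Dendrogram,
    PartitionComparison,
    average_linkage,
    compare_partitions,
    cut_tree,
    suggest_cut,
)
from .datamatrix import DataMatrix, read_matrix_csv, standardize, write_matrix_csv
from .dimensionality import DimensionalityReport, nonoverlap_dimension
from .geometry import (
    ConfidencePolygon,
    cloud_polygons,
    polygons_table,
    polygons_to_json,
)
from .pca import PCAModel, fit_pca
from .simulate import SyntheticSpec, synth_eeg_study, synth_feature_matrix

logger = logging.getLogger("pcaboot")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "build_matrix"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``mode`` selects the input: ``"synthetic"`` (latent-factor feature
    matrix), ``"matrix"`` (CSV with row ids and variable names), or
    ``"features"`` (long-format CSV of raw EEG series to be turned into the
    feature matrix first). ``m = "auto"`` retains the bootstrap criterion's
    m*, floored at 2 so the confidence polygons always have a plane to live
    in (the second axis is flagged as non-retained when m* = 1).
    """

    mode: str = "synthetic"
    input_path: str | None = None
    out_dir: str = "pcaboot_out"
    R: int = 1000
    alpha: float = 0.0
    m: int | str = "auto"
    seed: int = 0
    fs: float = 400.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(eeg.BANDS)
    )
    trim_method: str = "peel"
    n_subjects: int = 24  # synthetic mode only
    condition_effect: float = 0.0  # synthetic mode only

    def validate(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.mode not in ("synthetic", "matrix", "features"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.mode != "synthetic" and self.input_path is None:
            raise ValueError(f"mode '{self.mode}' requires an input path")
        _check_bands(self.bands)


def _check_bands(bands: dict[str, tuple[float, float]]) -> None:
    """Bands must not overlap except at shared boundary bins."""
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (na, (lo_a, hi_a)), (nb, (lo_b, hi_b)) in zip(items, items[1:]):
        if hi_a > lo_b:
            raise ValueError(f"bands {na} and {nb} overlap beyond a shared edge")


@dataclass
class RunResult:
    """In-memory bundle of everything a pipeline run produced."""

    X: DataMatrix
    model: PCAModel
    bands: EigenvalueBands
    report: DimensionalityReport
    m: int
    cloud: BootstrapCloud
    polygons: list[ConfidencePolygon]
    centroids: pd.DataFrame
    tree_scores: Dendrogram
    tree_centroids: Dendrogram
    comparison: PartitionComparison
    cut_scores: float
    cut_centroids: float


def build_matrix(cfg: RunConfig) -> DataMatrix:
    """Materialize the raw input matrix for a run, per the config mode."""
    if cfg.mode == "synthetic":
        spec = SyntheticSpec(
            n_subjects=cfg.n_subjects,
            seed=cfg.seed,
            condition_effect=cfg.condition_effect,
        )
        return synth_feature_matrix(spec)
    if cfg.mode == "matrix":
        return read_matrix_csv(cfg.input_path)
    # features mode: long CSV with subject, condition, value columns
    df = pd.read_csv(cfg.input_path)
    required = {"subject", "condition", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"features CSV needs columns {sorted(required)}")
    sets = []
    for (sid, cond), grp in df.groupby(["subject", "condition"], sort=True):
        series = grp["value"].to_numpy(dtype=float)
        filtered = eeg.bandpass_filter(series, cfg.fs)
        sets.append(
            eeg.make_epochs(
                filtered,
                cfg.fs,
                min_epochs=150,
                subject_id=str(sid),
                condition=str(cond),
            )
        )
    X, excluded = eeg.build_feature_matrix(sets, bands=cfg.bands)
    if excluded:
        logger.info("excluded subjects (too few epochs or missing condition): %s",
                    ", ".join(excluded))
    return X


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunResult:
    """Run the whole validation pipeline; optionally write the result bundle."""
    cfg.validate()
    X = build_matrix(cfg)
    Xs = standardize(X)
    model = fit_pca(Xs)
    plan = make_resample_plan(X.n, cfg.R, cfg.seed)
    bands = replicate_eigenvalues(X, plan, alpha=0.0)
    report = nonoverlap_dimension(bands, model=model)
    if cfg.m == "auto":
        m = max(report.m_star, 2)
        if report.m_star < 2:
            logger.info(
                "m* = %d; plotting plane uses m = 2, second axis not retained",
                report.m_star,
            )
    else:
        m = int(cfg.m)
    cloud = partial_bootstrap_scores(X, model, plan, m=m)
    if cloud.dropped_replicates:
        logger.warning(
            "dropped %d degenerate replicate(s): %s",
            len(cloud.dropped_replicates),
            cloud.dropped_replicates,
        )
    polygons = cloud_polygons(cloud, alpha=cfg.alpha, method=cfg.trim_method)
    centroids = pd.DataFrame(
        {
            "object_id": [pg.object_id for pg in polygons],
            "x": [pg.centroid[0] for pg in polygons],
            "y": [pg.centroid[1] for pg in polygons],
        }
    )
    scores2 = model.scores[:, :2]
    tree_scores = average_linkage(scores2, model.row_ids)
    tree_centroids = average_linkage(
        centroids[["x", "y"]].to_numpy(), list(centroids["object_id"])
    )
    cut_s = suggest_cut(tree_scores)
    cut_c = suggest_cut(tree_centroids)
    comparison = compare_partitions(
        cut_tree(tree_scores, cut_s), cut_tree(tree_centroids, cut_c)
    )
    result = RunResult(
        X=X,
        model=model,
        bands=bands,
        report=report,
        m=m,
        cloud=cloud,
        polygons=polygons,
        centroids=centroids,
        tree_scores=tree_scores,
        tree_centroids=tree_centroids,
        comparison=comparison,
        cut_scores=cut_s,
        cut_centroids=cut_c,
    )
    if write:
        _write_bundle(cfg, result)
    return result


def _write_bundle(cfg: RunConfig, res: RunResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(res.X, out / "matrix.csv")
    res.model.to_json(out / "model.json")
    res.bands.to_csv(out / "eigenvalue_bands.csv")
    res.bands.ci_frame().to_csv(out / "eigenvalue_ci.csv", index=False)
    res.cloud.to_csv(out / "cloud.csv")
    polygons_table(res.polygons).to_csv(out / "polygons.csv", index=False)
    polygons_to_json(res.polygons, out / "polygon_vertices.json")
    res.centroids.to_csv(out / "centroids.csv", index=False)
    res.tree_scores.to_newick(out / "dendrogram_scores.nwk")
    res.tree_centroids.to_newick(out / "dendrogram_centroids.nwk")
    res.report.to_json(out / "dimensionality.json")
    res.comparison.cross_table.to_csv(out / "partition_crosstab.csv")
    log = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "R": cfg.R,
        "effective_R": res.cloud.effective_R,
        "dropped_replicates": res.cloud.dropped_replicates,
        "alpha": cfg.alpha,
        "m": res.m,
        "m_star": res.report.m_star,
        "explained_at_m_star_pct": res.report.explained_at_m,
        "n_cloud_points": res.cloud.n_points,
        "suggested_cut_scores": res.cut_scores,
        "suggested_cut_centroids": res.cut_centroids,
        "rand_index_scores_vs_centroids": res.comparison.rand_index,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
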