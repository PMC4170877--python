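"""Partial bootstrap of PCA: row resampling, replicate eigenvalues, score clouds.

The ordinary bootstrap of a PCA is awkward because every resampled matrix has
its own singular vectors, which may be reflected or rotated relative to the
original ones (the classical fix is Procrustes alignment). The *partial*
bootstrap sidesteps this: each resampled matrix is re-standardized and its
rows are projected as supplementary points onto the ORIGINAL loading basis
``V``. Stacking the R projected replicate matrices yields ``n`` clouds of
``~R`` points each (``nR`` points in total) living in the original principal
planes, one cloud per object, whose spread measures the sampling variability
of that object's score.

Replicate eigenvalues, by contrast, come from a fresh SVD of each resampled,
re-standardized matrix; their per-rank spread gives the confidence bands used
for dimensionality selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamatrix import DataMatrix
from .pca import PCAModel

__all__ = [
    "ResamplePlan",
    "BootstrapCloud",
    "EigenvalueBands",
    "make_resample_plan",
    "partial_bootstrap_scores",
    "replicate_eigenvalues",
    "percentile_ci",
]


@dataclass
class ResamplePlan:
    """R lists of n row indices drawn with replacement, reproducible by seed.

    Each replicate has its own deterministic substream (seeded by
    ``(seed, r)``) so that any single replicate can be regenerated in
    isolation and adding replicates never changes existing ones.
    """

    n: int
    R: int
    seed: int
    index_lists: np.ndarray  # (R, n) int array

    def __post_init__(self) -> None:
        self.index_lists = np.asarray(self.index_lists)
        if self.index_lists.shape != (self.R, self.n):
            raise ValueError("index_lists must have shape (R, n)")
        if self.index_lists.min() < 0 or self.index_lists.max() >= self.n:
            raise ValueError("resample indices out of range")


@dataclass
class BootstrapCloud:
    """All projected replicate scores, tagged by origin object and replicate.

    ``points`` has one row per projected replicate observation (``nR`` rows
    when no replicate is dropped); ``origin_object[i]`` names which original
    row the point replicates. ``per_object_count`` counts each original
    object's appearances over all kept replicates — their mean is exactly the
    effective R, since every replicate contributes exactly n draws.
    """

    points: np.ndarray  # (N, m)
    origin_object: np.ndarray  # (N,) of labels
    replicate_id: np.ndarray  # (N,) of ints
    per_object_count: np.ndarray  # (n,) ints, ordered as row_ids
    row_ids: list[str]
    m: int
    effective_R: int
    dropped_replicates: list[int] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def object_points(self, object_id: str) -> np.ndarray:
        return self.points[self.origin_object == object_id]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.points, columns=[f"dim{j + 1}" for j in range(self.m)]
        )
        df.insert(0, "replicate_id", self.replicate_id)
        df.insert(0, "object_id", self.origin_object)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EigenvalueBands:
    """Replicate eigenvalue sets (one nonincreasing row per replicate).

    ``ci_per_rank`` holds a (lo, hi) pair per rank: the full min/max range at
    ``alpha = 0`` (the convention used for the non-overlap dimensionality
    criterion), percentile bounds otherwise.
    """

    replicate_eigenvalues: np.ndarray  # (R_eff, p)
    alpha: float
    ci_per_rank: np.ndarray  # (p, 2)
    dropped_replicates: list[int] = field(default_factory=list)

    @property
    def R(self) -> int:
        return self.replicate_eigenvalues.shape[0]

    @property
    def p(self) -> int:
        return self.replicate_eigenvalues.shape[1]

    def with_alpha(self, alpha: float) -> "EigenvalueBands":
        ci = np.array(
            [
                percentile_ci(self.replicate_eigenvalues[:, k], alpha)
                for k in range(self.p)
            ]
        )
        return EigenvalueBands(
            replicate_eigenvalues=self.replicate_eigenvalues,
            alpha=alpha,
            ci_per_rank=ci,
            dropped_replicates=list(self.dropped_replicates),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.replicate_eigenvalues,
            columns=[f"rank{k + 1}" for k in range(self.p)],
        ).to_csv(path, index_label="replicate")

    def ci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.p + 1),
                "lo": self.ci_per_rank[:, 0],
                "hi": self.ci_per_rank[:, 1],
            }
        )


def make_resample_plan(n: int, R: int, seed: int) -> ResamplePlan:
    """Draw R resamples of n row indices with replacement, deterministically."""
    if n < 2:
        raise ValueError("need at least 2 rows to resample")
    if R < 1:
        raise ValueError("need at least one replicate")
    idx = np.empty((R, n), dtype=np.int64)
    for r in range(R):
        idx[r] = np.random.default_rng([seed, r]).integers(0, n, size=n)
    return ResamplePlan(n=n, R=R, seed=seed, index_lists=idx)


def _standardize_rows(rows: np.ndarray) -> np.ndarray | None:
    """Mean-center and scale columns (n-1 SD); None if any column is constant."""
    mu = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        return None
    return (rows - mu) / sd


def partial_bootstrap_scores(
    X: DataMatrix,
    model: PCAModel,
    plan: ResamplePlan,
    m: int,
    use_original_scaling: bool = False,
) -> BootstrapCloud:
    """Project every resampled, re-standardized row onto the original loadings.

    Parameters
    ----------
    X
        The raw (unstandardized) training matrix the model was fit from.
    model
        The PCA fit of the standardized training matrix; its first ``m``
        loading columns receive the supplementary points.
    plan
        Row-resampling plan (R replicates of n indices).
    m
        Number of retained dimensions for the cloud.
    use_original_scaling
        If True, standardize each replicate with the ORIGINAL sample's
        means/SDs instead of the replicate's own moments. Default False:
        each replicate carries its own standardization, so the cloud reflects
        the sampling variability of the scaling as well.

    Replicates in which some column becomes constant (impossible in practice
    for continuous data) are dropped and recorded in ``dropped_replicates``;
    the cloud's ``effective_R`` is reduced accordingly.
    """
    if plan.n != X.n:
        raise ValueError("plan row count does not match matrix")
    p = X.p
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}], got {m}")
    V = model.loadings[:, :m]
    if use_original_scaling:
        Xs0 = (
            X.values - X.values.mean(axis=0)
        ) / X.values.std(axis=0, ddof=1)
    blocks: list[np.ndarray] = []
    rep_ids: list[np.ndarray] = []
    origins: list[np.ndarray] = []
    dropped: list[int] = []
    row_ids = np.asarray(X.row_ids, dtype=object)
    counts = np.zeros(X.n, dtype=np.int64)
    for r in range(plan.R):
        idx = plan.index_lists[r]
        if use_original_scaling:
            std = Xs0[idx]
        else:
            std = _standardize_rows(X.values[idx])
            if std is None:
                dropped.append(r)
                continue
        blocks.append(std @ V)
        rep_ids.append(np.full(X.n, r, dtype=np.int64))
        origins.append(row_ids[idx])
        np.add.at(counts, idx, 1)
    if not blocks:
        raise ValueError("every replicate was degenerate; nothing to project")
    return BootstrapCloud(
        points=np.vstack(blocks),
        origin_object=np.concatenate(origins),
        replicate_id=np.concatenate(rep_ids),
        per_object_count=counts,
        row_ids=list(X.row_ids),
        m=m,
        effective_R=plan.R - len(dropped),
        dropped_replicates=dropped,
    )


def replicate_eigenvalues(
    X: DataMatrix, plan: ResamplePlan, alpha: float = 0.0
) -> EigenvalueBands:
    """SVD each resampled, re-standardized matrix; collect its eigenvalues.

    Row ``r`` of the result holds the correlation-matrix eigenvalues
    ``singular_values**2 / (n - 1)`` of replicate ``r``, in decreasing order
    (zero-padded if a replicate is rank-deficient). Rows each sum to ``p``.
    """
    if plan.n != X.n:
        raise ValueError("plan row count does not match matrix")
    n, p = X.n, X.p
    rows = np.zeros((plan.R, p))
    dropped: list[int] = []
    keep = []
    for r in range(plan.R):
        std = _standardize_rows(X.values[plan.index_lists[r]])
        if std is None:
            dropped.append(r)
            continue
        s = np.linalg.svd(std, compute_uv=False)
        lam = np.zeros(p)
        lam[: s.size] = s**2 / (n - 1)
        rows[r] = lam
        keep.append(r)
    reps = rows[keep]
    if reps.shape[0] == 0:
        raise ValueError("every replicate was degenerate")
    bands = EigenvalueBands(
        replicate_eigenvalues=reps,
        alpha=alpha,
        ci_per_rank=np.zeros((p, 2)),
        dropped_replicates=dropped,
    )
    return bands.with_alpha(alpha)


def percentile_ci(values: np.ndarray, alpha: float) -> tuple[float, float]:
    """Percentile bootstrap confidence interval from a set of replicates.

    ``alpha = 0`` returns the full range (min, max). Otherwise the bounds are
    the order statistics at 1-based ranks ``ceil(R * alpha / 2)`` and
    ``R - ceil(R * alpha / 2) + 1`` — e.g. the 25th and 976th of 1000 sorted
    values at ``alpha = 0.05``.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 2:
        raise ValueError("need at least 2 values for a percentile interval")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if alpha == 0:
        return float(v[0]), float(v[-1])
    k = max(1, math.ceil(v.size * alpha / 2))
    return float(v[k - 1]), float(v[v.size - k])
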