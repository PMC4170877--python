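"""SVD-based principal components analysis on standardized data.

The decomposition is ``X = U D V^T`` with ``X`` the standardized n x p
matrix. Columns of ``V`` (the loadings) form an orthonormal basis; scores are
``Z = X V = U D``; eigenvalues of the sample correlation matrix are
``sigma_j^2 = lambda_j^2 / (n - 1)`` where ``lambda_j`` are the singular
values. For standardized input the eigenvalues sum to ``p`` (the trace of a
correlation matrix), so cumulative explained variance has the familiar
``sum_{j<=m} sigma_j^2 / p`` form.

Sign convention: the SVD leaves each component's sign arbitrary; here every
loading column is flipped, if needed, so that its largest-magnitude entry is
positive. This makes fits deterministic and comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamatrix import DataMatrix

__all__ = [
    "PCAModel",
    "fit_pca",
    "explained_variance_pct",
    "project_supplementary",
]


@dataclass
class PCAModel:
    """One PCA fit: loadings, singular values, eigenvalues, scores.

    ``loadings`` is p x p with orthonormal columns (components); ``scores``
    is n x p and equals both ``X V`` and ``U D``. ``explained_variance_pct``
    holds the per-component (marginal) percentages.
    """

    loadings: np.ndarray
    singular_values: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    explained_variance_pct: np.ndarray
    n_fit: int
    col_names: list[str]
    row_ids: list[str]
    source_col_means: np.ndarray | None = None
    source_col_sds: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path: str | Path) -> None:
        """Export the model with fixed field names (arrays as nested lists)."""
        payload = {
            "n_fit": self.n_fit,
            "col_names": self.col_names,
            "row_ids": self.row_ids,
            "loadings": self.loadings.tolist(),
            "singular_values": self.singular_values.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scores": self.scores.tolist(),
            "explained_variance_pct": self.explained_variance_pct.tolist(),
            "source_col_means": None
            if self.source_col_means is None
            else self.source_col_means.tolist(),
            "source_col_sds": None
            if self.source_col_sds is None
            else self.source_col_sds.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            singular_values=np.asarray(d["singular_values"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            explained_variance_pct=np.asarray(
                d["explained_variance_pct"], dtype=float
            ),
            n_fit=int(d["n_fit"]),
            col_names=list(d["col_names"]),
            row_ids=list(d["row_ids"]),
            source_col_means=None
            if d["source_col_means"] is None
            else np.asarray(d["source_col_means"], dtype=float),
            source_col_sds=None
            if d["source_col_sds"] is None
            else np.asarray(d["source_col_sds"], dtype=float),
        )


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # flip each component so the largest-|.| loading entry is positive
    V = Vt.T
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return U, V


def fit_pca(Xs: DataMatrix) -> PCAModel:
    """Fit PCA to a standardized matrix via the SVD.

    Requires ``n > p`` rows so that the full p x p loading basis exists (the
    use case is many objects on few derived variables).
    """
    if not Xs.standardized:
        raise ValueError("fit_pca expects a standardized matrix; call standardize()")
    n, p = Xs.values.shape
    if n <= 1:
        raise ValueError("need more than one observation")
    if n <= p:
        raise ValueError(f"need n > p for a full loading basis (n={n}, p={p})")
    U, s, Vt = np.linalg.svd(Xs.values, full_matrices=False)
    U, V = _fix_signs(U, Vt)
    eigenvalues = s**2 / (n - 1)
    scores = U * s  # = X V = U D
    ev_pct = 100.0 * eigenvalues / eigenvalues.sum()
    return PCAModel(
        loadings=V,
        singular_values=s,
        eigenvalues=eigenvalues,
        scores=scores,
        explained_variance_pct=ev_pct,
        n_fit=n,
        col_names=list(Xs.col_names),
        row_ids=list(Xs.row_ids),
        source_col_means=Xs.col_means,
        source_col_sds=Xs.col_sds,
    )


def explained_variance_pct(eigenvalues: np.ndarray, m: int) -> float:
    """Cumulative percent of variance explained by the first ``m`` components.

    ``100 * sum(eigenvalues[:m]) / sum(eigenvalues)``. Invariant to uniform
    rescaling of the eigenvalues; equals 100 at ``m = p``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("eigenvalues must be a non-empty 1-D sequence")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be nonnegative")
    total = lam.sum()
    if total <= 0:
        raise ValueError("eigenvalues must not all be zero")
    if not 1 <= m <= lam.size:
        raise ValueError(f"m must be in [1, {lam.size}], got {m}")
    return float(100.0 * lam[:m].sum() / total)


def project_supplementary(
    x_new: np.ndarray, model: PCAModel, m: int | None = None
) -> np.ndarray:
    """Project standardized supplementary rows onto the model's loading basis.

    ``x_new`` is a single p-vector or a (q, p) block already expressed on the
    training standardization scale; the result is ``x_new @ V[:, :m]``.
    """
    x = np.atleast_2d(np.asarray(x_new, dtype=float))
    p = model.p
    if x.shape[1] != p:
        raise ValueError(f"supplementary rows have {x.shape[1]} columns, model has {p}")
    if m is None:
        m = p
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}], got {m}")
    return x @ model.loadings[:, :m]


def scree_table(model: PCAModel) -> pd.DataFrame:
    """Rank / eigenvalue / marginal % / cumulative % table (scree profile)."""
    lam = model.eigenvalues
    cum = 100.0 * np.cumsum(lam) / lam.sum()
    return pd.DataFrame(
        {
            "rank": np.arange(1, lam.size + 1),
            "eigenvalue": lam,
            "explained_pct": model.explained_variance_pct,
            "cumulative_pct": cum,
        }
    )
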