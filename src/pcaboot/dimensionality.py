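"""Choosing the number of nontrivial axes from bootstrap eigenvalue bands.

The non-overlap criterion: with per-rank bands over the replicate
eigenvalues (full min/max range at trim level 0), retain dimensionality
``m*`` when every consecutive leading rank pair up to ``m* - 1`` separates,

    min(sigma_k*) - max(sigma_{k+1}*) > 0   for k = 1, ..., m* - 1,

i.e. ``m*`` is 1 plus the number of leading consecutive positive gaps. When
no rank pair separates, ``m* = 1`` (at least one axis is always retained).
The criterion is reported next to the classical scree profile; the two need
not agree and no adjudication between them is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import EigenvalueBands
from .pca import PCAModel, explained_variance_pct, scree_table

__all__ = ["DimensionalityReport", "nonoverlap_dimension", "scree_report"]


@dataclass
class DimensionalityReport:
    """Bootstrap dimensionality decision plus the per-rank gap table."""

    m_star: int
    gap_table: pd.DataFrame  # rank, lo, hi, gap_to_next
    scree_eigenvalues: np.ndarray | None = None
    explained_at_m: float | None = None
    alpha: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "m_star": self.m_star,
            "alpha": self.alpha,
            "explained_at_m_pct": self.explained_at_m,
            "scree_eigenvalues": None
            if self.scree_eigenvalues is None
            else list(map(float, self.scree_eigenvalues)),
            "gap_table": self.gap_table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def summary(self) -> str:
        lines = [
            f"bootstrap non-overlap criterion: retain m* = {self.m_star} axes"
            f" (bands at alpha = {self.alpha:g})",
        ]
        if self.explained_at_m is not None:
            lines.append(
                f"explained variance at m* (original fit): {self.explained_at_m:.1f}%"
            )
        lines.append(self.gap_table.to_string(index=False))
        return "\n".join(lines)


def nonoverlap_dimension(
    bands: EigenvalueBands,
    model: PCAModel | None = None,
    alpha: float | None = None,
) -> DimensionalityReport:
    """Apply the non-overlap criterion to replicate eigenvalue bands.

    ``alpha`` defaults to the bands' own trim level (0 gives the min/max
    criterion as originally stated; a positive value applies the same rule to
    percentile bounds instead). If a fitted model is supplied, the report
    also carries its scree eigenvalues and the explained variance at m*.
    """
    if bands.R < 2:
        raise ValueError("need at least 2 replicates")
    b = bands if alpha is None or alpha == bands.alpha else bands.with_alpha(alpha)
    lo, hi = b.ci_per_rank[:, 0], b.ci_per_rank[:, 1]
    p = b.p
    gaps = lo[:-1] - hi[1:]  # gap between rank k and rank k+1 bands
    m_star = 1
    for g in gaps:
        if g > 0:
            m_star += 1
        else:
            break
    table = pd.DataFrame(
        {
            "rank": np.arange(1, p + 1),
            "lo": lo,
            "hi": hi,
            "gap_to_next": np.append(gaps, np.nan),
            "separated": np.append(gaps > 0, False),
        }
    )
    scree = None if model is None else model.eigenvalues
    explained = (
        None
        if model is None
        else explained_variance_pct(model.eigenvalues, min(m_star, p))
    )
    return DimensionalityReport(
        m_star=m_star,
        gap_table=table,
        scree_eigenvalues=scree,
        explained_at_m=explained,
        alpha=b.alpha,
    )


def scree_report(model: PCAModel) -> pd.DataFrame:
    """Scree profile with an optional (clearly heuristic) elbow suggestion.

    The elbow heuristic marks the rank just before the largest second
    difference of the eigenvalue sequence — the point where the profile bends
    hardest. Flat (equal-eigenvalue) profiles get no elbow. This is a visual
    aid only; the bootstrap criterion is the validated rule.
    """
    tab = scree_table(model)
    lam = model.eigenvalues
    tab["elbow"] = False
    if lam.size >= 3:
        d2 = lam[:-2] - 2 * lam[1:-1] + lam[2:]  # at interior ranks 2..p-1
        if d2.max() > 1e-12:
            tab.loc[int(np.argmax(d2)), "elbow"] = True  # rank before the bend
    return tab
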