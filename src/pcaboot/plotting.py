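"""Best-effort plots of the principal plane, scree, eigenvalue bands, trees."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; callers save to file

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

__all__ = [
    "plot_principal_plane",
    "plot_scree",
    "plot_eigenvalue_hist",
    "plot_dendrogram",
]


def plot_principal_plane(model, polygons=None, centroids=None, ax=None):
    """Scores on PC1/PC2, optionally with confidence polygons and centroids."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    z = model.scores[:, :2]
    ax.scatter(z[:, 0], z[:, 1], s=12, color="k", zorder=3)
    for rid, (x, y) in zip(model.row_ids, z):
        ax.annotate(rid, (x, y), fontsize=6, xytext=(2, 2),
                    textcoords="offset points")
    if polygons is not None:
        for pg in polygons:
            v = np.vstack([pg.vertices, pg.vertices[:1]])
            ax.plot(v[:, 0], v[:, 1], lw=0.6, color="tab:blue", alpha=0.7)
    if centroids is not None:
        ax.scatter(centroids["x"], centroids["y"], marker="x", s=20,
                   color="tab:red", zorder=4)
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    return ax


def plot_scree(model, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    lam = model.eigenvalues
    ax.plot(np.arange(1, lam.size + 1), lam, "o-")
    ax.set_xlabel("component rank")
    ax.set_ylabel("eigenvalue")
    return ax


def plot_eigenvalue_hist(bands, rank, original=None, ax=None, bins=30):
    """Histogram of replicate eigenvalues at one rank (1-based)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(bands.replicate_eigenvalues[:, rank - 1], bins=bins,
            color="tab:gray")
    if original is not None:
        ax.axvline(original, ls="--", color="k")
    ax.set_xlabel(f"replicate eigenvalue, rank {rank}")
    ax.set_ylabel("count")
    return ax


def plot_dendrogram(tree, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(tree.linkage, labels=tree.leaf_labels, ax=ax,
                         leaf_font_size=6)
    ax.set_ylabel("merge height")
    return ax
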