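"""Average-linkage (UPGMA) clustering of score sets and partition comparison.

The validation step compares two agglomerative dendrograms built on the
principal plane: one from the original PC scores, one from the bootstrap
polygon centroids. If the centroids are a faithful validation set, the two
trees should suggest the same grouping; extra structure appearing only in
the centroid tree flags objects whose original scores were unstable.

Average linkage (inter-cluster distance = mean of all pairwise inter-point
Euclidean distances) is used because it is the most merge-stable of the
classical agglomerative rules. The heavy lifting is delegated to
``scipy.cluster.hierarchy``; this module owns the Dendrogram container,
height cuts, Newick export, and a pair-counting partition comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "Dendrogram",
    "average_linkage",
    "cut_tree",
    "compare_partitions",
    "suggest_cut",
    "PartitionComparison",
]


@dataclass
class Dendrogram:
    """Full agglomerative merge tree over labeled leaves.

    ``linkage`` is the (q-1, 4) scipy linkage matrix; heights (column 2) are
    nondecreasing for average linkage on a metric.
    """

    linkage: np.ndarray
    leaf_labels: list[str]

    @property
    def q(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge list as (member_set_a, member_set_b, height), in merge order."""
        q = self.q
        members: dict[int, frozenset] = {
            i: frozenset([self.leaf_labels[i]]) for i in range(q)
        }
        out = []
        for step, (a, b, h, _) in enumerate(self.linkage):
            sa, sb = members[int(a)], members[int(b)]
            out.append((sa, sb, float(h)))
            members[q + step] = sa | sb
        return out

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with branch lengths = merge-height differences.

        Each internal node sits at its merge height; a child's branch length
        is the parent height minus the child's own height (0 for leaves).
        """
        q = self.q
        node_height = {i: 0.0 for i in range(q)}
        node_str = {i: self.leaf_labels[i] for i in range(q)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - node_height[a]
            lb = h - node_height[b]
            node_str[q + step] = (
                f"({node_str[a]}:{la:.12g},{node_str[b]}:{lb:.12g})"
            )
            node_height[q + step] = h
        tree = node_str[q + len(self.linkage) - 1] + ";"
        if path is not None:
            Path(path).write_text(tree + "\n")
        return tree


def average_linkage(points: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA dendrogram of 2-D (or k-D) points under Euclidean distance."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    q = pts.shape[0]
    if q < 2:
        raise ValueError("need at least 2 points to cluster")
    if labels is None:
        labels = [str(i) for i in range(q)]
    if len(labels) != q:
        raise ValueError("labels length does not match point count")
    Z = hierarchy.linkage(pdist(pts), method="average")
    return Dendrogram(linkage=Z, leaf_labels=list(labels))


def cut_tree(d: Dendrogram, height: float) -> dict[str, int]:
    """Partition = connected components of merges at height <= cut height.

    Cutting below the first merge gives q singletons; above the last merge,
    one cluster. Returns a label -> cluster id mapping (ids are arbitrary but
    deterministic).
    """
    if height < 0:
        raise ValueError("cut height must be nonnegative")
    flat = hierarchy.fcluster(d.linkage, t=height, criterion="distance")
    return {lab: int(c) for lab, c in zip(d.leaf_labels, flat)}


@dataclass
class PartitionComparison:
    """Pair-counting agreement between two partitions of the same leaves."""

    rand_index: float
    n_pairs_agree: int
    n_pairs: int
    cross_table: pd.DataFrame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PartitionComparison(rand_index={self.rand_index:.4f}, "
            f"agree={self.n_pairs_agree}/{self.n_pairs})"
        )


def compare_partitions(
    a: dict[str, int], b: dict[str, int]
) -> PartitionComparison:
    """Rand index (fraction of leaf pairs on which the partitions agree).

    Identical partitions score 1; the score is symmetric and invariant to
    cluster relabeling. Also returns the cluster cross-tabulation.
    """
    if set(a) != set(b):
        raise ValueError("partitions are over different leaf sets")
    labels = sorted(a)
    la = np.array([a[k] for k in labels])
    lb = np.array([b[k] for k in labels])
    q = len(labels)
    if q < 2:
        raise ValueError("need at least 2 leaves to compare partitions")
    # contingency-based pair counting
    ct = pd.crosstab(pd.Series(la, name="a"), pd.Series(lb, name="b"))
    nij = ct.to_numpy(dtype=np.int64)
    comb2 = lambda x: x * (x - 1) // 2  # noqa: E731
    same_both = comb2(nij).sum()
    same_a = comb2(nij.sum(axis=1)).sum()
    same_b = comb2(nij.sum(axis=0)).sum()
    total = comb2(q)
    agree = int(total - same_a - same_b + 2 * same_both)
    return PartitionComparison(
        rand_index=agree / total,
        n_pairs_agree=agree,
        n_pairs=int(total),
        cross_table=ct,
    )


def suggest_cut(d: Dendrogram) -> float:
    """Heuristic cut height: midpoint of the largest gap between merge heights.

    Ties go to the earliest (lowest) gap. Purely a convenience for scripted
    runs — published analyses choose cut heights by inspecting the tree.
    """
    if d.q < 3:
        raise ValueError("need at least 3 leaves for a cut suggestion")
    h = np.sort(d.heights)
    gaps = np.diff(h)
    i = int(np.argmax(gaps))  # argmax takes the earliest on ties
    return float((h[i] + h[i + 1]) / 2.0)
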