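"""Hierarchical clustering of taxa by subunit copy-number profiles.

Produces the heatmap-ready organization of the copy-number matrix: taxa
agglomeratively clustered on their count vectors, with normalized genome
metrics and the configuration class joined in dendrogram leaf order.

The agglomeration is written out directly (rather than delegated) because
ties are broken deterministically by the lexicographically smallest taxon
pair, making output independent of input row order; with 100-200 taxa the
O(n^3) loop is negligible.  Pair distances come from
:func:`scipy.spatial.distance.pdist`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .content import ANCESTRAL_PROFILE, classify_matrix, normalize_metrics

__all__ = [
    "Dendrogram",
    "Merge",
    "count_distances",
    "hierarchical_cluster",
    "heatmap_table",
    "plot_heatmap",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}
_LINKAGES = ("complete", "average", "single")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two merged clusters (frozensets of taxon
    labels) and the linkage height."""

    left: frozenset[str]
    right: frozenset[str]
    height: float


@dataclass(frozen=True)
class Dendrogram:
    """Merge sequence plus the induced leaf order (cluster-contiguous)."""

    merges: tuple[Merge, ...]
    leaf_order: tuple[str, ...]

    @property
    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


def count_distances(matrix: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric pairwise distance table between taxa count vectors."""
    if metric not in _METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {sorted(_METRICS)}"
        )
    if len(matrix) < 2:
        raise ValueError("need at least 2 taxa")
    d = squareform(pdist(matrix.values.astype(float), metric=_METRICS[metric]))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def hierarchical_cluster(distances: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaks.

    At each step the pair of clusters at minimal linkage distance is merged;
    among equidistant pairs the one whose (sorted) representative taxon
    labels are lexicographically smallest wins.  Supported linkages:
    complete (default), average, single.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; supported: {_LINKAGES}")
    labels = list(distances.index)
    if list(distances.columns) != labels:
        raise ValueError("distance table index/columns mismatch")
    D = distances.values.astype(float)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance table must be symmetric with zero diagonal")

    # cluster state: list of (sorted member tuple, member indices, order list)
    clusters: list[tuple[tuple[str, ...], list[int], list[str]]] = [
        ((lb,), [i], [lb]) for i, lb in enumerate(labels)
    ]
    merges: list[Merge] = []

    def link(ia: list[int], ib: list[int]) -> float:
        block = D[np.ix_(ia, ib)]
        if linkage == "complete":
            return float(block.max())
        if linkage == "average":
            return float(block.mean())
        return float(block.min())

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = link(clusters[x][1], clusters[y][1])
                key = (d, min(clusters[x][0], clusters[y][0]),
                       max(clusters[x][0], clusters[y][0]))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (height, _, _), x, y = best
        a, b = clusters[x], clusters[y]
        # put the lexicographically smaller cluster on the left
        if min(b[0]) < min(a[0]):
            a, b = b, a
        merges.append(Merge(frozenset(a[0]), frozenset(b[0]), height))
        merged = (
            tuple(sorted(a[0] + b[0])),
            a[1] + b[1],
            a[2] + b[2],
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return Dendrogram(tuple(merges), tuple(clusters[0][2]))


def heatmap_table(
    dendrogram: Dendrogram,
    matrix: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    reference: Mapping[str, int] = ANCESTRAL_PROFILE,
) -> pd.DataFrame:
    """Copy-number matrix in dendrogram leaf order with normalized genome
    metrics and the per-taxon configuration class joined on."""
    order = list(dendrogram.leaf_order)
    if set(order) != set(matrix.index):
        raise ValueError("dendrogram taxa do not match copy-number matrix")
    out = matrix.loc[order].copy()
    out["configuration"] = classify_matrix(matrix, reference).loc[order]
    if metrics is not None:
        if not set(order) <= set(metrics.index):
            missing = sorted(set(order) - set(metrics.index))
            raise ValueError(f"metrics table missing taxa: {missing}")
        normed = normalize_metrics(metrics)
        out["gs_norm"] = normed.loc[order, "gs_norm"]
        out["gc_norm"] = normed.loc[order, "gc_norm"]
    return out


def plot_heatmap(table: pd.DataFrame, path: str) -> None:
    """Optional thin rendering of the ordered table (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    numeric = table.select_dtypes("number")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * numeric.shape[1]), max(4, 0.12 * len(table)))
    )
    im = ax.imshow(numeric.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(numeric.shape[1]), numeric.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(table)), table.index, fontsize=4)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
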