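"""Hierarchical clustering of genes and samples on log2(RPKM).

Agglomerative clustering with complete linkage (inter-cluster distance =
maximum pairwise distance) on Euclidean distances, the combination used for
expression heatmaps of the RP panel.  Complete linkage guarantees monotone
merge heights, which is asserted on every run.  A Pearson correlation matrix
over samples complements the trees, and the leaf-ordered matrix behind the
heatmap is exported as TSV so downstream checks never touch image files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError
from .io import write_tsv


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ConfigurationError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ConfigurationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ConfigurationError("distance matrix diagonal is not zero")
        if (m < 0).any():
            raise ConfigurationError("distances must be non-negative")
        self.matrix = m

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class Dendrogram:
    """Binary agglomerative merge tree (scipy linkage encoding) plus leaf labels."""

    labels: tuple[str, ...]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ConfigurationError("linkage matrix shape does not match labels")
        if np.any(np.diff(self.heights) < -1e-9):
            raise ConfigurationError("merge heights are not monotone non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` flat clusters; labels are 1-based cluster ids."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        """Newick string with branch lengths equal to merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{node.dist + length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({left},{right});"


def euclidean_distances(matrix: pd.DataFrame, axis: str = "rows") -> DistanceMatrix:
    """Pairwise Euclidean distances between rows (genes) or columns (samples)."""
    if axis not in ("rows", "columns"):
        raise ConfigurationError(f"axis must be rows/columns, got {axis!r}")
    data = matrix if axis == "rows" else matrix.T
    arr = data.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ConfigurationError("matrix contains NaN values")
    dist = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(ids=tuple(str(i) for i in data.index), matrix=dist)


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate with complete linkage (max pairwise inter-cluster distance)."""
    if len(d.ids) < 2:
        raise ConfigurationError("need >= 2 items to cluster")
    linkage = hierarchy.linkage(d.condensed, method="complete")
    return Dendrogram(labels=d.ids, linkage=linkage)


def pearson_correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson coefficients between sample columns over gene vectors."""
    if expr.shape[0] < 2:
        raise ConfigurationError("need >= 2 genes for sample correlations")
    sd = expr.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ConfigurationError(f"sample {bad!r} has zero variance")
    corr = expr.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_heatmap(
    log_expr: pd.DataFrame,
    row_tree: Dendrogram,
    col_tree: Dendrogram,
    out_tsv: str | Path,
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Reorder the matrix by both dendrograms, write it as TSV, optionally render.

    The rendered heatmap uses a black (low) to yellow (high) colour ramp;
    all quantitative checks run on the returned/leaf-ordered TSV.
    """
    if set(row_tree.labels) != set(map(str, log_expr.index)):
        raise ConfigurationError("row tree labels do not match matrix rows")
    if set(col_tree.labels) != set(map(str, log_expr.columns)):
        raise ConfigurationError("column tree labels do not match matrix columns")
    ordered = log_expr.loc[row_tree.leaf_order(), col_tree.leaf_order()]
    ordered.index.name = "gene_id"
    write_tsv(ordered, out_tsv)
    if out_png is not None:
        _render_heatmap(ordered, out_png)
    return ordered


def _render_heatmap(ordered: pd.DataFrame, out_png: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("black_yellow", ["black", "yellow"])
    fig, ax = plt.subplots(figsize=(8, 10))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xlabel("samples (leaf order)")
    ax.set_ylabel("genes (leaf order)")
    fig.colorbar(im, ax=ax, label="log2(RPKM + pseudocount)")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
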