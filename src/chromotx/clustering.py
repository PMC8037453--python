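"""Hierarchical clustering of the DEG x chromogroup modified-FC matrix.

Rows (genes) are centered and scaled, distances are Euclidean, linkage is
UPGMA (average linkage); cutting the dendrogram at k clusters labels
rows/columns.  Chromogroups sharing an aberration pattern (e.g. the two
1q-gain/16q-loss groups) pair up when the dosage effect dominates the
fold-change profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def build_fc_matrix(per_group_fc: dict[str, pd.Series]) -> pd.DataFrame:
    """Assemble the gene x chromogroup modified-FC matrix.

    Genes missing from some group's contrast are filled with 0 (no
    evidence of change), keeping the matrix dense.
    """
    frame = pd.DataFrame(per_group_fc)
    frame = frame.fillna(0.0)
    if not np.isfinite(frame.to_numpy()).all():
        raise ValueError("non-finite fold-change values")
    frame.index.name = "gene_id"
    return frame


def scale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sample SD 1.

    Constant rows cannot be scaled and are set to all-zeros (logged).
    """
    if matrix.shape[1] < 2:
        raise ValueError("row scaling needs at least two columns")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("scale_rows: %d constant row(s) set to zeros", int(flat.sum()))
    sd[sd == 0] = 1.0
    out = (vals - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def upgma_cluster(
    matrix: pd.DataFrame, axis: str = "rows", k: int | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """UPGMA dendrogram (scipy linkage matrix) and optional k-cut labels.

    ``axis`` selects rows or columns.  Merge heights are average pairwise
    Euclidean distances; the agglomeration is deterministic (scipy breaks
    distance ties by cluster index).
    """
    if axis == "rows":
        data = matrix
    elif axis == "columns":
        data = matrix.T
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    n = data.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two items")
    if k is not None and k > n:
        raise ValueError(f"cannot cut {n} items into {k} clusters")
    z = linkage(data.to_numpy(dtype=float), method="average", metric="euclidean")
    labels = None
    if k is not None:
        flat = cut_tree(z, n_clusters=k).ravel()
        labels = pd.Series(flat, index=data.index, name="cluster")
    return z, labels


def cophenetic_distances(matrix: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pairwise cophenetic (dendrogram merge height) distances."""
    data = matrix if axis == "rows" else matrix.T
    z, _ = upgma_cluster(matrix, axis=axis)
    coph = squareform(cophenet(z, pdist(data.to_numpy(dtype=float)))[1])
    return pd.DataFrame(coph, index=data.index, columns=data.index)


def linkage_table(z: np.ndarray) -> pd.DataFrame:
    """Merge list as a tidy table (left, right, height, size)."""
    return pd.DataFrame(z, columns=["left", "right", "height", "size"]).astype(
        {"left": int, "right": int, "size": int}
    )
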