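"""Pseudobulk CRE-by-cluster accessibility matrices from single-cell counts.

Collapses a feature-by-cell count matrix to a feature-by-cluster matrix
by multiplication with a binary cluster-by-cell membership matrix,
normalized by the number of cells per cluster.  No additional depth
normalization is applied here; TMM scaling is applied downstream where
the annotation workflow requires it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fragments import SparseCountMatrix


def pseudobulk_matrix(
    counts: SparseCountMatrix,
    labels: Mapping[str, str],
    min_cells: int = 1,
) -> pd.DataFrame:
    """Average counts over cells within each cluster.

    ``labels`` maps barcode -> cluster id; every labelled barcode must be
    present in the matrix.  Clusters with fewer than ``min_cells`` member
    cells are dropped.  Output columns are sorted cluster ids.
    """
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    bc_idx = {b: i for i, b in enumerate(counts.barcodes)}
    unknown = [b for b in labels if b not in bc_idx]
    if unknown:
        raise ValueError(f"labelled barcodes absent from matrix: {unknown[:5]}")

    clusters: dict[str, list[int]] = {}
    for barcode, cluster in labels.items():
        clusters.setdefault(str(cluster), []).append(bc_idx[barcode])
    kept = {c: idx for c, idx in clusters.items() if len(idx) >= min_cells}
    if not kept:
        raise ValueError("no cluster satisfies the min_cells threshold")

    cluster_ids = sorted(kept)
    n_cells, n_clusters = len(counts.barcodes), len(cluster_ids)
    rows, cols = [], []
    for j, c in enumerate(cluster_ids):
        for i in kept[c]:
            rows.append(i)
            cols.append(j)
    membership = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cells, n_clusters)
    ).tocsr()
    summed = counts.matrix @ membership  # features x clusters
    sizes = np.array([len(kept[c]) for c in cluster_ids], dtype=float)
    values = np.asarray(summed.todense()) / sizes
    return pd.DataFrame(values, index=counts.feature_ids, columns=cluster_ids)


def drop_sparse_celltypes(
    pseudobulk: pd.DataFrame, max_zero_fraction: float = 0.70
) -> pd.DataFrame:
    """Drop cell-type columns with zero values for more than the given fraction of CREs (strict >)."""
    zero_frac = (pseudobulk == 0).mean(axis=0)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError("all cell types exceed the zero-fraction threshold")
    return pseudobulk.loc[:, keep]
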