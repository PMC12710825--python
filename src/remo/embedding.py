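"""Normalization, feature selection, dimension reduction, and cluster-separation metrics.

Matrices are feature-by-cell (cells in columns) throughout, matching the
count matrices produced by :mod:`remo.fragments`.  Two embedding paths
are provided: log-normalization + variable-feature selection + PCA (the
module-count path) and TF-IDF + truncated SVD, i.e. latent semantic
indexing (the peak-count path).  Cluster separation in an embedding is
measured against external labels with the Calinski-Harabasz index, the
per-cluster mean silhouette, and per-cluster mean kNN purity.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, svds
from sklearn.metrics import calinski_harabasz_score, pairwise_distances, silhouette_samples


def _as_csc(matrix) -> sp.csc_matrix:
    if sp.issparse(matrix):
        return matrix.tocsc().astype(float)
    return sp.csc_matrix(np.asarray(matrix, dtype=float))


def log_normalize(matrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """Depth-normalize and log-transform: ln(1 + scale * count / cell_total).

    Cells are columns.  The sparsity pattern is preserved; cells with
    zero total counts stay all-zero (a warning is issued).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    X = _as_csc(matrix)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} cells have zero counts and stay all-zero",
            stacklevel=2,
        )
    inv = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
    X = X @ sp.diags(inv)
    X.data = np.log1p(scale * X.data)
    return X.tocsr()


def tfidf(matrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """TF-IDF weighting: ln(1 + scale * TF * IDF), the LSI input transform.

    TF = count / cell_total; IDF = n_cells / n_cells_with_feature.
    Features observed in no cell stay all-zero (warning), as do cells
    with zero total counts.
    """
    X = _as_csc(matrix)
    n_cells = X.shape[1]
    totals = np.asarray(X.sum(axis=0)).ravel()
    df = np.asarray((X > 0).sum(axis=1)).ravel()
    if (df == 0).any():
        warnings.warn(
            f"{int((df == 0).sum())} features observed in zero cells stay all-zero",
            stacklevel=2,
        )
    if (totals == 0).any():
        warnings.warn("cells with zero counts stay all-zero", stacklevel=2)
    inv_tot = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
    idf = np.divide(n_cells, df, out=np.zeros(len(df)), where=df > 0)
    X = sp.diags(idf) @ X @ sp.diags(inv_tot)
    X.data = np.log1p(scale * X.data)
    return X.tocsr()


# ---------------------------------------------------------------------------
# variable-feature selection


def _loess(x_train, y_train, x_eval, span: float = 0.3, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights (LOESS).

    For each evaluation point, the nearest ``span`` fraction of training
    points is fit with a weighted degree-``degree`` polynomial.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    x_eval = np.asarray(x_eval, float)
    n = len(x_train)
    window = max(degree + 2, int(np.ceil(span * n)))
    window = min(window, n)
    out = np.empty(len(x_eval))
    order = np.argsort(x_train, kind="stable")
    xs, ys = x_train[order], y_train[order]
    for i, x0 in enumerate(x_eval):
        # nearest `window` training points around x0
        pos = np.searchsorted(xs, x0)
        lo = max(0, min(pos - window // 2, n - window))
        hi = lo + window
        # widen to the true nearest set at the boundary
        while lo > 0 and (x0 - xs[lo - 1]) < (xs[hi - 1] - x0):
            lo -= 1
            hi -= 1
        xw, yw = xs[lo:hi], ys[lo:hi]
        d = np.abs(xw - x0)
        dmax = d.max()
        w = np.ones_like(d) if dmax == 0 else (1 - (d / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        coeffs = np.polynomial.polynomial.polyfit(
            xw - x0, yw, deg=degree, w=np.sqrt(w)
        )
        out[i] = coeffs[0]
    return out


def select_variable_features(
    matrix,
    n_features: int = 20_000,
    downsample: int = 2_000,
    span: float = 0.3,
    degree: int = 2,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean-variance residual feature selection with a downsampled LOESS fit.

    Per feature (row), log10 mean and log10 variance are computed over
    all cells (zeros included).  A LOESS curve of log-variance on
    log-mean is fit on up to ``downsample`` features taken evenly across
    the log-mean rank range, and the residual (observed - predicted
    log-variance) is evaluated for every feature.  Returns the indices
    of the ``n_features`` largest residuals (ties by feature order) and
    the dispersion table.  Features with zero variance are excluded.
    """
    X = _as_csc(matrix).tocsr()
    n = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    ok = var > 0
    if ok.sum() < 10:
        raise ValueError("need at least 10 features with positive variance")
    feat_idx = np.where(ok)[0]
    log_mean = np.log10(mean[ok])
    log_var = np.log10(var[ok])

    order = np.argsort(log_mean, kind="stable")
    n_train = min(downsample, len(order))
    train = order[np.linspace(0, len(order) - 1, n_train).round().astype(int)]
    predicted = _loess(log_mean[train], log_var[train], log_mean, span=span, degree=degree)
    residual = log_var - predicted

    table = pd.DataFrame(
        {
            "feature": feat_idx,
            "log_mean": log_mean,
            "log_variance": log_var,
            "predicted": predicted,
            "residual": residual,
        }
    )
    if n_features > len(feat_idx):
        warnings.warn(
            f"n_features={n_features} exceeds {len(feat_idx)} usable features; returning all",
            stacklevel=2,
        )
        n_features = len(feat_idx)
    top = np.argsort(-residual, kind="stable")[:n_features]
    return np.sort(feat_idx[top]), table


# ---------------------------------------------------------------------------
# dimension reduction


def truncated_svd(
    matrix,
    n_dims: int = 50,
    center: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated SVD of the cell-by-feature view of a feature-by-cell matrix.

    With ``center=False`` this is the plain truncated SVD used for LSI.
    With ``center=True`` the feature means are removed implicitly
    through the matrix-vector products (the dense centered matrix is
    never materialized), giving PCA scores.  Component signs are fixed
    so each component's largest-magnitude feature loading is positive.
    Returns (embedding [cells x n_dims], singular values descending).
    """
    X = _as_csc(matrix)
    n_feat, n_cells = X.shape
    if n_dims >= min(n_feat, n_cells):
        raise ValueError(
            f"n_dims={n_dims} must be < min(cells, features)={min(n_feat, n_cells)}"
        )
    A = X.T.tocsr()  # cells x features
    if center:
        mu = np.asarray(X.mean(axis=1)).ravel()  # feature means
        ones_c = np.ones(n_cells)

        def matvec(v):
            v = np.asarray(v).ravel()
            return A @ v - ones_c * float(mu @ v)

        def rmatvec(v):
            v = np.asarray(v).ravel()
            return A.T @ v - mu * float(v.sum())

        def matmat(V):
            return A @ V - np.outer(ones_c, mu @ V)

        def rmatmat(V):
            return A.T @ V - np.outer(mu, V.sum(axis=0))

        op = LinearOperator(
            (n_cells, n_feat),
            matvec=matvec,
            rmatvec=rmatvec,
            matmat=matmat,
            rmatmat=rmatmat,
            dtype=float,
        )
    else:
        op = A
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(A.shape))
    u, s, vt = svds(op, k=n_dims, v0=v0)
    desc = np.argsort(-s, kind="stable")
    u, s, vt = u[:, desc], s[desc], vt[desc]
    for c in range(n_dims):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    return u * s, s


# ---------------------------------------------------------------------------
# cluster-separation metrics


def _check_labels(embedding, labels) -> tuple[np.ndarray, np.ndarray]:
    emb = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if emb.shape[0] != len(labels):
        raise ValueError("labels must align with embedding rows")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    return emb, labels


def ch_index(embedding, labels) -> float:
    """Calinski-Harabasz index: between- over within-cluster dispersion ratio."""
    emb, labels = _check_labels(embedding, labels)
    return float(calinski_harabasz_score(emb, labels))


def silhouette_by_cluster(embedding, labels) -> pd.Series:
    """Mean silhouette width per cluster (Euclidean distance).

    Per-cluster averaging accounts for unbalanced cell type proportions;
    cells in singleton clusters get silhouette 0.
    """
    emb, labels = _check_labels(embedding, labels)
    s = silhouette_samples(emb, labels)
    return pd.Series(s).groupby(pd.Series(labels)).mean().rename("silhouette")


def knn_purity(embedding, labels, k: int = 20) -> pd.Series:
    """Mean kNN purity per cluster.

    Per cell: the fraction of its k Euclidean nearest neighbours (self
    excluded; ties at the k-th distance broken by index) sharing the
    cell's label, averaged within each cluster.
    """
    emb, labels = _check_labels(embedding, labels)
    n = len(labels)
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    dist = pairwise_distances(emb)
    np.fill_diagonal(dist, np.inf)
    nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]
    same = labels[nbrs] == labels[:, None]
    purity = same.mean(axis=1)
    return pd.Series(purity).groupby(pd.Series(labels)).mean().rename("knn_purity")
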