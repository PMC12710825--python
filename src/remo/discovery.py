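"""Two-stage discovery of regulatory element modules.

Stage one groups CREs into broad clusters from a CRE-by-experiment
signal matrix (e.g. ChIP-seq signal across many experiments): per-
experiment quantile clipping, TMM normalization, log(1+x), PCA, a
k-nearest-neighbour graph in PC space converted to a shared-nearest-
neighbour (SNN) graph with Jaccard edge weights, and Leiden clustering
with the modularity objective.

Stage two subclusters each broad cluster per chromosome using the
co-accessibility-by-contact score between CRE pairs i, j::

    S_ij = R_ij * (C_ij + D_ij)

where R is the Pearson correlation of accessibility across pseudobulk
cell clusters (negatives clipped to 0), C the scaled Hi-C contact
probability, and D a Gaussian kernel on genomic distance
(exp(-x^2 / 2 sigma^2), sigma = 500 kb).  A weighted graph keeps the top
30 edges per node ranked by S, and Leiden community detection with the
Constant Potts Model objective (resolution 0.5) defines the modules.
Candidate pairs are restricted to the same chromosome within 1 Mb,
matching the contact cap.  Every CRE is assigned to exactly one module;
modules never span chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
import scipy.sparse as sp

from .contacts import ContactMap, contact_for_pair
from .intervals import GenomicInterval, RegionSet, pairwise_distance

DEFAULT_SIGMA = 500_000.0
DEFAULT_CANDIDATE_WINDOW = 1_000_000.0


# ---------------------------------------------------------------------------
# normalization


def clip_columns(matrix: np.ndarray, quantile: float = 0.90) -> np.ndarray:
    """Clip each column's values above its ``quantile`` to the quantile value.

    The threshold is computed over the column's nonzero entries so that
    sparse columns (mostly-zero signal tracks) are not clipped to zero.
    """
    X = np.asarray(matrix, dtype=float).copy()
    for j in range(X.shape[1]):
        nz = X[:, j] != 0
        if nz.any():
            q = np.quantile(X[nz, j], quantile)
            X[:, j] = np.minimum(X[:, j], q)
    return X


def tmm_factors(
    matrix: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factor per column (sample).

    The reference column is the one whose 75th percentile is closest to
    the mean of 75th percentiles.  For each column the factor is
    2**(trimmed weighted mean of log2 ratios against the reference),
    computed over features positive in both columns, trimming 30% from
    each tail on M and 5% on A, with precision (inverse asymptotic
    variance) weights.  Ratios are taken on raw column values so the
    factor absorbs sequencing depth; factors are normalized to geometric
    mean 1.  Dividing each column by its factor normalizes the matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    colsum = X.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("all-zero column in matrix")
    q75 = np.quantile(X, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    n_cols = X.shape[1]
    factors = np.ones(n_cols)
    yr_all = X[:, ref]
    for k in range(n_cols):
        yk_all = X[:, k]
        pos = (yk_all > 0) & (yr_all > 0)
        if not pos.any():
            factors[k] = colsum[k] / colsum[ref]
            continue
        yk, yr = yk_all[pos], yr_all[pos]
        M = np.log2(yk / yr)
        A = 0.5 * np.log2(yk * yr)
        w = (colsum[k] - yk) / (colsum[k] * yk) + (colsum[ref] - yr) / (
            colsum[ref] * yr
        )
        w = np.maximum(w, 1e-12)
        n_g = len(M)
        rM, rA = rankdata(M), rankdata(A)
        keep = (
            (rM > n_g * trim_m)
            & (rM <= n_g * (1 - trim_m))
            & (rA > n_g * trim_a)
            & (rA <= n_g * (1 - trim_a))
        )
        if not keep.any():
            keep = np.ones(n_g, dtype=bool)
        wk = 1.0 / w[keep]
        factors[k] = 2.0 ** (np.sum(M[keep] * wk) / np.sum(wk))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# stage one: broad clustering


def broad_cluster(
    signal,
    clip_quantile: float = 0.90,
    n_pcs: int = 50,
    knn: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Broad clustering of CREs from a CRE-by-experiment signal matrix.

    Pipeline: per-experiment quantile clipping -> TMM normalization ->
    log(1+x) -> PCA -> kNN in PC space -> SNN (Jaccard weights) ->
    Leiden with the modularity objective.  Returns one integer label per
    CRE; deterministic for a fixed seed.
    """
    if n_pcs < 1:
        raise ValueError(f"n_pcs must be >= 1, got {n_pcs}")
    X = np.asarray(signal, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 CREs and 2 experiments")
    X = clip_columns(X, clip_quantile)
    X = X / tmm_factors(X)
    X = np.log1p(X)
    n_comp = min(n_pcs, n - 1, p)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)

    k = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(pcs)
    _, nbr = nn.kneighbors(pcs)
    # neighbour sets include the point itself (self removed from the
    # returned list first, then re-added) so identical points get Jaccard 1
    sets = np.empty((n, k + 1), dtype=np.int64)
    for i in range(n):
        others = [j for j in nbr[i] if j != i][:k]
        while len(others) < k:  # duplicates collapsed by sklearn ties
            others.append(i)
        sets[i] = [i] + others
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, sets.ravel())), shape=(n, n)
    )
    adj.data = np.minimum(adj.data, 1.0)
    shared = (adj @ adj.T).tocoo()
    size = adj.sum(axis=1).A1
    edges, weights = [], []
    for i, j, s in zip(shared.row, shared.col, shared.data):
        if i < j and s > 0:
            union = size[i] + size[j] - s
            edges.append((int(i), int(j)))
            weights.append(float(s / union))
    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights=weights,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------
# stage two: co-accessibility-by-contact score


def coaccessibility(pseudobulk, i: int, j: int) -> float:
    """Pearson correlation of two CREs across pseudobulk clusters, clipped at 0.

    Zero-variance rows give 0.
    """
    X = np.asarray(pseudobulk, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 pseudobulk clusters")
    a, b = X[i], X[j]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return max(r, 0.0)


def _standardized_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.zeros_like(X, dtype=float)
    ok = (sd > 0).ravel()
    Z[ok] = (X[ok] - mu[ok]) / sd[ok]
    return Z


def distance_kernel(x, sigma: float = DEFAULT_SIGMA):
    """Gaussian kernel exp(-x^2 / (2 sigma^2)) on genomic distance (bp)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    out = np.exp(-(x**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def score_pairs(
    pseudobulk,
    regions: Sequence[GenomicInterval],
    contact_map: ContactMap | None = None,
    candidate_window: float = DEFAULT_CANDIDATE_WINDOW,
    sigma: float = DEFAULT_SIGMA,
) -> list[tuple[int, int, float]]:
    """Score all same-chromosome CRE pairs within ``candidate_window``.

    ``pseudobulk`` rows must align with ``regions`` (one broad cluster,
    one chromosome).  Returns (i, j, S) with i < j and S > 0.
    """
    X = np.asarray(pseudobulk, dtype=float)
    if X.shape[0] != len(regions):
        raise ValueError("pseudobulk rows must align with regions")
    chroms = {iv.chrom for iv in regions}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    Z = _standardized_rows(X)
    n_ct = X.shape[1]
    mids = np.array([iv.midpoint for iv in regions])
    order = np.argsort(mids, kind="stable")
    out: list[tuple[int, int, float]] = []
    for a_pos, a in enumerate(order):
        for b in order[a_pos + 1 :]:
            x = abs(mids[b] - mids[a])
            if x > candidate_window:
                break
            r = float(Z[a] @ Z[b]) / n_ct
            if r <= 0:
                continue
            c = contact_for_pair(contact_map, regions[a], regions[b]) if contact_map else 0.0
            d = distance_kernel(x, sigma)
            s = r * (c + d)
            if s > 0:
                i, j = (int(a), int(b)) if a < b else (int(b), int(a))
                out.append((i, j, s))
    return out


@dataclass
class CoAccessGraph:
    """Undirected weighted CRE graph from per-node top-k score selection."""

    n_nodes: int
    edges: list[tuple[int, int]]
    weights: list[float]

    def __post_init__(self):
        for (i, j), w in zip(self.edges, self.weights):
            if i == j:
                raise ValueError("self-edges are not allowed")
            if w <= 0:
                raise ValueError("edge weights must be positive")


def build_topk_graph(
    pairs: Sequence[tuple[int, int, float]], n_nodes: int, k: int = 30
) -> CoAccessGraph:
    """Keep each node's k highest-S incident pairs; union over nodes.

    An edge survives if either endpoint kept it; ties at the k-th score
    are broken towards the smaller partner index.  Duplicate edges carry
    a single weight.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    incident: dict[int, list[tuple[float, int, int]]] = {}
    for idx, (i, j, s) in enumerate(pairs):
        if s <= 0:
            raise ValueError("pair scores must be positive")
        incident.setdefault(i, []).append((s, j, idx))
        incident.setdefault(j, []).append((s, i, idx))
    kept: set[int] = set()
    for node, cand in incident.items():
        cand.sort(key=lambda t: (-t[0], t[1]))
        kept.update(idx for _, _, idx in cand[:k])
    edges, weights = [], []
    for idx in sorted(kept):
        i, j, s = pairs[idx]
        edges.append((min(i, j), max(i, j)))
        weights.append(float(s))
    return CoAccessGraph(n_nodes=n_nodes, edges=edges, weights=weights)


def leiden_cpm(
    graph: CoAccessGraph, resolution: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Leiden community detection with the Constant Potts Model objective.

    Isolated nodes become singleton communities; deterministic for a
    fixed seed.
    """
    g = igraph.Graph(n=graph.n_nodes, edges=graph.edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.CPMVertexPartition,
        weights=graph.weights or None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class ModuleSet:
    """A total partition of CREs into modules with per-module statistics.

    ``labels`` holds one module id per CRE, aligned with the region set
    the modules were built from; ``stats`` is indexed by module id with
    columns ``size`` and ``mean_pairwise_distance`` (bp; 0 for
    singletons).
    """

    cre_ids: list[str]
    labels: list[str]
    stats: pd.DataFrame

    def __post_init__(self):
        if len(self.cre_ids) != len(self.labels):
            raise ValueError("labels must align with cre_ids")

    @property
    def assignment(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cre_ids, name="module")

    def members(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, m in enumerate(self.labels):
            out.setdefault(m, []).append(i)
        return out

    @property
    def mean_size(self) -> float:
        return float(self.stats["size"].mean())

    @classmethod
    def from_labels(cls, regions: RegionSet, labels: Sequence[str]) -> "ModuleSet":
        """Build a module set from per-CRE labels (e.g. a module BED's column 4)."""
        if len(labels) != len(regions):
            raise ValueError("labels must align with regions")
        members: dict[str, list[int]] = {}
        for i, m in enumerate(labels):
            members.setdefault(str(m), []).append(i)
        rows = []
        for m, idx in members.items():
            chroms = {regions[i].chrom for i in idx}
            if len(chroms) > 1:
                raise ValueError(f"module {m} spans chromosomes {sorted(chroms)}")
            if len(idx) > 1:
                mean_dist = float(
                    np.mean(
                        [
                            pairwise_distance(regions[a], regions[b])
                            for a, b in combinations(idx, 2)
                        ]
                    )
                )
            else:
                mean_dist = 0.0
            rows.append((m, len(idx), mean_dist))
        stats = pd.DataFrame(
            rows, columns=["module", "size", "mean_pairwise_distance"]
        ).set_index("module")
        return cls(
            cre_ids=[_cre_id(iv) for iv in regions],
            labels=[str(m) for m in labels],
            stats=stats,
        )


def _cre_id(iv: GenomicInterval) -> str:
    return iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"


def assemble_modules(
    partitions: Sequence[tuple[str, Sequence[int], Sequence[int]]],
    regions: RegionSet,
) -> ModuleSet:
    """Combine per-chromosome partitions into a total, chrom-prefixed module set.

    ``partitions`` entries are (chrom, global CRE indices, local labels).
    CREs absent from every partition become singleton modules, so the
    assignment is a total function.  Raises on overlapping assignments.
    """
    module_of: dict[int, str] = {}
    counters: dict[str, int] = {}
    for chrom, indices, labels in partitions:
        if len(indices) != len(labels):
            raise ValueError("indices and labels must align")
        remap: dict[int, str] = {}
        for gi, lab in zip(indices, labels):
            if gi in module_of:
                raise RuntimeError(f"CRE index {gi} assigned in two partitions")
            if regions[gi].chrom != chrom:
                raise RuntimeError(
                    f"CRE {gi} on {regions[gi].chrom} in partition for {chrom}"
                )
            if lab not in remap:
                counters[chrom] = counters.get(chrom, 0) + 1
                remap[lab] = f"{chrom}_m{counters[chrom]}"
            module_of[gi] = remap[lab]
    for gi, iv in enumerate(regions):
        if gi not in module_of:
            counters[iv.chrom] = counters.get(iv.chrom, 0) + 1
            module_of[gi] = f"{iv.chrom}_m{counters[iv.chrom]}"

    labels = [module_of[i] for i in range(len(regions))]
    members: dict[str, list[int]] = {}
    for i, m in enumerate(labels):
        members.setdefault(m, []).append(i)
    rows = []
    for m, idx in members.items():
        if len(idx) > 1:
            dists = [
                pairwise_distance(regions[a], regions[b])
                for a, b in combinations(idx, 2)
            ]
            mean_dist = float(np.mean(dists))
        else:
            mean_dist = 0.0
        rows.append((m, len(idx), mean_dist))
    stats = pd.DataFrame(
        rows, columns=["module", "size", "mean_pairwise_distance"]
    ).set_index("module")
    return ModuleSet(
        cre_ids=[_cre_id(iv) for iv in regions], labels=labels, stats=stats
    )


def discover_modules(
    signal,
    pseudobulk,
    regions: RegionSet,
    contact_maps: Mapping[str, ContactMap] | None = None,
    clip_quantile: float = 0.90,
    n_pcs: int = 50,
    knn: int = 50,
    top_k: int = 30,
    resolution: float = 0.5,
    candidate_window: float = DEFAULT_CANDIDATE_WINDOW,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
) -> ModuleSet:
    """End-to-end module discovery.

    ``signal`` (CRE x experiment) drives broad clustering; ``pseudobulk``
    (CRE x cell cluster) provides co-accessibility; both must align
    row-wise with ``regions``.  Returns a total :class:`ModuleSet`.
    """
    signal = np.asarray(signal, dtype=float)
    pb = np.asarray(pseudobulk, dtype=float)
    if signal.shape[0] != len(regions) or pb.shape[0] != len(regions):
        raise ValueError("signal and pseudobulk rows must align with regions")
    broad = broad_cluster(
        signal, clip_quantile=clip_quantile, n_pcs=n_pcs, knn=knn, seed=seed
    )
    contact_maps = contact_maps or {}
    partitions = []
    for chrom in regions.chroms:
        cmap = contact_maps.get(chrom)
        chrom_mask = np.array([iv.chrom == chrom for iv in regions])
        for label in np.unique(broad[chrom_mask]):
            idx = np.where(chrom_mask & (broad == label))[0]
            if len(idx) < 2:
                continue
            sub_regions = [regions[int(i)] for i in idx]
            pairs = score_pairs(
                pb[idx],
                sub_regions,
                contact_map=cmap,
                candidate_window=candidate_window,
                sigma=sigma,
            )
            if not pairs:
                continue
            graph = build_topk_graph(pairs, n_nodes=len(idx), k=top_k)
            local = leiden_cpm(graph, resolution=resolution, seed=seed)
            partitions.append((chrom, [int(i) for i in idx], list(local)))
    return assemble_modules(partitions, regions)
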