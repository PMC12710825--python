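"""Module annotation with cell-type specificity and ontology-term enrichment.

Two workflows live here.

*Module annotation* scores each module against each cell type: pseudobulk
accessibilities are binarized at the 90% cumulative-sum threshold per
cell type, the tau specificity index is computed per CRE from the binary
matrix, accessibilities are transformed to per-cell-type deciles, and
each (module, cell type) score is the tau-weighted sum of member-CRE
deciles.  Duplicate cell types (the same ontology term observed in
several tissues) are averaged, and each module keeps its top 5 terms
provided their score clears the global retention cutoff (the 10th
percentile of all scores, i.e. the upper 90%).

*Cluster annotation* ranks modules per cell cluster by a signed
significance score r = sign(log2FC) * (-log10 p) from differential
accessibility results and runs preranked set enrichment (classic
weighted Kolmogorov-Smirnov statistic, permutation null, sign-matched
NES, Benjamini-Hochberg adjustment) against the module sets of each
ontology term.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300


def binarize_cumsum(values, target: float = 0.90) -> tuple[np.ndarray, float]:
    """Binarize one cell type's accessibility at the cumulative-sum threshold.

    Values are sorted descending and the threshold is the value at which
    the running cumulative sum first reaches ``target`` times the total.
    Entries >= threshold map to 1 (ties at the threshold are all set to
    1).  A zero total yields an all-zero vector.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("accessibilities must be non-negative")
    total = v.sum()
    if total == 0:
        return np.zeros(len(v), dtype=int), 0.0
    desc = np.sort(v)[::-1]
    idx = int(np.searchsorted(np.cumsum(desc), target * total))
    threshold = float(desc[min(idx, len(desc) - 1)])
    return (v >= threshold).astype(int), threshold


def tau_index(binarized) -> np.ndarray:
    """Tau specificity index per CRE from a CRE-by-cell-type binary matrix.

    tau = sum_i (1 - x_i) / (N - 1) with N cell types; 1 means the CRE
    is accessible in exactly one cell type, 0 in all of them.  CREs
    binarized to zero everywhere carry no specificity evidence and are
    assigned tau = 0 (they contribute nothing to downstream weighted
    sums).
    """
    X = np.asarray(binarized)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 cell types")
    n_ct = X.shape[1]
    on = X.sum(axis=1)
    tau = (n_ct - on) / (n_ct - 1)
    tau[on == 0] = 0.0
    return tau.astype(float)


def decile_transform(values) -> np.ndarray:
    """Map one cell type's accessibilities to decile values in {0, 0.1, ..., 1}.

    Zeros map to 0; nonzero values are ranked ascending (average ranks
    for ties) and mapped to ceil(10 * rank / n_nonzero) / 10.
    """
    v = np.asarray(values, dtype=float)
    out = np.zeros(len(v))
    nz = v != 0
    if nz.any():
        ranks = rankdata(v[nz], method="average")
        out[nz] = np.ceil(10.0 * ranks / nz.sum()) / 10.0
    return out


def module_celltype_scores(
    deciles: pd.DataFrame,
    tau: np.ndarray | pd.Series,
    modules: Mapping[str, str] | pd.Series,
    celltype_to_term: Mapping[str, str],
    top_n: int = 5,
    retain_quantile: float = 0.10,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Tau-weighted module-by-term scores and top-term assignments.

    ``deciles`` is CRE-by-cell-type (rows indexed by CRE id), ``tau`` the
    per-CRE specificity weights aligned with its rows, and ``modules``
    maps CRE id -> module id.  score(m, ct) = sum over member CREs of
    tau * decile; columns mapping to the same ontology term are averaged.
    Per module the ``top_n`` highest-scoring terms are kept when their
    score is strictly above the global ``retain_quantile`` quantile of
    all (module, term) scores (the "upper 90%" of scores).
    """
    tau = np.asarray(tau, dtype=float)
    if len(tau) != len(deciles):
        raise ValueError("tau must align with decile rows")
    modules = pd.Series(dict(modules) if not isinstance(modules, pd.Series) else modules)
    if not set(deciles.index) <= set(modules.index):
        raise ValueError("every CRE in deciles needs a module assignment")
    weighted = deciles.mul(tau, axis=0)
    per_module = weighted.groupby(modules.reindex(deciles.index)).sum()
    if per_module.empty:
        raise RuntimeError("empty module encountered")
    terms = pd.Index([celltype_to_term[c] for c in per_module.columns], name="term")
    scores = per_module.T.groupby(terms).mean().T

    cutoff = float(np.quantile(scores.to_numpy().ravel(), retain_quantile))
    assigned: dict[str, list[str]] = {}
    for m, row in scores.iterrows():
        ranked = row.sort_values(ascending=False, kind="stable")
        keep = [t for t, s in ranked.items() if s > cutoff][:top_n]
        assigned[str(m)] = keep
    return scores, assigned


def signed_score(log2fc, p) -> np.ndarray | float:
    """Signed significance r = sign(log2FC) * (-log10 p), p floored at 1e-300."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p > 1):
        raise ValueError("p-values must be <= 1")
    if np.any(p <= 0):
        warnings.warn("p-values <= 0 floored at 1e-300", stacklevel=2)
    p = np.clip(p, P_FLOOR, 1.0)
    r = np.sign(log2fc) * (-np.log10(p))
    return float(r) if r.ndim == 0 else r


def _enrichment_scores(
    weights_sorted: np.ndarray, hit_matrix: np.ndarray
) -> np.ndarray:
    """Weighted KS enrichment score for each row of a boolean hit matrix.

    ``weights_sorted`` are |r| in ranking order; each row of
    ``hit_matrix`` marks the member positions of one set.  The ES is the
    running-sum deviation of maximal magnitude.
    """
    n = len(weights_sorted)
    hits = hit_matrix.astype(float) * weights_sorted
    hit_totals = hits.sum(axis=1, keepdims=True)
    set_sizes = hit_matrix.sum(axis=1, keepdims=True)
    miss_step = 1.0 / np.maximum(n - set_sizes, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hit = np.where(hit_totals > 0, np.cumsum(hits, axis=1) / hit_totals, 0.0)
    p_miss = np.cumsum((~hit_matrix) * miss_step, axis=1)
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    es = dev[np.arange(dev.shape[0]), idx]
    es[np.ravel(hit_totals) == 0] = 0.0
    return es


def preranked_enrichment(
    ranked: pd.Series,
    term_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    padj_cutoff: float | None = 0.05,
) -> pd.DataFrame:
    """Preranked set enrichment over module ranks.

    ``ranked`` maps module id -> signed score r (the ranking universe,
    e.g. restricted to a dataset's variable features); ``term_sets`` maps
    each ontology term to its module set.  The enrichment score is the
    weighted KS running-sum statistic with weight |r|; the null comes
    from ``n_perm`` random same-size module sets; NES divides the ES by
    the mean |null ES| of matching sign and the permutation p-value is
    estimated among matching-sign nulls.  Results are BH-adjusted across
    terms, sorted by NES (decreasing) then adjusted p (increasing), and
    filtered to padj <= ``padj_cutoff`` unless it is None.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if len(ranked) == 0:
        raise ValueError("empty ranking universe")
    rng = np.random.default_rng(seed)
    order = np.argsort(-ranked.to_numpy(), kind="stable")
    universe = ranked.index.to_numpy()[order]
    weights = np.abs(ranked.to_numpy()[order])
    pos_of = {m: i for i, m in enumerate(universe)}
    n = len(universe)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for term, members in term_sets.items():
        positions = sorted(pos_of[m] for m in members if m in pos_of)
        if not positions:
            continue
        size = len(positions)
        hit = np.zeros((1, n), dtype=bool)
        hit[0, positions] = True
        es = float(_enrichment_scores(weights, hit)[0])
        if size not in null_cache:
            perm_hits = np.zeros((n_perm, n), dtype=bool)
            draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
            perm_hits[np.arange(n_perm)[:, None], draws] = True
            null_cache[size] = _enrichment_scores(weights, perm_hits)
        null = null_cache[size]
        same_sign = null * np.sign(es) > 0 if es != 0 else np.zeros(n_perm, bool)
        n_same = int(same_sign.sum())
        if es == 0 or n_same == 0:
            nes, pval = 0.0, 1.0
        else:
            nes = es / float(np.mean(np.abs(null[same_sign])))
            exceed = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
            pval = (exceed + 1) / (n_same + 1)
        rows.append((term, size, es, nes, pval))
    if not rows:
        raise ValueError("no term set intersects the ranking universe")
    res = pd.DataFrame(rows, columns=["term", "size", "es", "nes", "pval"])
    res["padj"] = multipletests(res["pval"], method="fdr_bh")[1]
    res = res.sort_values(["nes", "padj"], ascending=[False, True], kind="stable")
    if padj_cutoff is not None:
        res = res[res["padj"] <= padj_cutoff]
    return res.reset_index(drop=True)


def annotate_clusters(
    diff_results: Mapping[str, pd.DataFrame],
    term_sets: Mapping[str, Iterable[str]],
    variable_modules: Iterable[str] | None = None,
    tissue: str | None = None,
    tissue_terms: Mapping[str, Sequence[str]] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    padj_cutoff: float | None = 0.05,
) -> dict[str, list[str]]:
    """Ordered enriched ontology terms per cell cluster.

    ``diff_results`` maps cluster id -> DataFrame with columns
    ``module``, ``log2fc`` and ``pval``.  Modules are ranked by the
    signed significance score (restricted to ``variable_modules`` when
    given) and tested against ``term_sets`` — limited to the terms of
    ``tissue`` when a tissue and a tissue -> terms mapping are supplied.
    """
    if tissue is not None:
        if tissue_terms is None or tissue not in tissue_terms:
            raise ValueError(f"tissue {tissue!r} not present in tissue mapping")
        allowed = set(tissue_terms[tissue])
        term_sets = {t: s for t, s in term_sets.items() if t in allowed}
        if not term_sets:
            raise ValueError(f"no term sets remain for tissue {tissue!r}")
    out: dict[str, list[str]] = {}
    for cluster, table in diff_results.items():
        sub = table
        if variable_modules is not None:
            sub = sub[sub["module"].isin(set(variable_modules))]
        ranked = pd.Series(
            signed_score(sub["log2fc"].to_numpy(), sub["pval"].to_numpy()),
            index=sub["module"].to_numpy(),
        )
        res = preranked_enrichment(
            ranked, term_sets, n_perm=n_perm, seed=seed, padj_cutoff=padj_cutoff
        )
        out[str(cluster)] = list(res["term"])
    return out


def annotation_accuracy(
    predictions: Mapping[str, Sequence[str]],
    reference: Mapping[str, str],
    top: int = 1,
) -> float:
    """Fraction of clusters whose reference term is within the top-k predictions."""
    if not reference:
        raise ValueError("empty reference")
    hits = sum(
        1
        for cluster, truth in reference.items()
        if truth in list(predictions.get(cluster, []))[:top]
    )
    return hits / len(reference)
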