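"""Correlation-based CRE-gene linkage and the module-level statistics built on it.

``link_peaks`` scores candidate CRE-gene pairs by the Pearson
correlation between CRE accessibility and gene expression across cells,
standardized against a background of CREs matched on mean accessibility.
``same_gene_logit`` asks whether two linked CREs regulating the same
gene are more likely to sit in the same module, controlling for genomic
distance with a logistic regression per chromosome::

    ln(p / (1 - p)) = b0 + b1 * log(d_ij) + b2 * X_samegene

``single_module_unlinked_ratio`` compares P(unlinked | single-CRE
module) with the base rate P(unlinked) from the 2x2 frequency table.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .discovery import ModuleSet
from .intervals import RegionSet

LINK_COLUMNS = ["cre", "gene", "pearson_r", "zscore", "pval"]


def _standardize_cells(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.zeros_like(X, dtype=float)
    ok = (sd > 0).ravel()
    Z[ok] = (X[ok] - mu[ok]) / sd[ok]
    return Z


def link_peaks(
    accessibility: pd.DataFrame,
    regions: RegionSet,
    expression: pd.DataFrame,
    tss: pd.DataFrame,
    distance: float = 5e5,
    min_distance: float = 500,
    min_cells: int = 10,
    n_background: int = 200,
    n_bins: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation-based CRE-gene links with a matched-background z-score.

    Parameters
    ----------
    accessibility
        CRE-by-cell normalized accessibility; rows align with ``regions``.
    expression
        Gene-by-cell normalized expression over the same cells (columns
        must match).
    tss
        DataFrame with columns ``gene``, ``chrom``, ``position`` — one
        row per transcript TSS; all transcripts of a gene are considered.
    distance, min_distance
        A CRE is a candidate for a gene when its midpoint lies within
        ``distance`` of at least one of the gene's TSS but at least
        ``min_distance`` from every TSS.
    min_cells
        CREs detected in fewer cells are skipped.
    n_background
        Background CREs sampled per candidate from the same
        mean-accessibility decile bin; the z-score standardizes the
        observed correlation against this null.

    Returns one row per tested (cre, gene) pair with Pearson r, z and a
    two-sided normal p-value.  Genes with no candidate CRE are omitted.
    """
    if list(accessibility.columns) != list(expression.columns):
        raise ValueError("accessibility and expression must share cell barcodes")
    if len(accessibility) != len(regions):
        raise ValueError("accessibility rows must align with regions")
    rng = np.random.default_rng(seed)
    A = accessibility.to_numpy(dtype=float)
    E = expression.to_numpy(dtype=float)
    n_cells = A.shape[1]
    Za = _standardize_cells(A)
    Ze = _standardize_cells(E)
    detected = (A > 0).sum(axis=1)
    mean_acc = A.mean(axis=1)
    # mean-accessibility decile bins for background matching
    ranks = scipy.stats.rankdata(mean_acc, method="average")
    bins = np.ceil(n_bins * ranks / len(ranks)).astype(int)
    bin_members = {b: np.where(bins == b)[0] for b in np.unique(bins)}
    mids = np.array([iv.midpoint for iv in regions])
    chroms = np.array([iv.chrom for iv in regions])
    gene_rows = {g: i for i, g in enumerate(expression.index)}

    rows = []
    for gene, sub in tss.groupby("gene", sort=True):
        gi = gene_rows.get(gene)
        if gi is None:
            continue
        cand_mask = np.zeros(len(regions), dtype=bool)
        too_close = np.zeros(len(regions), dtype=bool)
        for _, t in sub.iterrows():
            on_chrom = chroms == t["chrom"]
            d = np.abs(mids - float(t["position"]))
            cand_mask |= on_chrom & (d <= distance)
            too_close |= on_chrom & (d < min_distance)
        cand = np.where(cand_mask & ~too_close & (detected >= min_cells))[0]
        for ci in cand:
            r = float(Za[ci] @ Ze[gi]) / n_cells
            pool = bin_members[bins[ci]]
            pool = pool[pool != ci]
            if len(pool) == 0:
                continue
            replace = len(pool) < n_background
            bg = rng.choice(pool, size=n_background, replace=replace)
            null_r = (Za[bg] @ Ze[gi]) / n_cells
            mu, sd = float(null_r.mean()), float(null_r.std())
            z = (r - mu) / sd if sd > 0 else 0.0
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            cre_id = (
                regions[int(ci)].name
                or f"{regions[int(ci)].chrom}:{regions[int(ci)].start}-{regions[int(ci)].end}"
            )
            rows.append((cre_id, gene, r, z, p))
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def combine_links(tables: Iterable[pd.DataFrame], p_cutoff: float = 0.05) -> pd.DataFrame:
    """Combine per-dataset link tables: keep significant links, max r per pair.

    For each (cre, gene) pair the row with the highest Pearson r among
    significant (p < ``p_cutoff``) entries is kept, carrying that
    dataset's p-value.
    """
    merged = pd.concat(list(tables), ignore_index=True)
    merged = merged[merged["pval"] < p_cutoff]
    idx = merged.groupby(["cre", "gene"])["pearson_r"].idxmax()
    return merged.loc[idx].reset_index(drop=True)


def linked_gene_sets(links: pd.DataFrame) -> dict[str, set[str]]:
    """Map CRE id -> set of linked genes from a link table."""
    out: dict[str, set[str]] = {}
    for cre, gene in zip(links["cre"], links["gene"]):
        out.setdefault(str(cre), set()).add(str(gene))
    return out


def cre_pair_table(
    modules: ModuleSet,
    links: pd.DataFrame,
    regions: RegionSet,
    max_dist: float = 1e6,
) -> pd.DataFrame:
    """Pairs of linked CREs within ``max_dist`` with model covariates.

    CREs not linked to any gene are excluded.  Columns: chrom, log_dist
    (natural log, distance floored at 1 bp), same_gene (linked gene sets
    share >= 1 element), same_module.
    """
    gene_sets = linked_gene_sets(links)
    assignment = modules.assignment
    linked_idx = [
        i for i, cid in enumerate(modules.cre_ids) if cid in gene_sets
    ]
    mids = np.array([regions[i].midpoint for i in linked_idx])
    chroms = np.array([regions[i].chrom for i in linked_idx])
    rows = []
    order = np.lexsort((mids, chroms))
    for a_pos in range(len(order)):
        a = order[a_pos]
        for b_pos in range(a_pos + 1, len(order)):
            b = order[b_pos]
            if chroms[b] != chroms[a]:
                break
            d = abs(mids[b] - mids[a])
            if d > max_dist:
                break
            ia, ib = linked_idx[a], linked_idx[b]
            ca, cb = modules.cre_ids[ia], modules.cre_ids[ib]
            rows.append(
                (
                    chroms[a],
                    float(np.log(max(d, 1.0))),
                    int(bool(gene_sets[ca] & gene_sets[cb])),
                    int(assignment[ca] == assignment[cb]),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "log_dist", "same_gene", "same_module"])


def fit_pair_model(pairs: pd.DataFrame) -> dict:
    """Fit the same-module logistic model on one chromosome's pair table.

    Returns coefficients, the Wald p-value and odds ratio for the
    same-gene term, and a ``separated`` flag for degenerate fits.
    """
    y = pairs["same_module"].to_numpy(dtype=float)
    X = sm.add_constant(pairs[["log_dist", "same_gene"]].to_numpy(dtype=float))
    if len(np.unique(y)) < 2:
        return {
            "beta0": np.nan, "beta1": np.nan, "beta2": np.nan,
            "beta2_se": np.nan, "beta2_pval": np.nan, "odds_ratio": np.nan,
            "n_pairs": len(pairs), "separated": True,
        }
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = fit.params
        separated = bool(np.any(~np.isfinite(fit.bse)) or np.any(np.abs(params) > 50))
        return {
            "beta0": float(params[0]),
            "beta1": float(params[1]),
            "beta2": float(params[2]),
            "beta2_se": float(fit.bse[2]),
            "beta2_pval": float(fit.pvalues[2]),
            "odds_ratio": float(np.exp(params[2])),
            "n_pairs": len(pairs),
            "separated": separated,
        }
    except Exception:
        return {
            "beta0": np.inf, "beta1": np.inf, "beta2": np.inf,
            "beta2_se": np.nan, "beta2_pval": np.nan, "odds_ratio": np.inf,
            "n_pairs": len(pairs), "separated": True,
        }


def same_gene_logit(
    modules: ModuleSet | None = None,
    links: pd.DataFrame | None = None,
    regions: RegionSet | None = None,
    max_dist: float = 1e6,
    pair_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-chromosome logistic regression of same-module on same-gene.

    Either pass (``modules``, ``links``, ``regions``) to enumerate
    linked-CRE pairs within ``max_dist``, or a prebuilt ``pair_table``
    with columns chrom, log_dist, same_gene, same_module.  Returns one
    row per chromosome with coefficients, the same-gene Wald p-value and
    odds ratio exp(b2).
    """
    if pair_table is None:
        if modules is None or links is None or regions is None:
            raise ValueError("need modules, links and regions (or a pair_table)")
        pair_table = cre_pair_table(modules, links, regions, max_dist=max_dist)
    results = []
    for chrom, sub in pair_table.groupby("chrom", sort=True):
        if len(sub) < 2:
            continue
        res = fit_pair_model(sub)
        res["chrom"] = chrom
        results.append(res)
    if not results:
        raise ValueError("no chromosome with at least 2 linked-CRE pairs")
    out = pd.DataFrame(results).set_index("chrom")
    return out


def single_module_unlinked_ratio(
    modules: ModuleSet, linked_cres: Iterable[str]
) -> float:
    """P(unlinked | single-CRE module) / P(unlinked) from the 2x2 table."""
    linked = set(linked_cres)
    sizes = modules.stats["size"]
    single_modules = set(sizes.index[sizes == 1])
    n_total = len(modules.cre_ids)
    is_single = np.array([m in single_modules for m in modules.labels])
    is_unlinked = np.array([c not in linked for c in modules.cre_ids])
    n_single = int(is_single.sum())
    n_unlinked = int(is_unlinked.sum())
    if n_single == 0:
        raise ValueError("no single-CRE modules")
    if n_unlinked == 0:
        raise ValueError("no unlinked CREs: base probability is zero")
    p_unlinked = n_unlinked / n_total
    p_unlinked_given_single = float((is_single & is_unlinked).sum()) / n_single
    return p_unlinked_given_single / p_unlinked
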