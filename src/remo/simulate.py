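"""Synthetic planted-structure data for every pipeline input.

``generate_world`` builds a fully synthetic genome of CREs organised
into planted modules, together with every file the pipeline consumes:
per-cell-type accessibility profiles (the pseudobulk matrix), a
ChIP-like CRE-by-experiment signal matrix, single-cell fragment
records, binned contact tables with elevated within-module contacts,
gene TSS and expression with planted CRE-gene links, and ontology
term mappings.  All stochastic draws flow from one seed; per-component
child seeds are derived deterministically so outputs are reproducible.

The planted world emulates lineage-specific regulation: each module has
one *primary* cell type in which its CREs are distinctly most
accessible (intensity 2 + Gamma(3, 1)), plus secondary on-cell-types
(probability 0.25, intensity Gamma(2, 0.5)).  Modules within a
chromosome are separated by >1.1 Mb so planted structure is genomically
distinct, while CREs within a module are spaced uniform(5 kb, 250 kb).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import TABLE_COLUMNS
from .fragments import SparseCountMatrix
from .intervals import FragmentRecord, GenomicInterval, RegionSet, write_bed, write_fragments


@dataclass
class PlantedWorld:
    """All synthetic inputs plus the planted ground truth."""

    seed: int
    celltypes: list[str]
    celltype_terms: dict[str, str]
    tissue_terms: dict[str, list[str]]
    regions: RegionSet  # name = CRE id, group = planted module id
    module_assignment: pd.Series  # CRE id -> planted module id
    module_primary: dict[str, str]  # module id -> primary cell type
    accessibility: pd.DataFrame  # CRE x cell type (pseudobulk ground truth)
    signal: pd.DataFrame  # CRE x ChIP-like experiment
    cells: pd.Series  # barcode -> cell type
    fragments: list[FragmentRecord]
    contact_tables: list[pd.DataFrame]
    tss: pd.DataFrame  # gene, chrom, position
    expression: SparseCountMatrix  # gene x cell counts
    gene_links: dict[str, list[str]]  # gene -> planted linked CRE ids

    @property
    def term_sets(self) -> dict[str, list[str]]:
        """Planted ontology term -> module ids with that primary cell type."""
        out: dict[str, list[str]] = {}
        for module, ct in self.module_primary.items():
            out.setdefault(self.celltype_terms[ct], []).append(module)
        return out


def generate_world(
    n_celltypes: int = 10,
    n_modules: int = 200,
    cres_per_module: int = 4,
    n_cells: int = 200,
    mean_frags_per_cell: float = 500.0,
    noise_sd: float = 0.05,
    seed: int = 7,
    modules_per_chrom: int = 25,
    cre_width: int = 400,
    bin_size: int = 5_000,
    n_chip_per_celltype: int = 3,
    n_contact_datasets: int = 2,
    profile_mode: str = "primary",
    max_chrom_length: int = 250_000_000,
) -> PlantedWorld:
    """Generate a planted world; see the module docstring for the model.

    ``profile_mode`` is ``"primary"`` (default: primary cell type plus
    random secondary on-types) or ``"one_hot"`` (each module accessible
    in exactly one cell type — disjoint profiles, useful with
    ``noise_sd=0`` for exact-recovery checks).
    """
    for name, v in [
        ("n_celltypes", n_celltypes), ("n_modules", n_modules),
        ("cres_per_module", cres_per_module), ("n_cells", n_cells),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be positive, got {v}")
    if profile_mode not in ("primary", "one_hot"):
        raise ValueError(f"unknown profile_mode {profile_mode!r}")
    ss = np.random.SeedSequence(seed)
    (
        rng_geom, rng_prof, rng_noise, rng_chip,
        rng_cells, rng_frag, rng_contact, rng_expr,
    ) = [np.random.default_rng(s) for s in ss.spawn(8)]

    celltypes = [f"celltype_{i:02d}" for i in range(n_celltypes)]
    celltype_terms = {ct: f"CL:{9000000 + i:07d}" for i, ct in enumerate(celltypes)}
    half = max(1, n_celltypes // 2)
    tissue_terms = {
        "tissue_a": [celltype_terms[ct] for ct in celltypes[:half]],
        "tissue_b": [celltype_terms[ct] for ct in celltypes[half:]],
    }

    # --- geometry ------------------------------------------------------
    intervals: list[GenomicInterval] = []
    module_ids: list[str] = []
    module_of_cre: list[str] = []
    module_members: dict[str, list[int]] = {}
    n_chroms = int(np.ceil(n_modules / modules_per_chrom))
    m = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = 100_000
        for _ in range(min(modules_per_chrom, n_modules - m)):
            module = f"{chrom}_p{len(module_members) + 1}"
            module_ids.append(module)
            module_members[module] = []
            mid = cursor
            for k in range(cres_per_module):
                if mid + cre_width // 2 > max_chrom_length:
                    raise ValueError(
                        f"module {module} exceeds chromosome length {max_chrom_length}"
                    )
                cre_idx = len(intervals)
                intervals.append(
                    GenomicInterval(
                        chrom,
                        mid - cre_width // 2,
                        mid + cre_width // 2,
                        name=f"cre_{cre_idx:05d}",
                        group=module,
                    )
                )
                module_of_cre.append(module)
                module_members[module].append(cre_idx)
                if k < cres_per_module - 1:
                    mid += int(rng_geom.uniform(5_000, 250_000))
            cursor = mid + int(rng_geom.uniform(1_100_000, 1_600_000))
            m += 1
    regions = RegionSet(intervals)
    cre_ids = [iv.name for iv in intervals]
    n_cres = len(intervals)

    # --- planted accessibility profiles --------------------------------
    module_primary: dict[str, str] = {}
    profiles = np.zeros((n_modules, n_celltypes))
    for mi, module in enumerate(module_ids):
        primary = int(rng_prof.integers(n_celltypes))
        module_primary[module] = celltypes[primary]
        if profile_mode == "one_hot":
            profiles[mi, primary] = 3.0
        else:
            profiles[mi, primary] = 2.0 + rng_prof.gamma(3.0, 1.0)
            secondary = rng_prof.random(n_celltypes) < 0.25
            secondary[primary] = False
            profiles[mi, secondary] = rng_prof.gamma(2.0, 0.5, size=int(secondary.sum()))

    module_index = {module: i for i, module in enumerate(module_ids)}
    base = profiles[[module_index[module] for module in module_of_cre]]
    accessibility = base + rng_noise.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else base.copy()
    accessibility = np.clip(accessibility, 0.0, None)
    acc_df = pd.DataFrame(accessibility, index=cre_ids, columns=celltypes)

    # --- ChIP-like signal matrix ---------------------------------------
    exp_cols, exp_names = [], []
    for ct_i, ct in enumerate(celltypes):
        for rep in range(n_chip_per_celltype):
            depth = float(np.exp(rng_chip.normal(0.0, 0.3)))
            col = accessibility[:, ct_i] * depth
            if noise_sd > 0:
                col = col + rng_chip.normal(0.0, noise_sd, size=n_cres)
            exp_cols.append(np.clip(col, 0.0, None))
            exp_names.append(f"{ct}_chip_{rep}")
    signal = pd.DataFrame(np.column_stack(exp_cols), index=cre_ids, columns=exp_names)

    # --- cells and fragments -------------------------------------------
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    cell_ct = rng_cells.integers(n_celltypes, size=n_cells)
    cells = pd.Series([celltypes[i] for i in cell_ct], index=barcodes, name="celltype")
    ct_sums = accessibility.sum(axis=0)
    lam = np.zeros((n_cres, n_cells))
    for j in range(n_cells):
        s = ct_sums[cell_ct[j]]
        if s > 0:
            lam[:, j] = accessibility[:, cell_ct[j]] * (mean_frags_per_cell / s)
    counts = rng_frag.poisson(lam)
    fragments: list[FragmentRecord] = []
    for i in range(n_cres):
        nz = np.nonzero(counts[i])[0]
        if len(nz) == 0:
            continue
        iv = intervals[i]
        mid = int(iv.midpoint)
        for j in nz:
            start = int(rng_frag.integers(iv.start, mid))
            end = int(rng_frag.integers(mid + 1, iv.end + 1))
            fragments.append(
                FragmentRecord(iv.chrom, start, end, barcodes[j], int(counts[i, j]))
            )

    # --- contact tables --------------------------------------------------
    mids = np.array([iv.midpoint for iv in intervals])
    pair_bins: list[tuple[str, int, int, bool]] = []
    seen = set()
    for module, members in module_members.items():
        chrom = intervals[members[0]].chrom
        for a in range(len(members)):
            for b in range(a, len(members)):
                ia, ib = members[a], members[b]
                if abs(mids[ib] - mids[ia]) > 1_000_000:
                    continue
                bi = int(mids[ia] // bin_size) * bin_size
                bj = int(mids[ib] // bin_size) * bin_size
                key = (chrom, min(bi, bj), max(bi, bj))
                if key not in seen:
                    seen.add(key)
                    pair_bins.append((*key, True))
        # background pairs near the module, baseline intensity
        bi = int(mids[members[0]] // bin_size) * bin_size
        for off in (10, 50, 120):
            key = (chrom, bi, bi + off * bin_size)
            if key not in seen:
                seen.add(key)
                pair_bins.append((*key, False))
    contact_tables = []
    for _ in range(n_contact_datasets):
        oe = rng_contact.exponential(1.0, size=len(pair_bins))
        oe = oe * np.where([w for *_, w in pair_bins], 5.0, 1.0)
        contact_tables.append(
            pd.DataFrame(
                [(c, i, j) for c, i, j, _ in pair_bins],
                columns=TABLE_COLUMNS[:3],
            ).assign(oe=oe)
        )

    # --- genes, TSS, expression ------------------------------------------
    genes, tss_rows, gene_links = [], [], {}
    for module, members in module_members.items():
        gene = f"gene_{module}"
        genes.append(gene)
        first = intervals[members[0]]
        tss_pos = max(int(first.midpoint) - 10_000, 1_000)
        tss_rows.append((gene, first.chrom, tss_pos))
        linked = [
            intervals[i].name
            for i in members
            if abs(mids[i] - tss_pos) <= 5e5 and abs(mids[i] - tss_pos) >= 500
        ]
        gene_links[gene] = linked
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "position"])
    cre_row = {cid: i for i, cid in enumerate(cre_ids)}
    expr_lam = np.zeros((len(genes), n_cells))
    for gi, gene in enumerate(genes):
        linked_rows = [cre_row[c] for c in gene_links[gene]]
        if linked_rows:
            per_ct = accessibility[linked_rows].mean(axis=0)
            expr_lam[gi] = 10.0 * per_ct[cell_ct]
    expr_counts = rng_expr.poisson(expr_lam)
    expression = SparseCountMatrix(
        genes, barcodes, sp.csr_matrix(expr_counts.astype(np.int64))
    )

    return PlantedWorld(
        seed=seed,
        celltypes=celltypes,
        celltype_terms=celltype_terms,
        tissue_terms=tissue_terms,
        regions=regions,
        module_assignment=pd.Series(module_of_cre, index=cre_ids, name="module"),
        module_primary=module_primary,
        accessibility=acc_df,
        signal=signal,
        cells=cells,
        fragments=fragments,
        contact_tables=contact_tables,
        tss=tss,
        expression=expression,
        gene_links=gene_links,
    )


def emit_inputs(world: PlantedWorld, directory) -> dict[str, Path]:
    """Write every pipeline input format to ``directory``; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fragments"] = d / "fragments.tsv.gz"
    write_fragments(world.fragments, paths["fragments"])

    paths["cres_bed"] = d / "cres.bed"
    write_bed(world.regions, paths["cres_bed"])

    paths["modules_bed"] = d / "modules_truth.bed"
    write_bed(world.regions, paths["modules_bed"], group_as_name=True)

    for k, table in enumerate(world.contact_tables):
        p = d / f"contacts_{k}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"contacts_{k}"] = p

    paths["signal"] = d / "chip_signal.tsv"
    world.signal.to_csv(paths["signal"], sep="\t")

    paths["pseudobulk"] = d / "pseudobulk.tsv"
    world.accessibility.to_csv(paths["pseudobulk"], sep="\t")

    paths["cells"] = d / "cells.tsv"
    world.cells.to_csv(paths["cells"], sep="\t")

    paths["expression"] = d / "expression"
    world.expression.write(paths["expression"])

    paths["tss"] = d / "tss.tsv"
    world.tss.to_csv(paths["tss"], sep="\t", index=False)

    for name, payload in [
        ("celltype_terms", world.celltype_terms),
        ("term_sets", world.term_sets),
        ("tissue_terms", world.tissue_terms),
    ]:
        p = d / f"{name}.json"
        p.write_text(json.dumps(payload, indent=1, sort_keys=True))
        paths[name] = p
    return paths
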