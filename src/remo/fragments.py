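"""Fragment-file quantification: barcode counting, feature matrices, QC.

Re-implements the fragment-file toolkit workflow: counting total
fragments per cell barcode, building feature-by-cell count matrices with
either insertion counting or paired insertion counting (PIC), filtering
fragment files by barcode inclusion lists, and per-cell QC metrics.

Counting semantics
------------------
Each fragment contributes two Tn5 insertion sites: ``start`` and
``end - 1``.  In *insertion* mode every insertion site falling inside a
region adds the record's duplicate count to that (region, barcode) cell,
so a fragment fully inside a region contributes twice.  In *pic* mode a
fragment is counted at most once per region: the record's count is added
when at least one of its two insertion sites falls in the region.  With
grouped quantification the features are the distinct region group labels
and counts are summed over member regions (a fragment hitting two
regions of the same group in pic mode is counted once per region, then
summed).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .intervals import FragmentRecord, RegionSet


class RegionIndex:
    """Per-chromosome interval index with binary search on starts.

    Regions are sorted by start; a running maximum of end positions
    bounds the backwards scan, so point queries cost O(log n + hits)
    for typical (shallowly overlapping) region sets.
    """

    def __init__(self, regions: RegionSet):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(regions):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
        for chrom, items in per_chrom.items():
            items.sort()
            starts = [s for s, _, _ in items]
            ends = [e for _, e, _ in items]
            idx = [i for _, _, i in items]
            cummax = []
            m = 0
            for e in ends:
                m = max(m, e)
                cummax.append(m)
            self._by_chrom[chrom] = (starts, ends, idx)
            # store running max alongside
            self._cummax = getattr(self, "_cummax", {})
            self._cummax[chrom] = cummax

    def query_point(self, chrom: str, pos: int) -> list[int]:
        """Indices of regions containing ``pos`` (0-based) on ``chrom``."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, idx = entry
        cummax = self._cummax[chrom]
        j = bisect_right(starts, pos) - 1
        hits = []
        while j >= 0 and cummax[j] > pos:
            if ends[j] > pos:  # starts[j] <= pos guaranteed
                hits.append(idx[j])
            j -= 1
        return hits


@dataclass
class SparseCountMatrix:
    """Feature-by-barcode integer counts with name sidecars."""

    feature_ids: list[str]
    barcodes: list[str]
    matrix: sp.csr_matrix  # shape (n_features, n_barcodes)

    def __post_init__(self):
        if self.matrix.shape != (len(self.feature_ids), len(self.barcodes)):
            raise ValueError("matrix shape does not match id lists")

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def write(self, directory) -> None:
        """Write matrix.mtx (1-based coordinate integer) + sidecar TSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            directory / "matrix.mtx",
            self.matrix.tocoo(),
            field="integer",
            symmetry="general",
        )
        (directory / "features.tsv").write_text(
            "".join(f"{f}\n" for f in self.feature_ids)
        )
        (directory / "barcodes.tsv").write_text(
            "".join(f"{b}\n" for b in self.barcodes)
        )

    @classmethod
    def read(cls, directory) -> "SparseCountMatrix":
        directory = Path(directory)
        mat = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
        features = (directory / "features.tsv").read_text().splitlines()
        barcodes = (directory / "barcodes.tsv").read_text().splitlines()
        return cls(features, barcodes, mat)


def count_barcodes(
    fragments: Iterable[FragmentRecord],
    min_count: int | None = None,
    top_n: int | None = None,
) -> pd.Series:
    """Total fragments per cell barcode.

    At most one of ``min_count`` / ``top_n`` may be given.  ``top_n``
    keeps the n barcodes with the highest totals, ties broken
    lexicographically by barcode.  Totals sum the per-record duplicate
    count fields.
    """
    if min_count is not None and top_n is not None:
        raise ValueError("give at most one of min_count and top_n")
    if top_n is not None and top_n <= 0:
        raise ValueError(f"top_n must be positive, got {top_n}")
    totals: dict[str, int] = {}
    for rec in fragments:
        totals[rec.barcode] = totals.get(rec.barcode, 0) + rec.count
    items = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if min_count is not None:
        items = [(b, c) for b, c in items if c >= min_count]
    elif top_n is not None:
        items = items[:top_n]
    return pd.Series(
        [c for _, c in items], index=[b for b, _ in items], name="total_fragments", dtype=int
    )


def build_matrix(
    fragments: Iterable[FragmentRecord],
    regions: RegionSet,
    barcodes: Sequence[str],
    mode: str = "insertion",
    grouped: bool = False,
) -> SparseCountMatrix:
    """Quantify fragments against regions into a sparse count matrix.

    ``mode`` is ``"insertion"`` or ``"pic"`` (see module docstring).
    With ``grouped=True`` the feature ids are the distinct group labels
    of ``regions`` (all regions must then be labelled) and counts are
    summed over member regions.  Barcodes not in ``barcodes`` are
    ignored; overlapping regions each receive counts independently.
    """
    if mode not in ("insertion", "pic"):
        raise ValueError(f"mode must be 'insertion' or 'pic', got {mode!r}")
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    if len(barcodes) == 0:
        raise ValueError("barcode inclusion list must be non-empty")

    if grouped:
        group_of: list[str] = []
        for iv in regions:
            if iv.group is None:
                raise ValueError("grouped=True requires a group label on every region")
            group_of.append(iv.group)
        feature_ids = sorted(set(group_of))
        feat_idx = {g: i for i, g in enumerate(feature_ids)}
        region_to_feature = [feat_idx[g] for g in group_of]
    else:
        feature_ids = [
            iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in regions
        ]
        region_to_feature = list(range(len(regions)))

    bc_idx = {b: i for i, b in enumerate(barcodes)}
    index = RegionIndex(regions)
    acc: dict[tuple[int, int], int] = {}
    for rec in fragments:
        bi = bc_idx.get(rec.barcode)
        if bi is None:
            continue
        left, right = rec.insertions
        hits_left = index.query_point(rec.chrom, left)
        hits_right = index.query_point(rec.chrom, right)
        if mode == "insertion":
            region_hits: Iterable[int] = hits_left + hits_right
        else:  # pic: each region at most once per fragment
            region_hits = set(hits_left) | set(hits_right)
        for r in region_hits:
            key = (region_to_feature[r], bi)
            acc[key] = acc.get(key, 0) + rec.count

    if acc:
        rows, cols = zip(*acc.keys())
        data = list(acc.values())
    else:
        rows, cols, data = [], [], []
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(feature_ids), len(barcodes)), dtype=np.int64
    ).tocsr()
    return SparseCountMatrix(list(feature_ids), list(barcodes), mat)


def filter_fragments(
    fragments: Iterable[FragmentRecord], barcodes: Iterable[str]
):
    """Yield the ordered subsequence of records whose barcode is included."""
    keep = set(barcodes)
    for rec in fragments:
        if rec.barcode in keep:
            yield rec


# TSS enrichment window geometry (ENCODE-style definition): insertions in
# +/- 1000 bp windows around each TSS; signal = central +/- 100 bp,
# background = outermost 100 bp of each flank.
_TSS_WINDOW = 1000
_TSS_CENTRAL = 100
_TSS_FLANK = 100
_CENTRAL_BP = 2 * _TSS_CENTRAL + 1  # 201
_FLANK_BP = 2 * _TSS_FLANK  # 200


def qc_metrics(
    fragments: Iterable[FragmentRecord],
    tss: RegionSet,
    mito_chrom: str = "chrM",
) -> pd.DataFrame:
    """Per-barcode QC metrics.

    Returns a DataFrame indexed by barcode with columns
    ``total_fragments``, ``mito_fragments``, ``tss_enrichment`` and
    ``nucleosome_signal``.

    * TSS enrichment: mean insertion count per bp in the central
      +/-100 bp around TSS positions divided by the mean per bp in the
      outermost 100 bp of each +/-1000 bp flank.  A pseudocount of one
      insertion is added to the flank total so the score stays finite;
      0/0 is defined as 0.
    * Nucleosome signal: (fragments of length 147-294) / (fragments of
      length < 147), 0 when the denominator is 0.

    TSS entries are taken as 1-bp positions (interval start); strand is
    ignored.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for iv in tss:
        tss_by_chrom.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.asarray(sorted(p)) for c, p in tss_by_chrom.items()}

    total: dict[str, int] = {}
    mito: dict[str, int] = {}
    central: dict[str, int] = {}
    flank: dict[str, int] = {}
    short_frags: dict[str, int] = {}
    mono_frags: dict[str, int] = {}

    for rec in fragments:
        b = rec.barcode
        total[b] = total.get(b, 0) + rec.count
        if rec.chrom == mito_chrom:
            mito[b] = mito.get(b, 0) + rec.count
        if rec.length < 147:
            short_frags[b] = short_frags.get(b, 0) + rec.count
        elif rec.length <= 294:
            mono_frags[b] = mono_frags.get(b, 0) + rec.count
        positions = tss_by_chrom.get(rec.chrom)
        if positions is not None:
            for pos in rec.insertions:
                lo = np.searchsorted(positions, pos - _TSS_WINDOW, side="left")
                hi = np.searchsorted(positions, pos + _TSS_WINDOW, side="right")
                for t in positions[lo:hi]:
                    off = abs(pos - int(t))
                    if off <= _TSS_CENTRAL:
                        central[b] = central.get(b, 0) + rec.count
                    elif _TSS_WINDOW - _TSS_FLANK < off <= _TSS_WINDOW:
                        flank[b] = flank.get(b, 0) + rec.count

    records = []
    for b in sorted(total):
        c = central.get(b, 0)
        f = flank.get(b, 0)
        if c == 0:
            enr = 0.0
        else:
            enr = (c / _CENTRAL_BP) / ((f + 1) / _FLANK_BP)
        short = short_frags.get(b, 0)
        nuc = mono_frags.get(b, 0) / short if short > 0 else 0.0
        records.append((b, total[b], mito.get(b, 0), enr, nuc))
    return pd.DataFrame.from_records(
        records,
        columns=["barcode", "total_fragments", "mito_fragments", "tss_enrichment", "nucleosome_signal"],
    ).set_index("barcode")
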