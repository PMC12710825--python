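"""Normalized chromatin-contact probabilities from binned observed/expected tables.

Builds the contact component C of the co-accessibility-by-contact score
from pre-extracted binned observed/expected (oe) Hi-C tables: per-dataset
quantile clipping, element-wise averaging across datasets, per-chromosome
min-max scaling to [0, 1], and a 1 Mb distance cap.  Raw ``.hic``/``.cool``
parsing is out of scope; tables carry (chrom, bin_i, bin_j, oe) with bin
coordinates given as bin-start positions in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .intervals import GenomicInterval

MAX_CONTACT_DISTANCE = 1_000_000
DEFAULT_BIN_SIZE = 5_000

TABLE_COLUMNS = ["chrom", "bin_i", "bin_j", "oe"]


@dataclass
class ContactMap:
    """Scaled contacts for one chromosome, keyed by canonical (i <= j) bin pairs."""

    chrom: str
    bin_size: int = DEFAULT_BIN_SIZE
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def get(self, bin_i: int, bin_j: int) -> float:
        if bin_i > bin_j:
            bin_i, bin_j = bin_j, bin_i
        return self.values.get((bin_i, bin_j), 0.0)

    def to_table(self) -> pd.DataFrame:
        rows = [(self.chrom, i, j, v) for (i, j), v in self.values.items()]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def read_contact_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    swap = df["bin_i"] > df["bin_j"]
    df.loc[swap, ["bin_i", "bin_j"]] = df.loc[swap, ["bin_j", "bin_i"]].to_numpy()
    # duplicate (symmetric) entries within one dataset collapse to their mean
    return df.groupby(["chrom", "bin_i", "bin_j"], as_index=False)["oe"].mean()


def prepare_contacts(
    tables: list[pd.DataFrame],
    bin_size: int = DEFAULT_BIN_SIZE,
    clip_quantile: float = 0.90,
    max_distance: int = MAX_CONTACT_DISTANCE,
) -> dict[str, ContactMap]:
    """Clip, average and min-max scale binned oe tables into contact maps.

    Per dataset and chromosome, values above the ``clip_quantile``
    quantile of the stored entries are clipped to that quantile.  Clipped
    values are averaged element-wise across datasets, treating entries
    missing from a dataset as 0.  The averaged values are min-max scaled
    per chromosome (a degenerate range maps to 0 everywhere) and pairs
    separated by more than ``max_distance`` are dropped.
    """
    if not tables:
        raise ValueError("at least one contact table is required")
    n_datasets = len(tables)
    clipped = []
    for t in tables:
        if (t["oe"] < 0).any():
            raise ValueError("oe values must be non-negative")
        t = _canonicalize(t)
        q = t.groupby("chrom")["oe"].transform(lambda v: v.quantile(clip_quantile))
        t["oe"] = np.minimum(t["oe"], q)
        clipped.append(t)
    merged = pd.concat(clipped, ignore_index=True)
    avg = (
        merged.groupby(["chrom", "bin_i", "bin_j"], as_index=False)["oe"].sum()
    )
    avg["oe"] /= n_datasets  # entries absent from a dataset count as 0
    avg = avg[(avg["bin_j"] - avg["bin_i"]).abs() <= max_distance]

    maps: dict[str, ContactMap] = {}
    for chrom, sub in avg.groupby("chrom"):
        lo, hi = sub["oe"].min(), sub["oe"].max()
        if hi > lo:
            scaled = (sub["oe"] - lo) / (hi - lo)
        else:
            scaled = pd.Series(np.zeros(len(sub)), index=sub.index)
        maps[str(chrom)] = ContactMap(
            chrom=str(chrom),
            bin_size=bin_size,
            values={
                (int(i), int(j)): float(v)
                for i, j, v in zip(sub["bin_i"], sub["bin_j"], scaled)
            },
        )
    return maps


def contact_for_pair(
    cmap: ContactMap, a: GenomicInterval, b: GenomicInterval
) -> float:
    """Scaled contact at the bin pair holding the two CRE midpoints.

    Returns 0 when the pair is absent or farther apart than the contact
    cap.  Raises on cross-chromosome queries.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"cross-chromosome contact query: {a.chrom} vs {b.chrom}")
    if a.chrom != cmap.chrom:
        raise ValueError(f"map is for {cmap.chrom}, query on {a.chrom}")
    bin_a = int(a.midpoint // cmap.bin_size) * cmap.bin_size
    bin_b = int(b.midpoint // cmap.bin_size) * cmap.bin_size
    if abs(bin_b - bin_a) > MAX_CONTACT_DISTANCE:
        return 0.0
    return cmap.get(bin_a, bin_b)
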