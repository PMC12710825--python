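"""Genomic intervals, BED and fragment-file I/O.

Coordinates are 0-based half-open (BED convention) everywhere in this
package.  Chromosome names are compared by exact string match; no "chr"
prefix normalization is applied.

A *fragment file* is the standard single-cell chromatin format: one
sequenced fragment per line as five tab-separated columns
(chrom, start, end, cell barcode, duplicate count), optionally
gzip/bgzip-compressed.  Fragment files are consumed as sequential scans;
no tabix index is required.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator


class ParseError(ValueError):
    """Malformed line in a BED or fragment file."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally named and grouped.

    ``group`` carries a module label when the interval comes from a
    grouped BED file (e.g. a module BED where column 4 is the module id).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    group: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """An ordered collection of :class:`GenomicInterval`.

    ``is_sorted`` records whether intervals are ordered lexicographically
    by chromosome and then numerically by start.  Names, when present,
    must be unique.
    """

    intervals: list[GenomicInterval]
    is_sorted: bool = field(init=False)

    def __post_init__(self):
        names = [iv.name for iv in self.intervals if iv.name is not None]
        if len(names) != len(set(names)):
            raise ValueError("interval names must be unique when present")
        self.is_sorted = all(
            (a.chrom, a.start) <= (b.chrom, b.start)
            for a, b in zip(self.intervals, self.intervals[1:])
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def groups(self) -> dict[str, list[int]]:
        """Map group label -> indices of member intervals (labelled only)."""
        out: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            if iv.group is not None:
                out.setdefault(iv.group, []).append(i)
        return out


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced ATAC fragment.

    ``start``/``end`` are the (already Tn5-adjusted) 0-based half-open
    fragment coordinates; ``count`` is the duplicate read count.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def insertions(self) -> tuple[int, int]:
        """The two Tn5 insertion sites: start and end - 1."""
        return (self.start, self.end - 1)


def _open_write(path) -> IO[str]:
    """Open for text writing; deterministic gzip (mtime=0) when path ends in .gz."""
    if str(path).endswith(".gz"):
        import io

        return io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
    return open(path, "wt")


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def open_text(path) -> IO[str]:
    """Open a possibly gzip/bgzip-compressed text file (autodetected)."""
    if _is_gzip(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bed(path, group_column: int | None = None) -> RegionSet:
    """Read a BED file (>= 3 columns) into a :class:`RegionSet`.

    Parameters
    ----------
    path
        Plain or gzip-compressed BED file.
    group_column
        Optional 1-based column index holding a group (module) label.
        When given, that column populates ``GenomicInterval.group``.
        When it is not column 4, column 4 (if present) is used as the
        interval name.

    Intervals are returned in file order; the sorted flag is computed.
    """
    intervals: list[GenomicInterval] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates: {fields[1]!r}, {fields[2]!r}") from None
            if start < 0:
                raise ParseError(path, lineno, f"negative start {start}")
            if end <= start:
                raise ParseError(path, lineno, f"end <= start ({start}, {end})")
            group = None
            if group_column is not None:
                if len(fields) < group_column:
                    raise ParseError(path, lineno, f"group column {group_column} missing")
                group = fields[group_column - 1]
            name = None
            if len(fields) >= 4 and group_column != 4:
                name = fields[3]
            intervals.append(GenomicInterval(chrom, start, end, name=name, group=group))
    return RegionSet(intervals)


def write_bed(regions: Iterable[GenomicInterval], path, group_as_name: bool = False) -> None:
    """Write intervals as BED.  With ``group_as_name`` column 4 is the group label."""
    with _open_write(path) as fh:
        for iv in regions:
            col4 = iv.group if group_as_name else iv.name
            if col4 is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{col4}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fragments(path) -> Iterator[FragmentRecord]:
    """Stream a 5-column fragment file; '#' comment lines are skipped."""
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(path, lineno, f"expected 5 columns, got {len(fields)}")
            try:
                start, end, count = int(fields[1]), int(fields[2]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer start/end/count") from None
            if start < 0:
                raise ParseError(path, lineno, f"negative coordinate {start}")
            try:
                yield FragmentRecord(fields[0], start, end, fields[3], count)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None


def write_fragments(records: Iterable[FragmentRecord], path) -> None:
    """Write fragment records as 5-column TSV; gzip when path ends in .gz."""
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.barcode}\t{rec.count}\n")


def pairwise_distance(a: GenomicInterval, b: GenomicInterval) -> float | None:
    """Midpoint-to-midpoint distance in bp; ``None`` across chromosomes.

    The genomic distance between two CREs is defined as the absolute
    difference of their interval midpoints: symmetric and stable under
    small boundary changes.
    """
    if a.chrom != b.chrom:
        return None
    return abs(a.midpoint - b.midpoint)
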