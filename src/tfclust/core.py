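"""Coordinate conventions, interval algebra and tabular genomic I/O.

All coordinates are 0-based half-open (BED dialect): an interval
``(chrom, start, end)`` covers bases ``start .. end-1``.  Overlap between two
intervals means at least one shared base.  These two conventions are used by
every other module in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Genome",
    "RegionSet",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "merge_overlapping",
    "merge_within_gap",
    "split_to_max_length",
    "overlap_fraction",
    "build_interval_index",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open coordinate span on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must be strictly greater than ``start``.
    strand : str
        One of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def clamped(self, genome: "Genome") -> "GenomicInterval":
        """Truncate the interval to ``[0, chromosome length)``."""
        length = genome[self.chrom]
        start = max(0, self.start)
        end = min(length, self.end)
        if start >= end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} lies entirely "
                f"outside chromosome of length {length}"
            )
        return replace(self, start=start, end=end)


class Genome:
    """Ordered map of chromosome name to length in base pairs."""

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self._sizes: dict[str, int] = dict(items)

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"Genome({self._sizes!r})"


@dataclass
class RegionSet:
    """A labelled collection of genomic intervals, kept sorted by position.

    ``merged`` asserts that the intervals are pairwise non-overlapping; it is
    set by the merge operations and cleared by anything that could introduce
    overlap.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    merged: bool = False

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a UCSC-style two-column chrom.sizes file (name, length)."""
    sizes: list[tuple[str, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            sizes.append((fields[0], int(fields[1])))
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in genome.items():
            handle.write(f"{name}\t{length}\n")


def read_bed(path: str | Path, label: str | None = None) -> RegionSet:
    """Read a BED3/BED5 file into a sorted :class:`RegionSet`.

    Track lines and ``#`` comments are skipped.  Name/score columns, when
    present, are ignored here; use :func:`tfclust.clustering.read_peaks` to
    retain them as peak attributes.

    Raises
    ------
    ValueError
        On non-integer coordinates or ``start >= end``, naming the offending
        line number.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            intervals.append(GenomicInterval(fields[0], start, end))
    return RegionSet(label=label, intervals=intervals)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3 (tab-separated, no header)."""
    with open(path, "w") as handle:
        for iv in regions:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _merge_sorted(intervals: list[GenomicInterval], gap: int) -> list[GenomicInterval]:
    """Merge sorted intervals whose edge-to-edge distance is <= gap."""
    out: list[GenomicInterval] = []
    for iv in intervals:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def merge_overlapping(regions: RegionSet) -> RegionSet:
    """Condense overlapping (or book-ended) intervals into disjoint regions.

    The union of covered bases is preserved; the result is flagged merged.
    Idempotent.
    """
    return RegionSet(
        label=regions.label,
        intervals=_merge_sorted(regions.intervals, gap=0),
        merged=True,
    )


def merge_within_gap(regions: RegionSet, gap: int) -> RegionSet:
    """Merge intervals whose edge-to-edge distance is at most ``gap`` bp.

    "Within ``gap`` bp of each other" is read as ``next.start - prev.end <=
    gap``, applied transitively along each chromosome.  ``gap=0`` reduces to
    :func:`merge_overlapping`.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    return RegionSet(
        label=regions.label,
        intervals=_merge_sorted(regions.intervals, gap=gap),
        merged=True,
    )


def split_to_max_length(regions: RegionSet, max_len: int) -> RegionSet:
    """Split every interval into left-greedy pieces of at most ``max_len`` bp.

    Splitting proceeds left to right in full ``max_len`` pieces with the
    remainder last; concatenating the pieces of one input interval
    reconstructs it exactly, so total covered length is conserved.
    """
    if max_len <= 0:
        raise ValueError(f"max_len must be > 0, got {max_len}")
    pieces: list[GenomicInterval] = []
    for iv in regions:
        pos = iv.start
        while iv.end - pos > max_len:
            pieces.append(GenomicInterval(iv.chrom, pos, pos + max_len, iv.strand))
            pos += max_len
        pieces.append(GenomicInterval(iv.chrom, pos, iv.end, iv.strand))
    return RegionSet(label=regions.label, intervals=pieces, merged=regions.merged)


def build_interval_index(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for fast overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def overlap_fraction(query: RegionSet | list[GenomicInterval], subject: RegionSet | list[GenomicInterval]) -> float:
    """Fraction of query intervals overlapping (>=1 bp) any subject interval.

    Returns 0.0 for an empty query.
    """
    query_ivs = list(query)
    if not query_ivs:
        return 0.0
    index = build_interval_index(subject)
    hits = 0
    for iv in query_ivs:
        tree = index.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            hits += 1
    return hits / len(query_ivs)
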