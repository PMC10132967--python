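"""Genomic intervals and interval-set algebra.

Coordinates are 1-based and inclusive at both ends, matching the breakpoint-graph
and cycle file dialects this package consumes.  Conversion to 0-based half-open
(BED) happens only at writer boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one chromosome.

    strand is '+', '-' or '.' (unoriented); it does not participate in the
    set algebra below.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 1
) -> list[GenomicInterval]:
    """Union of intervals, merging same-chromosome intervals separated by <= gap bp.

    gap=1 merges abutting intervals ([1,10] and [11,20] -> [1,20]); gap=0 merges
    only overlapping ones.  Output is sorted by (chrom, start) and non-overlapping.
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered (input need not be pre-merged)."""
    return sum(iv.length for iv in merge_intervals(intervals, gap=0))


def intersect_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Number of bases covered by both interval sets."""
    am = merge_intervals(a, gap=0)
    bm = merge_intervals(b, gap=0)
    total = 0
    for x in am:
        for y in bm:
            if x.overlaps(y):
                total += min(x.end, y.end) - max(x.start, y.start) + 1
    return total


def jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """Base-level Jaccard index of two interval sets (0 when either is empty)."""
    inter = intersect_length(a, b)
    union = total_length(a) + total_length(b) - inter
    return inter / union if union else 0.0


def interval_sets_overlap(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> bool:
    return intersect_length(a, b) > 0


def to_bed_line(iv: GenomicInterval, name: str = ".") -> str:
    """Render as a BED (0-based half-open) line."""
    return f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}"
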