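"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` internally; the GTF
boundary code converts from/to the 1-based inclusive convention.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals, merged where overlapping or bookended.

    All intervals must share one chromosome and strand; the result is sorted
    and pairwise disjoint (adjacent intervals are coalesced).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge intervals across chromosomes: {sorted(chroms)}")
    strand = ivs[0].strand
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:  # overlap or bookend
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    chrom = ivs[0].chrom
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def complement_within(
    intervals: Sequence[GenomicInterval], extent: GenomicInterval
) -> list[GenomicInterval]:
    """Gaps of a sorted disjoint interval list within ``extent``."""
    gaps: list[GenomicInterval] = []
    cursor = extent.start
    for iv in intervals:
        if iv.start > cursor:
            gaps.append(GenomicInterval(extent.chrom, cursor, iv.start, extent.strand))
        cursor = max(cursor, iv.end)
    if cursor < extent.end:
        gaps.append(GenomicInterval(extent.chrom, cursor, extent.end, extent.strand))
    return gaps


class IntervalSet:
    """Sorted disjoint intervals on one chromosome with O(log n) containment."""

    __slots__ = ("starts", "ends")

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.starts = [iv.start for iv in intervals]
        self.ends = [iv.end for iv in intervals]

    def contains_block(self, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely within one member interval."""
        i = bisect_right(self.starts, start) - 1
        return i >= 0 and end <= self.ends[i]
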