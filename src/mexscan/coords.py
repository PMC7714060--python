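"""Genomic coordinate primitives.

All coordinates inside the package are 0-based, half-open. GFF3 and
InterProScan files use 1-based, inclusive coordinates; conversion happens
exactly once, at the I/O boundary (:mod:`mexscan.io`).
"""
from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a named sequence, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive (start, end) pair to 0-based half-open."""
    if end1 < start1:
        raise ValueError(f"end < start in 1-based interval: ({start1}, {end1})")
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Inverse of :func:`to_zero_based`."""
    return start0 + 1, end0


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap length of two half-open integer intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
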