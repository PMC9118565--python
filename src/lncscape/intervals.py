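"""Half-open genomic intervals and set arithmetic on them.

Every coordinate in this package is 0-based half-open (``[start, end)``),
the BED convention. Format readers convert on input, writers convert back.
All overlap statistics in the classification, TE and conservation modules
reduce to the three primitives here: merging an interval list into a
disjoint union, measuring a union, and intersecting two unions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "union_length",
    "intersect_unions",
    "overlap_bp",
    "complement_intervals",
    "STRANDS",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, start: int, end: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, start, end, self.strand)


Pair = tuple[int, int]


def merge_intervals(pairs: Iterable[Pair]) -> list[Pair]:
    """Merge (start, end) pairs into a sorted disjoint union.

    Touching intervals (end == next start) are merged; the union length
    is unaffected either way.
    """
    out: list[Pair] = []
    for s, e in sorted(pairs):
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union_length(pairs: Iterable[Pair]) -> int:
    return sum(e - s for s, e in merge_intervals(pairs))


def intersect_unions(a: Sequence[Pair], b: Sequence[Pair]) -> list[Pair]:
    """Intersection of two interval lists (need not be pre-merged)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Pair] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_bp(a: Sequence[Pair], b: Sequence[Pair]) -> int:
    """Total overlapping bases between two interval sets on one chromosome."""
    return sum(e - s for s, e in intersect_unions(a, b))


def complement_intervals(pairs: Sequence[Pair], length: int) -> list[Pair]:
    """Gaps of ``pairs`` within [0, length)."""
    out: list[Pair] = []
    pos = 0
    for s, e in merge_intervals(pairs):
        if s > pos:
            out.append((pos, min(s, length)))
        pos = max(pos, e)
        if pos >= length:
            break
    if pos < length:
        out.append((pos, length))
    return out
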