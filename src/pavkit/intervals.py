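"""Half-open interval arithmetic on 0-based genome coordinates.

All region accounting in the package (genic/intergenic spans, covered-base
unions, complements) runs through these primitives so that base counts are
unambiguous: an interval [start, end) has length end - start and two
intervals touching at a coordinate share no bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


Span = tuple[int, int]


def merge_spans(spans: Iterable[Span]) -> list[Span]:
    """Union of (start, end) spans as a sorted, non-overlapping list.

    Adjacent spans ([0,5), [5,9)) are coalesced; the union length is
    unchanged either way.
    """
    out: list[Span] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def spans_length(spans: Iterable[Span]) -> int:
    return sum(e - s for s, e in merge_spans(spans))


def complement_spans(spans: Sequence[Span], chrom_length: int) -> list[Span]:
    """Gaps of a merged span list within [0, chrom_length)."""
    out: list[Span] = []
    pos = 0
    for s, e in merge_spans(spans):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < chrom_length:
        out.append((pos, chrom_length))
    return out


def intersect_spans(a: Sequence[Span], b: Sequence[Span]) -> list[Span]:
    """Intersection of two span lists (each merged internally first)."""
    a = merge_spans(a)
    b = merge_spans(b)
    out: list[Span] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out
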