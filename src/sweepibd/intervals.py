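"""Genomic interval algebra.

All intervals in this package are 0-based, half-open ``[start, end)`` —
the BED convention.  VCF positions (1-based) and GFF3 coordinates
(1-based, closed) are converted at the I/O boundary so that interval
arithmetic never has to special-case a coordinate system.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with an optional score (BED5 column 5)."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap (>= 1 bp shared); book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def with_score(self, score: float | None) -> "GenomicInterval":
        return replace(self, score=score)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append(iv)
    for ivs in grouped.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return grouped


def merge_intervals(
    intervals: Iterable[GenomicInterval], book_ended: bool = True
) -> list[GenomicInterval]:
    """Union-merge intervals per chromosome.

    With ``book_ended=True`` (default) touching intervals (``end == next
    start``) are merged as well; with 50 %-overlap sliding windows separate
    book-ended regions would be artifacts of the window grid.
    Idempotent: ``merge(merge(x)) == merge(x)``.  Scores are dropped.
    """
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        cur_start = cur_end = None
        for iv in _by_chrom_single(intervals, chrom):
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start < cur_end or (book_ended and iv.start == cur_end):
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def _by_chrom_single(
    intervals: Iterable[GenomicInterval], chrom: str
) -> list[GenomicInterval]:
    return sorted(
        (iv for iv in intervals if iv.chrom == chrom),
        key=lambda iv: (iv.start, iv.end),
    )


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Exact base-pair intersection of two interval sets (bedtools intersect).

    Both sides are union-merged first, so the result is a disjoint, sorted
    list equal to per-base set intersection.  Commutative and associative.
    """
    am = merge_intervals(a, book_ended=False)
    bm = merge_intervals(b, book_ended=False)
    a_by = _by_chrom(am)
    b_by = _by_chrom(bm)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def intersect_many(sets: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    """Base-pair intersection across two or more interval sets."""
    if not sets:
        return []
    result = merge_intervals(sets[0], book_ended=False)
    for other in sets[1:]:
        result = intersect_intervals(result, other)
        if not result:
            break
    return result


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered (after union-merge, so overlaps count once)."""
    return sum(iv.length for iv in merge_intervals(intervals, book_ended=False))


def coverage_fraction(
    truth: Sequence[GenomicInterval], detected: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``truth`` bases covered by ``detected`` (recall on bases)."""
    denom = total_length(truth)
    if denom == 0:
        return float("nan")
    return total_length(intersect_intervals(truth, detected)) / denom
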