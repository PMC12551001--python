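"""Strand-agnostic genomic interval sets with merged-set algebra.

Coordinates are 0-based half-open throughout (the BED convention); VCF
positions are converted at the I/O boundary. An :class:`IntervalSet` always
stores a canonical form: per chromosome, a sorted list of disjoint,
non-abutting ``(start, end)`` pairs, so equality, total length and containment
are well defined regardless of how the set was built.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _chrom_sort_key(chrom: str) -> Tuple[int, str]:
    """Sort autosomes numerically, then X, Y, MT, then anything else."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (int(c), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (order.get(c.upper(), 26), c)


def _merge(pairs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for start, end in sorted(pairs):
        if out and start <= out[-1][1]:  # overlap or abut -> merge
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


class IntervalSet:
    """A merged set of genomic intervals supporting set algebra.

    Invariant: stored intervals on one chromosome neither overlap nor abut,
    and are sorted; ``total_length`` is then simply the sum of spans.
    """

    __slots__ = ("_by_chrom",)

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom = {c: _merge(p) for c, p in raw.items() if p}

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        return cls(GenomicInterval(c, s, e) for c, s, e in tuples)

    @classmethod
    def _from_merged(cls, by_chrom: Dict[str, List[Tuple[int, int]]]) -> "IntervalSet":
        obj = cls()
        obj._by_chrom = {c: list(p) for c, p in by_chrom.items() if p}
        return obj

    # -- inspection ---------------------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom, key=_chrom_sort_key):
            for start, end in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, start, end)

    def __len__(self) -> int:
        return sum(len(p) for p in self._by_chrom.values())

    def __bool__(self) -> bool:
        return bool(self._by_chrom)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __hash__(self) -> int:
        return hash(
            tuple(sorted((c, tuple(p)) for c, p in self._by_chrom.items()))
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_length} bp)"

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom, key=_chrom_sort_key)

    @property
    def total_length(self) -> int:
        return sum(e - s for p in self._by_chrom.values() for s, e in p)

    # -- queries ------------------------------------------------------------

    def contains_span(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies fully inside one stored interval."""
        pairs = self._by_chrom.get(chrom)
        if not pairs or start >= end:
            return False
        i = bisect_right([p[0] for p in pairs], start) - 1
        if i < 0:
            return False
        s, e = pairs[i]
        return s <= start and end <= e

    def overlaps_span(self, chrom: str, start: int, end: int) -> bool:
        pairs = self._by_chrom.get(chrom)
        if not pairs or start >= end:
            return False
        i = bisect_right([p[0] for p in pairs], start) - 1
        if i >= 0 and pairs[i][1] > start:
            return True
        return i + 1 < len(pairs) and pairs[i + 1][0] < end

    # -- algebra ------------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        merged: Dict[str, List[Tuple[int, int]]] = {}
        for chrom in set(self._by_chrom) | set(other._by_chrom):
            merged[chrom] = _merge(
                self._by_chrom.get(chrom, []) + other._by_chrom.get(chrom, [])
            )
        return IntervalSet._from_merged(merged)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, List[Tuple[int, int]]] = {}
        for chrom in set(self._by_chrom) & set(other._by_chrom):
            a, b = self._by_chrom[chrom], other._by_chrom[chrom]
            i = j = 0
            pairs: List[Tuple[int, int]] = []
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    pairs.append((lo, hi))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            if pairs:
                out[chrom] = pairs
        return IntervalSet._from_merged(out)

    def pad(self, flank: int) -> "IntervalSet":
        """Extend every interval by ``flank`` bases on both sides (floor 0)."""
        return IntervalSet(
            GenomicInterval(c, max(0, s - flank), e + flank)
            for c, pairs in self._by_chrom.items()
            for s, e in pairs
        )


def union_all(sets: Iterable[IntervalSet]) -> IntervalSet:
    out = IntervalSet()
    for s in sets:
        out = out.union(s)
    return out
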