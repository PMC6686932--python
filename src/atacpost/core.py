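"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention).  Readers that accept
1-based formats (VCF-style variant positions) convert at the boundary, so
code past the readers never sees a 1-based coordinate.  Chromosome names are
compared by exact string match; there is no "chr" aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRANDS = ("+", "-", ".")


class UnknownChromosomeError(KeyError):
    """A coordinate refers to a chromosome absent from the genome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return bp_overlap(self, other) > 0

    def shifted(self, start: int, end: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, start, end, self.strand)


def bp_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two half-open intervals (0 across chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_union(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals into a sorted, disjoint cover of the same bases.

    Book-ended intervals ([0,5) + [5,9)) merge into one; strand is dropped.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def covered_bp(intervals: list[GenomicInterval]) -> int:
    """Total number of distinct bases covered by a (possibly overlapping) set."""
    return sum(len(iv) for iv in merge_union(intervals))


def distance_to_nearest(
    query: GenomicInterval, targets: list[GenomicInterval]
) -> tuple[int, int] | None:
    """Signed gap (bp) to the nearest target and the target's list index.

    0 when overlapping; positive when the nearest target lies right of the
    query, negative when left.  Equidistant ties go to the target with the
    smaller start.  Returns ``None`` when no target shares the chromosome.
    """
    best: tuple[int, int, int] | None = None  # (|d|, target.start, index)
    best_d = 0
    for i, t in enumerate(targets):
        if t.chrom != query.chrom:
            continue
        if bp_overlap(query, t) > 0:
            d = 0
        elif t.start >= query.end:
            d = t.start - query.end
        else:
            d = -(query.start - t.end)
        key = (abs(d), t.start, i)
        if best is None or key < best:
            best, best_d = key, d
    if best is None:
        return None
    return best_d, best[2]


class DisjointIntervals:
    """Merged interval set supporting fast overlap and membership queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        merged = merge_union(intervals)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    @property
    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values())))

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    def overlap_bp(self, iv: GenomicInterval) -> int:
        if iv.chrom not in self._starts:
            return 0
        starts, ends = self._starts[iv.chrom], self._ends[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], iv.start)
        e = np.minimum(ends[lo:hi], iv.end)
        return int(np.clip(e - s, 0, None).sum())

    def overlaps(self, iv: GenomicInterval) -> bool:
        return self.overlap_bp(iv) > 0

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions (half-open containment)."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._starts or positions.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        ok[ok] = positions[ok] < ends[idx[ok]]
        return ok

    def assign_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Index of the merged interval containing each position, -1 outside."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._starts:
            return np.full(positions.shape, -1, dtype=np.int64)
        starts, ends = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        bad = (idx < 0) | (positions >= ends[np.clip(idx, 0, None)])
        idx[bad] = -1
        return idx


class OverlapIndex:
    """Overlap queries against an arbitrary (possibly overlapping) interval list.

    Returns original list indices; built once, queried many times.
    """

    def __init__(self, intervals: list[GenomicInterval]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        self._intervals = intervals
        for chrom, idxs in by_chrom.items():
            idxs_arr = np.array(idxs, dtype=np.int64)
            starts = np.array([intervals[i].start for i in idxs], dtype=np.int64)
            ends = np.array([intervals[i].end for i in idxs], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends, idxs_arr = starts[order], ends[order], idxs_arr[order]
            cummax_end = np.maximum.accumulate(ends)
            self._data[chrom] = (starts, ends, cummax_end, idxs_arr)

    def query(self, iv: GenomicInterval) -> list[int]:
        """Indices of stored intervals sharing >= 1 bp with ``iv``."""
        if iv.chrom not in self._data:
            return []
        starts, ends, cummax_end, idxs = self._data[iv.chrom]
        lo = int(np.searchsorted(cummax_end, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            return []
        sel = ends[lo:hi] > iv.start
        return [int(i) for i in idxs[lo:hi][sel]]


@dataclass
class Genome:
    """Chromosome sizes plus optional mappability and blacklist tracks.

    ``mappability`` holds the uniquely-mappable regions; absent track means
    every base is treated as uniquely mappable.
    """

    sizes: dict[str, int]
    mappability: DisjointIntervals | None = None
    blacklist: DisjointIntervals | None = None

    def __post_init__(self) -> None:
        for chrom, size in self.sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive size for chromosome {chrom}")
        if self.blacklist is not None:
            for iv in self.blacklist.intervals():
                self.validate(iv)

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.sizes:
            raise UnknownChromosomeError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.sizes[iv.chrom]}"
            )

    def contains(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.sizes and iv.end <= self.sizes[iv.chrom]

    def mappable_fraction(self, iv: GenomicInterval) -> float:
        if self.mappability is None:
            return 1.0
        return self.mappability.overlap_bp(iv) / len(iv)

    def in_blacklist(self, iv: GenomicInterval) -> bool:
        return self.blacklist is not None and self.blacklist.overlaps(iv)


def bp_overlap_checked(a: GenomicInterval, b: GenomicInterval, genome: Genome) -> int:
    """`bp_overlap` that first validates both intervals against a genome."""
    genome.validate(a)
    genome.validate(b)
    return bp_overlap(a, b)
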