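"""Exact genomic interval arithmetic.

All coordinates are 0-based half-open internally; file readers convert at
the boundary (GFF3 and RepeatMasker ``.out`` are 1-based inclusive, BED is
already half-open).  Interval sets are stored per chromosome as sorted
``(n, 2)`` integer arrays; after :func:`merge` the intervals on each
chromosome are pairwise disjoint and non-adjacent, which makes every
downstream coverage computation a simple vectorized pass.

All analyses in this package are strand-agnostic, so intervals carry no
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "ChromSizes",
    "merge",
    "subtract",
    "intersect",
    "total_bp",
    "overlap_fraction",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based_inclusive(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (GFF3 / RepeatMasker style)."""
        return cls(chrom, start - 1, end)


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp (all lengths > 0)."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        items = sizes.items() if isinstance(sizes, Mapping) else sizes
        for name, length in items:
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if name in self:
            raise ValueError(f"duplicate chromosome {name!r}")
        self[name] = length

    @property
    def total(self) -> int:
        return sum(self.values())


class IntervalSet:
    """A collection of intervals grouped by chromosome.

    The canonical (merged) form has, per chromosome, sorted, pairwise
    disjoint, non-adjacent intervals; :meth:`merged` returns that form and
    set-algebra helpers operate on it.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        by_chrom: Dict[str, list] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._arrays: Dict[str, np.ndarray] = {
            c: np.asarray(sorted(pairs), dtype=np.int64) for c, pairs in by_chrom.items()
        }
        self._is_merged = False

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray], *, merged: bool = False) -> "IntervalSet":
        out = cls()
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size == 0:
                continue
            if np.any(arr[:, 0] >= arr[:, 1]) or np.any(arr[:, 0] < 0):
                bad = arr[(arr[:, 0] >= arr[:, 1]) | (arr[:, 0] < 0)][0]
                raise ValueError(f"malformed interval {chrom}:{bad[0]}-{bad[1]}")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            out._arrays[chrom] = arr[order]
        out._is_merged = merged
        return out

    # -- introspection -------------------------------------------------

    @property
    def chroms(self) -> list:
        return sorted(self._arrays)

    def array(self, chrom: str) -> np.ndarray:
        return self._arrays.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for start, end in self._arrays[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    def __len__(self) -> int:
        return sum(len(a) for a in self._arrays.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.merged(), other.merged()
        if a.chroms != b.chroms:
            return False
        return all(np.array_equal(a.array(c), b.array(c)) for c in a.chroms)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._arrays)} chroms)"

    # -- set algebra ---------------------------------------------------

    def merged(self) -> "IntervalSet":
        if self._is_merged:
            return self
        out_arrays = {}
        for chrom, arr in self._arrays.items():
            out_arrays[chrom] = _merge_sorted(arr)
        return IntervalSet.from_arrays(out_arrays, merged=True)

    def total_bp(self) -> int:
        m = self.merged()
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in m._arrays.values()))


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge a start-sorted (n,2) array; adjacent intervals coalesce."""
    if len(arr) == 0:
        return arr
    starts, ends = arr[:, 0], np.maximum.accumulate(arr[:, 1])
    # a new run begins where start > running max end of everything before
    new_run = np.empty(len(arr), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > ends[:-1]
    run_starts = np.flatnonzero(new_run)
    out = np.empty((len(run_starts), 2), dtype=np.int64)
    out[:, 0] = starts[run_starts]
    out[:, 1] = np.maximum.reduceat(arr[:, 1], run_starts)
    return out


def merge(iset: IntervalSet) -> IntervalSet:
    """Canonicalize to sorted, disjoint, non-adjacent intervals per chrom."""
    return iset.merged()


def _subtract_chrom(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b, both merged (n,2) arrays on one chromosome."""
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    pieces = []
    bi = 0
    nb = len(b)
    for start, end in a:
        cur = start
        # advance past b intervals ending at or before cur
        while bi < nb and b[bi, 1] <= cur:
            bi += 1
        j = bi
        while j < nb and b[j, 0] < end:
            bs, be = b[j]
            if bs > cur:
                pieces.append((cur, bs))
            cur = max(cur, be)
            if cur >= end:
                break
            j += 1
        if cur < end:
            pieces.append((cur, end))
    return np.asarray(pieces, dtype=np.int64).reshape(-1, 2)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by *a* and not by *b*."""
    am, bm = a.merged(), b.merged()
    out = {}
    for chrom in am.chroms:
        res = _subtract_chrom(am.array(chrom), bm.array(chrom))
        if len(res):
            out[chrom] = res
    return IntervalSet.from_arrays(out, merged=True)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by both *a* and *b*."""
    am, bm = a.merged(), b.merged()
    out = {}
    for chrom in am.chroms:
        x, y = am.array(chrom), bm.array(chrom)
        if len(x) == 0 or len(y) == 0:
            continue
        pieces = []
        i = j = 0
        while i < len(x) and j < len(y):
            s = max(x[i, 0], y[j, 0])
            e = min(x[i, 1], y[j, 1])
            if s < e:
                pieces.append((s, e))
            if x[i, 1] <= y[j, 1]:
                i += 1
            else:
                j += 1
        if pieces:
            out[chrom] = np.asarray(pieces, dtype=np.int64)
    return IntervalSet.from_arrays(out, merged=True)


def total_bp(iset: IntervalSet) -> int:
    """Number of distinct bases covered (union semantics)."""
    return iset.total_bp()


def covered_bp_in(interval: GenomicInterval, iset: IntervalSet) -> int:
    """Bases of *interval* covered by *iset* (exact integer arithmetic)."""
    arr = iset.merged().array(interval.chrom)
    if len(arr) == 0:
        return 0
    starts = np.maximum(arr[:, 0], interval.start)
    ends = np.minimum(arr[:, 1], interval.end)
    return int(np.clip(ends - starts, 0, None).sum())


def overlap_fraction(interval: GenomicInterval, iset: IntervalSet) -> float:
    """Fraction of *interval*'s bases covered by *iset*, in [0, 1]."""
    return covered_bp_in(interval, iset) / interval.length
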