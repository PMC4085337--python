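"""Half-open genomic interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)``. The functions in
this module operate either on :class:`GenomicInterval` lists (convenience
layer) or directly on parallel numpy arrays of starts/ends (hot paths).
Array inputs marked *merged* must be sorted by start and pairwise disjoint;
:func:`merge_arrays` produces that canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "merge_arrays",
    "intersect_arrays",
    "subtract_arrays",
    "overlap_size",
    "to_arrays",
    "from_arrays",
    "merge_intervals",
    "subtract_intervals",
    "total_length",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def to_arrays(intervals: Iterable[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    """Starts/ends arrays from an interval iterable (single chromosome assumed)."""
    ivs = list(intervals)
    starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
    ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
    return starts, ends


def from_arrays(
    starts: np.ndarray, ends: np.ndarray, chrom: str, strand: str = "+"
) -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, int(s), int(e), strand)
        for s, e in zip(starts, ends)
        if e > s
    ]


def merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical form: sorted by start, overlapping/adjacent runs fused.

    Touching intervals ([0,5),[5,9)) are fused; empty intervals are dropped.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > cummax[:-1]
    run_starts = np.flatnonzero(new_run)
    out_s = s[new_run]
    out_e = np.maximum.reduceat(e, run_starts)
    return out_s, out_e


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(owner index, flat index) pairs for concatenated ranges lo[i]..hi[i]."""
    counts = hi - lo
    owners = np.repeat(np.arange(lo.size), counts)
    if owners.size == 0:
        return owners, owners
    flat = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    return owners, flat + lo[owners]


def intersect_arrays(
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of two merged interval sets; result is merged."""
    a_starts = np.asarray(a_starts, dtype=np.int64)
    a_ends = np.asarray(a_ends, dtype=np.int64)
    b_starts = np.asarray(b_starts, dtype=np.int64)
    b_ends = np.asarray(b_ends, dtype=np.int64)
    if a_starts.size == 0 or b_starts.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lo = np.searchsorted(b_ends, a_starts, side="right")
    hi = np.searchsorted(b_starts, a_ends, side="left")
    owners, bi = _expand_ranges(lo, hi)
    out_s = np.maximum(a_starts[owners], b_starts[bi])
    out_e = np.minimum(a_ends[owners], b_ends[bi])
    keep = out_e > out_s
    return out_s[keep], out_e[keep]


def overlap_size(
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> int:
    """Total overlapping bases between two merged interval sets."""
    s, e = intersect_arrays(a_starts, a_ends, b_starts, b_ends)
    return int((e - s).sum())


def subtract_arrays(
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """a minus b for merged interval sets; result is merged."""
    a_starts = np.asarray(a_starts, dtype=np.int64)
    a_ends = np.asarray(a_ends, dtype=np.int64)
    if a_starts.size == 0:
        return a_starts, a_ends
    b_starts = np.asarray(b_starts, dtype=np.int64)
    b_ends = np.asarray(b_ends, dtype=np.int64)
    if b_starts.size == 0:
        return a_starts.copy(), a_ends.copy()
    # complement of b over the covering span, then intersect with a
    lo = min(a_starts[0], b_starts[0])
    hi = max(a_ends[-1], b_ends[-1])
    comp_s = np.concatenate(([lo], b_ends))
    comp_e = np.concatenate((b_starts, [hi]))
    keep = comp_e > comp_s
    return intersect_arrays(a_starts, a_ends, comp_s[keep], comp_e[keep])


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merged interval list; all inputs must share one chromosome."""
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError("merge_intervals requires a single chromosome")
    strand = intervals[0].strand
    s, e = merge_arrays(*to_arrays(intervals))
    return from_arrays(s, e, intervals[0].chrom, strand)


def subtract_intervals(
    regions: Sequence[GenomicInterval], mask: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``regions`` not covered by ``mask`` (same chromosome)."""
    if not regions:
        return []
    chrom = regions[0].chrom
    strand = regions[0].strand
    rs, re = merge_arrays(*to_arrays(regions))
    mask_here = [m for m in mask if m.chrom == chrom]
    ms, me = merge_arrays(*to_arrays(mask_here))
    s, e = subtract_arrays(rs, re, ms, me)
    return from_arrays(s, e, chrom, strand)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)
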