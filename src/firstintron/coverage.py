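"""Overlaying conservation tracks and peak sets onto analysis regions.

A :class:`ScoreTrack` holds per-base conservation probabilities (e.g.
PhastCons) as sparse step intervals; bases with no step have implicit
score 0, matching the download semantics of conservation tracks where
unaligned bases are simply absent. A base is *conserved* when its score is
greater than or equal to the threshold (inclusive, 0.5 by default).
A :class:`PeakSet` is a merged set of signal peaks for one regulatory mark
in one cell line; coverage of a region is the fraction of its bases under
a peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    from_arrays,
    intersect_arrays,
    merge_arrays,
    overlap_size,
    subtract_arrays,
    to_arrays,
)

__all__ = [
    "ScoreTrack",
    "PeakSet",
    "RegionSummary",
    "conserved_fraction",
    "coverage_fraction",
    "partition_by_conservation",
    "read_bedgraph",
    "read_wiggle",
    "read_peaks",
    "write_region_summaries",
]


@dataclass
class ScoreTrack:
    """Sparse per-chromosome score steps; uncovered bases score 0."""

    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, scores), sorted, non-overlapping
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_steps(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "ScoreTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in records:
            if e > s:
                by_chrom.setdefault(chrom, []).append((s, e, v))
        steps = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            scores = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping score steps")
            steps[chrom] = (starts, ends, scores)
        return cls(steps)

    def conserved_intervals(
        self, chrom: str, threshold: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Merged intervals whose score >= threshold (raw float compare)."""
        key = (chrom, threshold)
        if key in self._cache:
            return self._cache[key]
        if chrom not in self.steps:
            empty = np.empty(0, np.int64)
            out = (empty, empty)
        else:
            starts, ends, scores = self.steps[chrom]
            keep = scores >= threshold
            out = merge_arrays(starts[keep], ends[keep])
        self._cache[key] = out
        return out

    def mean_score(self, region: GenomicInterval) -> float:
        """Mean per-base score over a region (absent bases count as 0)."""
        if region.length == 0:
            return float("nan")
        if region.chrom not in self.steps:
            return 0.0
        starts, ends, scores = self.steps[region.chrom]
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        return float(np.sum((e - s) * scores[lo:hi]) / region.length)


@dataclass
class PeakSet:
    """Merged peak intervals for one mark/cell line."""

    mark_name: str
    cell_line: str = ""
    peaks: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        mark_name: str,
        intervals: Iterable[GenomicInterval],
        cell_line: str = "",
    ) -> "PeakSet":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        peaks = {
            chrom: merge_arrays(*to_arrays(ivs)) for chrom, ivs in by_chrom.items()
        }
        return cls(mark_name, cell_line, peaks)

    def union(self, other: "PeakSet") -> "PeakSet":
        """Merge peaks of a replicate file for the same mark/cell line."""
        peaks = {}
        for chrom in sorted(set(self.peaks) | set(other.peaks)):
            a = self.peaks.get(chrom, (np.empty(0, np.int64),) * 2)
            b = other.peaks.get(chrom, (np.empty(0, np.int64),) * 2)
            peaks[chrom] = merge_arrays(
                np.concatenate([a[0], b[0]]), np.concatenate([a[1], b[1]])
            )
        return PeakSet(self.mark_name, self.cell_line, peaks)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, np.int64)
        return self.peaks.get(chrom, (empty, empty))


@dataclass
class RegionSummary:
    """Conserved fraction and per-mark coverage of one analysis region."""

    region_id: str
    effective_length: int
    conserved_fraction: float
    coverage: dict[str, float] = field(default_factory=dict)


def _region_arrays(
    regions: Sequence[GenomicInterval],
) -> tuple[str | None, np.ndarray, np.ndarray, int]:
    regions = [r for r in regions if r.length > 0]
    if not regions:
        return None, np.empty(0, np.int64), np.empty(0, np.int64), 0
    chroms = {r.chrom for r in regions}
    if len(chroms) != 1:
        raise ValueError("regions must share one chromosome")
    s, e = merge_arrays(*to_arrays(regions))
    return regions[0].chrom, s, e, int((e - s).sum())


def conserved_fraction(
    regions: Sequence[GenomicInterval], track: ScoreTrack, threshold: float = 0.5
) -> float:
    """Fraction of region bases with score >= threshold; NaN when empty."""
    chrom, rs, re_, total = _region_arrays(regions)
    if total == 0:
        return float("nan")
    cs, ce = track.conserved_intervals(chrom, threshold)
    return overlap_size(rs, re_, cs, ce) / total


def coverage_fraction(regions: Sequence[GenomicInterval], peaks: PeakSet) -> float:
    """Fraction of region bases under a peak; NaN when the region is empty."""
    chrom, rs, re_, total = _region_arrays(regions)
    if total == 0:
        return float("nan")
    ps, pe = peaks.chrom_arrays(chrom)
    return overlap_size(rs, re_, ps, pe) / total


def partition_by_conservation(
    regions: Sequence[GenomicInterval], track: ScoreTrack, threshold: float = 0.5
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split region bases into (conserved, non-conserved) interval lists.

    The two lists are disjoint and their union is exactly the input bases.
    """
    chrom, rs, re_, total = _region_arrays(regions)
    if total == 0:
        return [], []
    strand = regions[0].strand
    cs, ce = track.conserved_intervals(chrom, threshold)
    cons = intersect_arrays(rs, re_, cs, ce)
    noncons = subtract_arrays(rs, re_, *cons)
    return (
        from_arrays(*cons, chrom, strand),
        from_arrays(*noncons, chrom, strand),
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_bedgraph(path: str | Path) -> ScoreTrack:
    """bedGraph (chrom, start, end, score) -> ScoreTrack."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "score": float},
    )
    steps = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping bedGraph intervals")
        steps[str(chrom)] = (starts, ends, sub["score"].to_numpy())
    return ScoreTrack(steps)


def read_wiggle(path: str | Path) -> ScoreTrack:
    """Fixed-/variable-step wiggle -> ScoreTrack (1-based wig coords)."""
    records: list[tuple[str, int, int, float]] = []
    mode = chrom = None
    pos = step = 1
    span = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                mode = line.split()[0]
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if mode == "fixedStep":
                    pos = int(fields["start"])
                    step = int(fields.get("step", 1))
                continue
            if mode == "fixedStep":
                records.append((chrom, pos - 1, pos - 1 + span, float(line)))
                pos += step
            elif mode == "variableStep":
                p, v = line.split()
                start = int(p) - 1
                records.append((chrom, start, start + span, float(v)))
            else:
                raise ValueError("wiggle data before any step declaration")
    return ScoreTrack.from_steps(records)


def read_peaks(
    path: str | Path, mark_name: str, cell_line: str = ""
) -> PeakSet:
    """BED3+/narrowPeak peaks; only chrom/start/end are consumed."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return PeakSet.from_intervals(mark_name, intervals, cell_line)


def write_region_summaries(
    summaries: Iterable[RegionSummary], path: str | Path
) -> None:
    rows = []
    for s in summaries:
        row = {
            "region_id": s.region_id,
            "effective_length": s.effective_length,
            "conserved_fraction": s.conserved_fraction,
        }
        row.update({f"cov_{m}": v for m, v in sorted(s.coverage.items())})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
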