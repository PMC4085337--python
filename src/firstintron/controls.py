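"""Confounder-control procedures for the first-intron analyses.

Four controls guard the headline enrichments against promoter artefacts:

* spillover filter  - drops genes whose promoter + first-exon signal
  coverage is at least as high as the first-intron coverage (signal merely
  spilling over from the promoter);
* overlap filter    - drops genes whose first intron intersects an exon or
  a 2 kb flank of a different gene;
* TSS-distance-matched comparison of first vs second introns within the
  500-1000 bp window where their TSS distances overlap;
* five-bin positional-bias scan locating the strongest signal along each
  first intron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import IntronRecord, TranscriptModel, flank_regions, FilterConfig
from .coverage import PeakSet, ScoreTrack
from .intervals import GenomicInterval, overlap_size
from .stats import rank_sum_test

__all__ = [
    "DistanceBinSpec",
    "PositionalBiasResult",
    "spillover_filter",
    "overlap_filter",
    "tss_matched_compare",
    "positional_bias",
]


@dataclass(frozen=True)
class DistanceBinSpec:
    """TSS-distance window and bin edges for the matched comparison."""

    min_distance: int = 500
    max_distance: int = 1000
    n_bins: int = 5
    edges: tuple[int, ...] = field(default=())

    def bin_edges(self) -> np.ndarray:
        if self.edges:
            e = np.asarray(self.edges)
        else:
            e = np.linspace(self.min_distance, self.max_distance, self.n_bins + 1)
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        return e


@dataclass
class PositionalBiasResult:
    mark_name: str
    fraction_per_bin: np.ndarray
    n_introns: int
    n_skipped: int


def spillover_filter(
    intron_cov: Mapping[str, float],
    promoter_exon_cov: Mapping[str, float],
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes whose first-intron coverage exceeds promoter + first exon.

    The comparison is strict: equal coverage (including 0 vs 0) excludes
    the gene, as does missing data on either side. The filter is applied
    per mark; pass the coverages for one mark at a time. Returns the
    surviving gene list plus an exclusion log.
    """
    kept, log = [], []
    for gene in sorted(set(intron_cov) | set(promoter_exon_cov)):
        ic = intron_cov.get(gene)
        pc = promoter_exon_cov.get(gene)
        if ic is None or pc is None or math.isnan(ic) or math.isnan(pc):
            log.append((gene, "missing_data", ic, pc))
        elif ic > pc:
            kept.append(gene)
        else:
            log.append((gene, "promoter_spillover", ic, pc))
    log_df = pd.DataFrame(
        log, columns=["gene_id", "reason", "intron_cov", "promoter_exon_cov"]
    )
    return kept, log_df


def overlap_filter(
    first_introns: Mapping[str, GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    flank: int = 2000,
) -> tuple[list[str], pd.DataFrame]:
    """Drop genes whose first intron intersects another gene's exons/flanks.

    ``first_introns`` maps gene id -> raw first-intron interval. Every exon
    and both ``flank``-bp flanks of every *other* gene count as forbidden
    territory.
    """
    cfg = FilterConfig(flank_length=flank)
    forbidden: dict[str, list[tuple[int, int, str]]] = {}
    for t in transcripts:
        regions = list(t.exons) + list(flank_regions(t, cfg))
        for iv in regions:
            forbidden.setdefault(iv.chrom, []).append((iv.start, iv.end, t.gene_id))
    by_chrom = {}
    for chrom, rows in forbidden.items():
        rows.sort()
        by_chrom[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=object),
        )
    kept, log = [], []
    for gene in sorted(first_introns):
        iv = first_introns[gene]
        hit = None
        if iv.chrom in by_chrom:
            starts, ends, owners = by_chrom[iv.chrom]
            cand = np.flatnonzero((starts < iv.end) & (ends > iv.start))
            for j in cand:
                if owners[j] != gene:
                    hit = owners[j]
                    break
        if hit is None:
            kept.append(gene)
        else:
            log.append((gene, "overlaps_other_gene", hit))
    log_df = pd.DataFrame(log, columns=["gene_id", "reason", "other_gene"])
    return kept, log_df


def tss_matched_compare(
    first: Sequence[tuple[int, float]],
    second: Sequence[tuple[int, float]],
    bins: DistanceBinSpec | None = None,
    min_per_side: int = 3,
) -> pd.DataFrame:
    """Per-distance-bin comparison of first vs second intron values.

    ``first``/``second`` are (tss_distance, value) pairs. Only introns with
    distance inside [min_distance, max_distance] (both edges inclusive)
    enter; within each bin a one-sided rank-sum test (first > second) is
    reported alongside medians and counts, with the p omitted (NaN,
    ``underpowered`` flag) below ``min_per_side`` introns on either side.
    """
    bins = bins or DistanceBinSpec()
    edges = bins.bin_edges()

    def _assign(pairs):
        d = np.array([p[0] for p in pairs], dtype=float)
        v = np.array([p[1] for p in pairs], dtype=float)
        ok = (d >= edges[0]) & (d <= edges[-1]) & ~np.isnan(v)
        d, v = d[ok], v[ok]
        bins = np.clip(np.digitize(d, edges, right=False) - 1, 0, len(edges) - 2)
        return bins, v

    b1, v1 = _assign(first)
    b2, v2 = _assign(second)
    rows = []
    for k in range(len(edges) - 1):
        a = v1[b1 == k]
        b = v2[b2 == k]
        row = {
            "bin_low": edges[k],
            "bin_high": edges[k + 1],
            "n_first": len(a),
            "n_second": len(b),
            "median_first": float(np.median(a)) if len(a) else float("nan"),
            "median_second": float(np.median(b)) if len(b) else float("nan"),
        }
        if len(a) >= min_per_side and len(b) >= min_per_side:
            row["p_greater"] = rank_sum_test(a, b, "greater")
            row["underpowered"] = False
        else:
            row["p_greater"] = float("nan")
            row["underpowered"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def _bin_density(
    intron: IntronRecord, signal: PeakSet | ScoreTrack, n_bins: int
) -> np.ndarray | None:
    """Per-bin signal density across the intron's trimmed span, 5' -> 3'."""
    if not intron.analysis_regions:
        return None
    span_start = intron.analysis_regions[0].start
    span_end = intron.analysis_regions[-1].end
    if span_end - span_start < n_bins:
        return None
    edges = np.linspace(span_start, span_end, n_bins + 1).astype(np.int64)
    dens = np.empty(n_bins)
    chrom = intron.raw.chrom
    for k in range(n_bins):
        region = GenomicInterval(chrom, int(edges[k]), int(edges[k + 1]))
        if isinstance(signal, ScoreTrack):
            dens[k] = signal.mean_score(region)
        else:
            ps, pe = signal.chrom_arrays(chrom)
            dens[k] = (
                overlap_size(
                    np.array([region.start]), np.array([region.end]), ps, pe
                )
                / region.length
            )
    if intron.raw.strand == "-":
        dens = dens[::-1]  # report bins in transcript orientation
    return dens


def positional_bias(
    introns: Sequence[IntronRecord],
    signal: PeakSet | ScoreTrack,
    n_bins: int = 5,
    mark_name: str | None = None,
) -> PositionalBiasResult:
    """Distribution of the argmax-signal bin across long first introns.

    Introns shorter than the cohort median raw length are excluded before
    binning; each surviving intron's trimmed span is cut into ``n_bins``
    equal bins (5' to 3' in transcript orientation) and the bin holding the
    highest signal density is recorded, ties resolved toward the 5'-most
    bin. Introns with no signal anywhere are skipped and counted
    separately. Fractions sum to 1 over the non-skipped introns.
    """
    if not introns:
        raise ValueError("no introns supplied")
    median_len = float(np.median([i.raw_length for i in introns]))
    cohort = [i for i in introns if i.raw_length >= median_len]
    counts = np.zeros(n_bins, dtype=np.int64)
    n_skipped = 0
    for intron in cohort:
        dens = _bin_density(intron, signal, n_bins)
        if dens is None or np.all(dens == 0):
            n_skipped += 1
            continue
        counts[int(np.argmax(dens))] += 1  # argmax takes the 5'-most tie
    total = int(counts.sum())
    fractions = counts / total if total else np.full(n_bins, float("nan"))
    name = mark_name or getattr(signal, "mark_name", "track")
    return PositionalBiasResult(name, fractions, total, n_skipped)
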