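"""Gene models, intron derivation and the cohort filtering rules.

Introns are the gaps between consecutive exons of a transcript, ranked by
ordinal position from the transcript's 5' end (ordinal 1 = first intron).
The cohort filters drop very short introns (< 1 kb by default), drop
length outliers above Q3 + 1.5 x IQR of the surviving pooled lengths, trim
300 bp off both intron ends to avoid splicing signals, and remove
repeat-masked bases. 2 kb flanking regions proxy the promoter (upstream)
and the 3' flank (downstream) of a transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, subtract_intervals, total_length

__all__ = [
    "TranscriptModel",
    "IntronRecord",
    "FilterConfig",
    "extract_introns",
    "filter_introns",
    "trim_and_mask",
    "flank_regions",
    "tss_distance",
    "select_representative",
    "read_gtf",
    "read_bed12",
    "read_bed_intervals",
    "write_intron_table",
]


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on one strand; introns/flanks/TSS derive from it."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"{self.transcript_id}: exon on wrong chromosome")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """TSS coordinate: 5'-most transcribed position in transcript orientation."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end


@dataclass
class IntronRecord:
    """One intron with its ordinal rank and filtered analysis sub-regions."""

    transcript_id: str
    gene_id: str
    ordinal: int
    raw: GenomicInterval
    analysis_regions: list[GenomicInterval] = field(default_factory=list)

    @property
    def raw_length(self) -> int:
        return self.raw.length

    @property
    def effective_length(self) -> int:
        return total_length(self.analysis_regions)

    @property
    def excluded(self) -> bool:
        """True once trimming/masking left nothing to analyse."""
        return self.effective_length == 0


@dataclass(frozen=True)
class FilterConfig:
    min_intron_length: int = 1000
    trim: int = 300
    conservation_threshold: float = 0.5
    flank_length: int = 2000
    iqr_factor: float = 1.5
    repeat_mode: str = "mask"  # "mask" removes bases, "drop" removes introns

    def __post_init__(self) -> None:
        if min(self.min_intron_length, self.trim, self.flank_length) <= 0:
            raise ValueError("lengths must be positive")
        if 2 * self.trim >= self.min_intron_length:
            raise ValueError("trim * 2 must be < min_intron_length")
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must be in (0, 1]")
        if self.repeat_mode not in ("mask", "drop"):
            raise ValueError("repeat_mode must be 'mask' or 'drop'")


def extract_introns(t: TranscriptModel) -> list[IntronRecord]:
    """Introns of ``t`` with ordinals counted from the transcript's 5' end.

    A transcript with n exons yields n-1 introns; on the minus strand the
    genomically rightmost gap is ordinal 1.
    """
    gaps = [
        GenomicInterval(t.chrom, prev.end, cur.start, t.strand)
        for prev, cur in zip(t.exons, t.exons[1:])
    ]
    if t.strand == "-":
        gaps = gaps[::-1]
    return [
        IntronRecord(t.transcript_id, t.gene_id, k, gap)
        for k, gap in enumerate(gaps, start=1)
    ]


def length_ceiling(lengths: Sequence[int], iqr_factor: float = 1.5) -> float:
    """Outlier ceiling Q3 + factor x IQR (linear-interpolated quartiles)."""
    arr = np.asarray(lengths, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return float(q3 + iqr_factor * (q3 - q1))


def filter_introns(
    introns: Sequence[IntronRecord], cfg: FilterConfig | None = None
) -> list[IntronRecord]:
    """Apply the length floor then the pooled Q3 + 1.5 x IQR outlier ceiling.

    The ceiling is computed over the raw lengths of the introns that survive
    the floor, pooled across all ordinals; the comparison is strictly
    greater, so introns exactly at the ceiling are retained.
    """
    cfg = cfg or FilterConfig()
    survivors = [i for i in introns if i.raw_length >= cfg.min_intron_length]
    if not survivors:
        return []
    ceiling = length_ceiling([i.raw_length for i in survivors], cfg.iqr_factor)
    return [i for i in survivors if i.raw_length <= ceiling]


def trim_and_mask(
    intron: IntronRecord,
    mask: Sequence[GenomicInterval],
    cfg: FilterConfig | None = None,
) -> IntronRecord:
    """Trim ``cfg.trim`` bases off both genomic ends and subtract the mask.

    In "drop" repeat mode an intron whose trimmed body overlaps any masked
    base comes back with empty analysis regions (flagged for exclusion).
    """
    cfg = cfg or FilterConfig()
    s = intron.raw.start + cfg.trim
    e = intron.raw.end - cfg.trim
    if e <= s:
        return replace(intron, analysis_regions=[])
    body = GenomicInterval(intron.raw.chrom, s, e, intron.raw.strand)
    mask_here = [m for m in mask if m.chrom == body.chrom and m.overlaps(body)]
    if cfg.repeat_mode == "drop" and mask_here:
        return replace(intron, analysis_regions=[])
    regions = subtract_intervals([body], mask_here)
    return replace(intron, analysis_regions=regions)


def flank_regions(
    t: TranscriptModel, cfg: FilterConfig | None = None
) -> tuple[GenomicInterval, GenomicInterval]:
    """(upstream, downstream) flanks in transcript orientation, clipped at 0."""
    cfg = cfg or FilterConfig()
    L = cfg.flank_length
    left = GenomicInterval(
        t.chrom, max(0, t.span.start - L), t.span.start, t.strand
    )
    right = GenomicInterval(t.chrom, t.span.end, t.span.end + L, t.strand)
    if t.strand == "+":
        return left, right
    return right, left


def tss_distance(intron: IntronRecord, t: TranscriptModel) -> int:
    """Genomic (unspliced) distance from the TSS to the intron's 5' boundary."""
    if t.strand == "+":
        d = intron.raw.start - t.tss
    else:
        d = t.tss - intron.raw.end
    if d < 0:
        raise ValueError(
            f"{intron.transcript_id} intron {intron.ordinal} upstream of TSS"
        )
    return d


def select_representative(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """One transcript per gene: most exons, widest span, then smallest id."""
    if not transcripts:
        raise ValueError("no transcripts to choose from")
    return min(
        transcripts,
        key=lambda t: (-len(t.exons), -t.span.length, t.transcript_id),
    )


# ---------------------------------------------------------------------------
# readers / writers

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Transcript models from the exon features of a GTF file.

    Only ``exon`` rows are consumed; 1-based inclusive GTF coordinates are
    converted to the internal 0-based half-open convention. Exons are
    grouped by ``transcript_id`` (``gene_id`` defaults to the transcript id
    when absent).
    """
    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = _parse_attrs(f[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            rec = by_tx.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": f[0],
                    "strand": f[6],
                    "exons": [],
                },
            )
            rec["exons"].append(
                GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    out = []
    for tid in sorted(by_tx):
        rec = by_tx[tid]
        exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
        out.append(
            TranscriptModel(tid, rec["gene_id"], rec["chrom"], rec["strand"], exons)
        )
    return out


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Transcript models from BED12 (blocks = exons, name = transcript id)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + sz, strand)
                for o, sz in zip(offsets, sizes)
            )
            out.append(TranscriptModel(name, name, chrom, strand, exons))
    return sorted(out, key=lambda t: t.transcript_id)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Plain BED3+ intervals (strand column honoured when present)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_intron_table(introns: Iterable[IntronRecord], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": i.transcript_id,
            "gene_id": i.gene_id,
            "ordinal": i.ordinal,
            "chrom": i.raw.chrom,
            "raw_start": i.raw.start,
            "raw_end": i.raw.end,
            "strand": i.raw.strand,
            "raw_length": i.raw_length,
            "effective_length": i.effective_length,
            "n_analysis_regions": len(i.analysis_regions),
        }
        for i in introns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    return genes
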