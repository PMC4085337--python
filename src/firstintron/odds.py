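"""Gene-wise log-odds enrichment of a mark in conserved first-intron bases.

For one gene, the analysed first-intron bases are partitioned by
conservation (score >= threshold) and by peak overlap, giving a 2x2 table
of base counts:

    SC  signal bases on conserved sites      NC  non-signal, conserved
    SN  signal bases on non-conserved sites  NN  non-signal, non-conserved

The odds ratio OR = (SC x NN) / (NC x SN) compares the proportion of
signal-covered bases between the conserved and non-conserved parts; its
log gets a Woolf-type 95% CI, log OR +/- z * sqrt(1/SC + 1/NC + 1/SN +
1/NN), and a Wald p-value. A single zero cell triggers the
Haldane-Anscombe correction (+0.5 to every cell, flagged); two or more
zero cells leave the gene undefined and excluded from cohort tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats as sps

from .annotation import IntronRecord
from .coverage import PeakSet, ScoreTrack, partition_by_conservation
from .intervals import merge_arrays, overlap_size, to_arrays

__all__ = [
    "ContingencyTable2x2",
    "OddsResult",
    "build_table",
    "odds_ratio",
    "cohort_tally",
    "write_odds_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    sc: int
    nc: int
    sn: int
    nn: int

    def __post_init__(self) -> None:
        if min(self.sc, self.nc, self.sn, self.nn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.sc + self.nc + self.sn + self.nn

    @property
    def n_zero_cells(self) -> int:
        return sum(c == 0 for c in (self.sc, self.nc, self.sn, self.nn))


@dataclass
class OddsResult:
    log_odds: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool
    sig_level: float = 0.01

    @property
    def defined(self) -> bool:
        return not math.isnan(self.log_odds)

    @property
    def significant(self) -> bool:
        return self.defined and self.p_value < self.sig_level


UNDEFINED_ODDS = OddsResult(*([float("nan")] * 4), corrected=False)


def build_table(
    first_intron: IntronRecord,
    track: ScoreTrack,
    peaks: PeakSet,
    threshold: float = 0.5,
) -> ContingencyTable2x2:
    """Base-count 2x2 table over the intron's analysis regions.

    Cells always sum to the intron's effective length.
    """
    if first_intron.effective_length == 0:
        raise ValueError(
            f"{first_intron.transcript_id}: no analysable bases in first intron"
        )
    cons, noncons = partition_by_conservation(
        first_intron.analysis_regions, track, threshold
    )
    chrom = first_intron.raw.chrom
    ps, pe = peaks.chrom_arrays(chrom)
    n_cons = sum(iv.length for iv in cons)
    n_noncons = sum(iv.length for iv in noncons)
    sc = overlap_size(*merge_arrays(*to_arrays(cons)), ps, pe) if cons else 0
    sn = overlap_size(*merge_arrays(*to_arrays(noncons)), ps, pe) if noncons else 0
    return ContingencyTable2x2(sc, n_cons - sc, sn, n_noncons - sn)


def odds_ratio(
    tbl: ContingencyTable2x2, alpha: float = 0.05, sig_level: float = 0.01
) -> OddsResult:
    """Log odds ratio with Woolf CI and Wald p; 0.5-corrected on one zero cell."""
    if tbl.n_zero_cells >= 2:
        return OddsResult(
            *([float("nan")] * 4), corrected=False, sig_level=sig_level
        )
    corrected = tbl.n_zero_cells == 1
    shift = 0.5 if corrected else 0.0
    sc, nc, sn, nn = (
        tbl.sc + shift,
        tbl.nc + shift,
        tbl.sn + shift,
        tbl.nn + shift,
    )
    log_odds = math.log(sc * nn / (nc * sn))
    se = math.sqrt(1 / sc + 1 / nc + 1 / sn + 1 / nn)
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(log_odds) / se)
    return OddsResult(
        log_odds, log_odds - z * se, log_odds + z * se, float(p), corrected,
        sig_level,
    )


def cohort_tally(
    results: Mapping[str, Mapping[str, OddsResult]],
) -> pd.DataFrame:
    """Per-mark counts of significantly enriched genes.

    ``results`` maps mark -> gene -> OddsResult. Genes with an undefined
    log-odds are excluded from the totals (missing data).
    """
    rows = []
    for mark in sorted(results):
        per_gene = [r for r in results[mark].values() if r.defined]
        rows.append(
            {
                "mark": mark,
                "n_total": len(per_gene),
                "n_sig_positive": sum(
                    r.significant and r.log_odds > 0 for r in per_gene
                ),
                "n_sig_negative": sum(
                    r.significant and r.log_odds < 0 for r in per_gene
                ),
            }
        )
    return pd.DataFrame(rows)


def write_odds_table(
    results: Mapping[str, Mapping[str, tuple[ContingencyTable2x2, OddsResult]]],
    path,
) -> None:
    """Per-gene TSV: mark, gene, cells, log-odds, CI, p, corrected flag."""
    rows = []
    for mark in sorted(results):
        for gene in sorted(results[mark]):
            tbl, res = results[mark][gene]
            rows.append(
                {
                    "gene_id": gene,
                    "mark": mark,
                    "SC": tbl.sc,
                    "NC": tbl.nc,
                    "SN": tbl.sn,
                    "NN": tbl.nn,
                    "log_odds": res.log_odds,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "corrected": int(res.corrected),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
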