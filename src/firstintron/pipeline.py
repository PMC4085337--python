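"""End-to-end orchestration: annotation -> coverage -> statistics -> report.

``run_pipeline`` reads one input bundle (GTF + conservation track + repeat
mask + per-mark peak BEDs + expression TSV), applies the cohort filters,
computes every analysis table and writes them to the output directory with
a provenance header. The same code path serves synthetic and real bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import annotation as ann
from . import controls as ctl
from . import coverage as cov
from . import odds as god
from . import stats as gst
from .intervals import GenomicInterval, merge_intervals

log = logging.getLogger("firstintron")

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    gtf: Path
    conservation: Path
    mask: Path | None
    peaks: dict[str, Path]
    expression: Path | None
    outdir: Path
    filters: ann.FilterConfig = field(default_factory=ann.FilterConfig)
    representative: bool = False
    drop_zero_zero: bool = True
    expression_is_log2p1: bool = True
    bin_size_cons: int = 10
    bin_size_expr: int = 50
    alpha: float = 0.05
    sig_p: float = 0.01
    max_ordinal: int = 20
    regression_ordinals: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def digest(self) -> str:
        """Hash of the analysis parameters (input paths excluded)."""
        skip = {"gtf", "conservation", "mask", "peaks", "expression", "outdir"}
        payload = {
            k: str(v) for k, v in sorted(vars(self).items()) if k not in skip
        }
        payload["marks"] = ",".join(sorted(self.peaks))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunResult:
    tables: dict[str, pd.DataFrame]
    counts: dict[str, int]

    def write(self, outdir: Path, header: str) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        with open(outdir / "counts.json", "w") as fh:
            json.dump(self.counts, fh, indent=1, sort_keys=True)


def _load_inputs(cfg: RunConfig):
    transcripts = ann.read_gtf(cfg.gtf)
    track = cov.read_bedgraph(cfg.conservation)
    mask = ann.read_bed_intervals(cfg.mask) if cfg.mask else []
    peaks = {
        m: cov.read_peaks(p, mark_name=m) for m, p in sorted(cfg.peaks.items())
    }
    expr = None
    if cfg.expression:
        expr = pd.read_csv(cfg.expression, sep="\t")
        tissue_cols = [c for c in expr.columns if c != "gene_id"]
        if not cfg.expression_is_log2p1:
            expr[tissue_cols] = np.log2(expr[tissue_cols] + 1)
    return transcripts, track, mask, peaks, expr


def _prepare_introns(cfg: RunConfig, transcripts, mask):
    """Cohort assembly: extract, length-filter (pooled), trim and mask."""
    genes = ann.group_by_gene(transcripts)
    if cfg.representative:
        kept_tx = [ann.select_representative(ts) for ts in genes.values()]
    else:
        kept_tx = transcripts
    raw = [i for t in kept_tx for i in ann.extract_introns(t)]
    filtered = ann.filter_introns(raw, cfg.filters)
    mask_by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in mask:
        mask_by_chrom.setdefault(m.chrom, []).append(m)
    prepared = []
    for i in filtered:
        rec = ann.trim_and_mask(i, mask_by_chrom.get(i.raw.chrom, []), cfg.filters)
        if not rec.excluded:
            prepared.append(rec)
    tx_by_id = {t.transcript_id: t for t in kept_tx}
    counts = {
        "transcripts": len(kept_tx),
        "genes": len(genes),
        "introns_raw": len(raw),
        "introns_length_filtered": len(filtered),
        "introns_analysable": len(prepared),
    }
    return prepared, tx_by_id, genes, counts


def _summarize(regions, track, peaks, threshold):
    cf = cov.conserved_fraction(regions, track, threshold)
    return cf, {m: cov.coverage_fraction(regions, p) for m, p in peaks.items()}


def run_pipeline(cfg: RunConfig) -> RunResult:
    transcripts, track, mask, peaks, expr = _load_inputs(cfg)
    introns, tx_by_id, genes, counts = _prepare_introns(cfg, transcripts, mask)
    thr = cfg.filters.conservation_threshold
    tables: dict[str, pd.DataFrame] = {}

    # per-intron summaries -------------------------------------------------
    log.info("summarizing %d introns", len(introns))
    rows = []
    for rec in introns:
        cf, covs = _summarize(rec.analysis_regions, track, peaks, thr)
        t = tx_by_id[rec.transcript_id]
        row = {
            "transcript_id": rec.transcript_id,
            "gene_id": rec.gene_id,
            "ordinal": rec.ordinal,
            "n_exons": len(t.exons),
            "raw_length": rec.raw_length,
            "effective_length": rec.effective_length,
            "tss_distance": ann.tss_distance(rec, t),
            "conserved_fraction": cf,
        }
        row.update({f"cov_{m}": v for m, v in covs.items()})
        rows.append(row)
    intron_df = pd.DataFrame(rows)
    tables["intron_summaries"] = intron_df

    mark_names = sorted(peaks)

    # ordinal group analyses ----------------------------------------------
    table = gst.ordinal_summary(
        zip(intron_df["ordinal"], intron_df["conserved_fraction"]),
        max_ordinal=cfg.max_ordinal,
    )
    tables["ordinal_conservation"] = table.summary()
    tests = gst.first_vs_rest_test(table, "greater")
    tables["ordinal_tests"] = pd.DataFrame(
        [
            {"value": "conserved_fraction", "comparison": str(k), "p_greater": p}
            for k, p in tests.items()
        ]
    )
    sig_rows = []
    for m in mark_names:
        t_m = gst.ordinal_summary(
            zip(intron_df["ordinal"], intron_df[f"cov_{m}"]),
            max_ordinal=cfg.max_ordinal,
        )
        s = t_m.summary()
        s.insert(0, "mark", m)
        sig_rows.append(s)
    tables["ordinal_signal"] = pd.concat(sig_rows, ignore_index=True)

    # correlations in first introns ---------------------------------------
    first = intron_df[intron_df["ordinal"] == 1]
    corr_rows = []
    for m in mark_names:
        _, binned, raw = gst.binned_kendall(
            first["conserved_fraction"],
            first[f"cov_{m}"],
            cfg.bin_size_cons,
            cfg.drop_zero_zero,
        )
        corr_rows.append(
            {
                "mark": m,
                "tau_binned": binned.tau,
                "p_binned": binned.p_value,
                "tau_raw": raw.tau,
                "p_raw": raw.p_value,
                "n_raw": raw.n,
            }
        )
    tables["signal_correlations"] = pd.DataFrame(corr_rows)

    # exon-count group regressions ----------------------------------------
    reg_rows = []
    for k in cfg.regression_ordinals:
        sub = intron_df[intron_df["ordinal"] == k]
        for value in ["conserved_fraction"] + [f"cov_{m}" for m in mark_names]:
            reg = gst.exon_group_regression(zip(sub["n_exons"], sub[value]))
            reg_rows.append(
                {
                    "ordinal": k,
                    "value": value,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "n_groups": reg.n_groups,
                }
            )
    tables["exon_regressions"] = pd.DataFrame(reg_rows)

    # per-gene first-intron view ------------------------------------------
    # one representative transcript per gene for gene-keyed analyses
    rep_tx = {g: ann.select_representative(ts) for g, ts in genes.items()}
    rep_ids = {t.transcript_id for t in rep_tx.values()}
    first_rep = first[first["transcript_id"].isin(rep_ids)]
    gene_cons = dict(zip(first_rep["gene_id"], first_rep["conserved_fraction"]))

    # expression correlations ----------------------------------------------
    if expr is not None:
        ex_rows = []
        tissue_cols = [c for c in expr.columns if c != "gene_id"]
        for tcol in tissue_cols:
            emap = dict(zip(expr["gene_id"], expr[tcol]))
            _, binned, raw = gst.expression_correlation(
                gene_cons, emap, cfg.bin_size_expr, cfg.drop_zero_zero
            )
            ex_rows.append(
                {
                    "tissue": tcol,
                    "tau_binned": binned.tau,
                    "p_binned": binned.p_value,
                    "tau_raw": raw.tau,
                    "p_raw": raw.p_value,
                    "n_raw": raw.n,
                }
            )
        tables["expression_correlations"] = pd.DataFrame(ex_rows)

    # gene-wise odds ratios -------------------------------------------------
    first_recs = {
        rec.gene_id: rec
        for rec in introns
        if rec.ordinal == 1 and rec.transcript_id in rep_ids
    }
    odds_results: dict[str, dict[str, god.OddsResult]] = {}
    odds_detail: dict[str, dict[str, tuple]] = {}
    for m in mark_names:
        per_gene = {}
        detail = {}
        for gid, rec in first_recs.items():
            tbl = god.build_table(rec, track, peaks[m], thr)
            res = god.odds_ratio(tbl, cfg.alpha, cfg.sig_p)
            per_gene[gid] = res
            detail[gid] = (tbl, res)
        odds_results[m] = per_gene
        odds_detail[m] = detail
    tables["odds_tally"] = god.cohort_tally(odds_results)
    odds_rows = []
    for m in mark_names:
        for gid in sorted(odds_detail[m]):
            tbl, res = odds_detail[m][gid]
            odds_rows.append(
                {
                    "gene_id": gid,
                    "mark": m,
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
    tables["odds_per_gene"] = pd.DataFrame(odds_rows)

    # controls --------------------------------------------------------------
    # promoter + first-exon pooled coverage per gene, per mark
    promoter_cov: dict[str, dict[str, float]] = {m: {} for m in mark_names}
    intron_cov: dict[str, dict[str, float]] = {m: {} for m in mark_names}
    for gid, rec in first_recs.items():
        t = rep_tx[gid]
        upstream, _ = ann.flank_regions(t, cfg.filters)
        first_exon = t.exons[0] if t.strand == "+" else t.exons[-1]
        region = merge_intervals(
            [
                GenomicInterval(t.chrom, upstream.start, upstream.end, t.strand),
                GenomicInterval(t.chrom, first_exon.start, first_exon.end, t.strand),
            ]
        )
        for m in mark_names:
            promoter_cov[m][gid] = cov.coverage_fraction(region, peaks[m])
            intron_cov[m][gid] = cov.coverage_fraction(
                rec.analysis_regions, peaks[m]
            )
    spill_rows, spill_logs = [], []
    survivors: dict[str, list[str]] = {}
    for m in mark_names:
        kept, excl = ctl.spillover_filter(intron_cov[m], promoter_cov[m])
        survivors[m] = kept
        excl.insert(0, "mark", m)
        spill_logs.append(excl)
        spill_rows.extend({"mark": m, "gene_id": g} for g in kept)
    tables["spillover_survivors"] = pd.DataFrame(spill_rows)
    nonempty = [df for df in spill_logs if not df.empty]
    tables["spillover_exclusions"] = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(
            columns=["mark", "gene_id", "reason", "intron_cov", "promoter_exon_cov"]
        )
    )

    first_iv = {gid: rec.raw for gid, rec in first_recs.items()}
    overlap_kept, overlap_log = ctl.overlap_filter(
        first_iv, transcripts, cfg.filters.flank_length
    )
    tables["overlap_survivors"] = pd.DataFrame({"gene_id": overlap_kept})
    tables["overlap_exclusions"] = overlap_log
    counts["overlap_survivors"] = len(overlap_kept)

    # trends after both filters (per mark)
    filt_rows = []
    for m in mark_names:
        keep = set(survivors[m]) & set(overlap_kept)
        sub = first[first["gene_id"].isin(keep)]
        _, binned, raw = gst.binned_kendall(
            sub["conserved_fraction"],
            sub[f"cov_{m}"],
            cfg.bin_size_cons,
            cfg.drop_zero_zero,
        )
        filt_rows.append(
            {
                "mark": m,
                "n_genes": len(sub),
                "tau_binned": binned.tau,
                "p_binned": binned.p_value,
                "tau_raw": raw.tau,
                "p_raw": raw.p_value,
            }
        )
    tables["filtered_correlations"] = pd.DataFrame(filt_rows)

    # conservation ordinal trend after the overlap filter
    sub = intron_df[
        intron_df["gene_id"].isin(overlap_kept)
        | (intron_df["ordinal"] > 1)  # other ordinals unaffected by the rule
    ]
    t_f = gst.ordinal_summary(
        zip(sub["ordinal"], sub["conserved_fraction"]), max_ordinal=cfg.max_ordinal
    )
    tables["ordinal_conservation_filtered"] = t_f.summary()

    # TSS-distance-matched first vs second introns
    bin_spec = ctl.DistanceBinSpec()
    tss_rows = []
    for value in ["conserved_fraction"] + [f"cov_{m}" for m in mark_names]:
        f_pairs = list(
            zip(first["tss_distance"], first[value])
        )
        second = intron_df[intron_df["ordinal"] == 2]
        s_pairs = list(zip(second["tss_distance"], second[value]))
        df = ctl.tss_matched_compare(f_pairs, s_pairs, bin_spec)
        df.insert(0, "value", value)
        tss_rows.append(df)
    tables["tss_matched"] = pd.concat(tss_rows, ignore_index=True)

    # positional bias of the strongest signal along first introns
    first_intron_recs = [rec for rec in introns if rec.ordinal == 1]
    pos_rows = []
    for m in mark_names:
        res = ctl.positional_bias(first_intron_recs, peaks[m], mark_name=m)
        pos_rows.append(
            {
                "signal": m,
                **{f"bin{k + 1}": res.fraction_per_bin[k] for k in range(5)},
                "n_introns": res.n_introns,
                "n_skipped": res.n_skipped,
            }
        )
    res = ctl.positional_bias(first_intron_recs, track, mark_name="conservation")
    pos_rows.append(
        {
            "signal": "conservation",
            **{f"bin{k + 1}": res.fraction_per_bin[k] for k in range(5)},
            "n_introns": res.n_introns,
            "n_skipped": res.n_skipped,
        }
    )
    tables["positional_bias"] = pd.DataFrame(pos_rows)

    result = RunResult(tables, counts)
    header = (
        f"# firstintron run config={cfg.digest()} seed={cfg.seed} "
        f"threshold={thr}\n"
    )
    result.write(Path(cfg.outdir), header)
    return result
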