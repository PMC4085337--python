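"""Synthetic genome bundle with planted conservation/regulatory structure.

The generator emits a complete input bundle — exon-level GTF, bedGraph
conservation track, repeat-mask BED, one peak BED per regulatory mark, an
expression TSV and a truth JSON — through the same file formats the
pipeline consumes for real data, with every statistical structure the
analysis assumes planted at configurable strength:

* multi-exon transcripts whose first introns are the longest (a lognormal
  mixture also supplies a short-first-intron subpopulation so the TSS
  distance window where first and second introns overlap is non-empty);
* a blocky conservation track whose expected conserved fraction decays
  with intron ordinal (c_1 > c_2 > c_3 > c_4 = c_5 = ...), modulated per
  gene by a latent propensity that also couples to exon count and to
  expression via Gaussian copulas with rank correlations tau_exons and
  tau_expr;
* per-mark signal: inside raw first introns the signal indicator is
  per-base independent with a two-rate Bernoulli model (rate logit shifted
  by the planted log-odds on conserved bases), which realizes the planted
  per-gene odds ratio exactly and keeps the per-base 2x2 sampling model of
  the gene-wise Wald test correct; everywhere else peaks are placed as a
  blocky renewal process with mark-specific widths (narrow for DHS/TFBS/
  H3K4me3, broad for H3K4me1/H3K9me3);
* expression values on the log2(RPKM + 1) scale for four pseudo-tissues.

Identical configs and seeds produce byte-identical bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["MarkModel", "SimConfig", "SimBundle", "simulate", "spike_spillover"]

TISSUES = ("hypothalamus", "heart", "skeletal_muscle", "lung")


@dataclass(frozen=True)
class MarkModel:
    """Planted placement model for one regulatory mark."""

    background_rate: float  # per-base coverage everywhere outside first introns
    first_intron_rate: float  # per-base rate on non-conserved first-intron bases
    log_odds: float  # planted log odds ratio on conserved first-intron bases
    peak_width: float  # mean width of background peaks (bp)

    def conserved_rate(self) -> float:
        logit = math.log(self.first_intron_rate / (1 - self.first_intron_rate))
        return 1 / (1 + math.exp(-(logit + self.log_odds)))


def default_marks() -> dict[str, MarkModel]:
    return {
        "DHS": MarkModel(0.03, 0.08, 1.0, 150.0),
        "TFBS": MarkModel(0.02, 0.06, 1.0, 200.0),
        "H3K4me1": MarkModel(0.05, 0.08, -0.4, 800.0),
        "H3K4me3": MarkModel(0.04, 0.08, 0.8, 400.0),
        "H3K9me3": MarkModel(0.05, 0.05, -0.3, 900.0),
        "CTCF": MarkModel(0.02, 0.03, 0.0, 300.0),
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_genes: int = 2000
    seed: int = 0
    n_chromosomes: int = 8
    # exon count marginal: 2 + negative binomial, truncated at max_exons
    exon_nbinom_n: float = 3.0
    exon_nbinom_p: float = 0.3
    max_exons: int = 25
    # intron length models (lognormal medians / sigmas, bp)
    first_intron_long_median: float = 7000.0
    first_intron_long_sigma: float = 0.4
    first_intron_short_median: float = 400.0
    first_intron_short_sigma: float = 0.6
    short_first_fraction: float = 0.25
    other_intron_median: float = 2300.0
    other_intron_sigma: float = 0.7
    # exon length models
    first_exon_median: float = 450.0
    first_exon_sigma: float = 0.6
    internal_exon_median: float = 150.0
    internal_exon_sigma: float = 0.4
    last_exon_median: float = 800.0
    last_exon_sigma: float = 0.5
    # conservation block model
    c_ordinals: tuple[float, ...] = (0.08, 0.05, 0.03, 0.02)
    flank_cons_rate: float = 0.03
    exon_cons_rate: float = 0.4
    decoy_rate: float = 0.04  # sub-threshold score blocks
    block_mean_length: float = 40.0
    sigma_c1: float = 0.5  # lognormal spread of per-gene first-intron rate
    # planted couplings (Kendall tau)
    tau_exons: float = 0.3
    tau_expr: float = 0.3
    tissue_noise: float = 0.3
    # marks
    marks: dict[str, MarkModel] = field(default_factory=default_marks)
    # repeats
    repeat_density: float = 0.08
    repeat_median: float = 250.0
    repeat_sigma: float = 0.7
    # layout / extras
    intergenic_gap: int = 6000
    n_overlap_genes: int = 0  # host genes given a nested gene in intron 1
    alt_transcript_fraction: float = 0.0
    trim: int = 300

    def __post_init__(self) -> None:
        rates = [self.flank_cons_rate, self.exon_cons_rate, self.decoy_rate]
        rates += list(self.c_ordinals)
        for m in self.marks.values():
            rates += [m.background_rate, m.first_intron_rate, m.conserved_rate()]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if min(self.first_intron_long_median, self.other_intron_median) <= 2 * self.trim:
            raise ValueError(
                "expected intron length must exceed twice the end trim"
            )

    @classmethod
    def null(cls, n_genes: int = 1000, seed: int = 0, **kw) -> "SimConfig":
        """All planted effects zero: flat ordinal conservation, no mark
        coupling to conservation, no exon-count or expression coupling."""
        marks = {
            name: MarkModel(m.background_rate, m.background_rate, 0.0, m.peak_width)
            for name, m in default_marks().items()
        }
        return cls(
            n_genes=n_genes,
            seed=seed,
            c_ordinals=(0.03,),
            tau_exons=0.0,
            tau_expr=0.0,
            marks=marks,
            **kw,
        )

    def c_for_ordinal(self, k: int) -> float:
        return self.c_ordinals[min(k, len(self.c_ordinals)) - 1]


@dataclass
class SimBundle:
    """Paths of one emitted bundle plus its truth record."""

    outdir: Path
    gtf: Path
    conservation: Path
    repeats: Path
    peak_files: dict[str, Path]
    expression: Path
    truth_file: Path
    truth: dict

    @classmethod
    def load(cls, outdir: str | Path) -> "SimBundle":
        outdir = Path(outdir)
        truth_file = outdir / "truth.json"
        truth = json.loads(truth_file.read_text())
        peak_files = {
            m: outdir / f"peaks_{m}.bed" for m in truth["params"]["marks"]
        }
        return cls(
            outdir,
            outdir / "genes.gtf",
            outdir / "conservation.bedGraph",
            outdir / "repeats.bed",
            peak_files,
            outdir / "expression.tsv",
            truth_file,
            truth,
        )


# ---------------------------------------------------------------------------
# internal generation helpers


def _lognormal_int(rng, median: float, sigma: float, size=None, lo: int = 8):
    vals = np.exp(np.log(median) + sigma * rng.standard_normal(size))
    return np.maximum(lo, np.rint(vals).astype(np.int64))


def _block_process(
    rng, start: int, end: int, rate: float, mean_len: float
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating renewal blocks with per-base occupancy ``rate``."""
    length = end - start
    if length <= 0 or rate <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    mean_gap = max(1.0, mean_len * (1 - rate) / rate)
    n_est = int(length / (mean_len + mean_gap) * 2 + 10)
    gaps = rng.geometric(min(1.0, 1 / mean_gap), n_est)
    lens = rng.geometric(min(1.0, 1 / mean_len), n_est)
    # stationary start: the region opens inside a block with probability
    # `rate`; geometric residual lengths are again geometric (memoryless)
    if rng.random() < rate:
        gaps[0] = 0
    starts = start + np.cumsum(gaps + lens) - lens
    ends = np.minimum(starts + lens, end)
    keep = starts < end
    return starts[keep], ends[keep]


def _bernoulli_runs(
    rng, starts: np.ndarray, ends: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """I.i.d. per-base sampling over an interval set, returned as runs."""
    lens = ends - starts
    total = int(lens.sum())
    if total == 0 or rate <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    k = rng.binomial(total, rate)
    if k == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    offsets = np.sort(rng.choice(total, size=k, replace=False))
    cum = np.concatenate(([0], np.cumsum(lens)))
    idx = np.searchsorted(cum, offsets, side="right") - 1
    pos = starts[idx] + (offsets - cum[idx])
    breaks = np.flatnonzero(np.diff(pos) > 1)
    run_starts = pos[np.concatenate(([0], breaks + 1))]
    run_ends = pos[np.concatenate((breaks, [pos.size - 1]))] + 1
    return run_starts, run_ends


def _complement_within(
    span: tuple[int, int], starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    s = np.concatenate(([span[0]], ends))
    e = np.concatenate((starts, [span[1]]))
    keep = e > s
    return s[keep], e[keep]


# ---------------------------------------------------------------------------
# main generator


def simulate(cfg: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate a synthetic input bundle under ``cfg`` into ``outdir``."""
    from .intervals import merge_arrays, subtract_arrays

    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n = cfg.n_genes
    # latent conservation propensity -> per-gene first-intron block rate
    z = rng.standard_normal(n)
    base_c1 = cfg.c_for_ordinal(1)
    c1_rate = np.clip(
        base_c1 * np.exp(cfg.sigma_c1 * z - cfg.sigma_c1**2 / 2), 1e-4, 0.5
    )

    short_first = rng.random(n) < cfg.short_first_fraction
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # realize first-intron conservation blocks up front (local coordinates)
    # so exon counts and expression can be rank-coupled to the *realized*
    # conserved fraction, the quantity the pipeline later measures
    fi_lens = np.where(
        short_first,
        _lognormal_int(
            rng, cfg.first_intron_short_median, cfg.first_intron_short_sigma, n
        ),
        _lognormal_int(
            rng, cfg.first_intron_long_median, cfg.first_intron_long_sigma, n
        ),
    )
    fi_blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    realized_c1 = np.empty(n)
    for i in range(n):
        L = int(fi_lens[i])
        total_rate = float(c1_rate[i]) + cfg.decoy_rate
        bs, be = _block_process(rng, 0, L, total_rate, cfg.block_mean_length)
        q = float(c1_rate[i]) / total_rate if total_rate > 0 else 0.0
        is_cons = rng.random(bs.size) < q
        scores = np.where(
            is_cons,
            rng.uniform(0.5, 1.0, bs.size),
            rng.uniform(0.05, 0.45, bs.size),
        )
        fi_blocks.append((bs, be, scores, is_cons))
        lo, hi = (cfg.trim, L - cfg.trim) if L > 2 * cfg.trim else (0, L)
        cs, ce = bs[is_cons], be[is_cons]
        covered = np.maximum(
            0, np.minimum(ce, hi) - np.maximum(cs, lo)
        ).sum() if cs.size else 0
        realized_c1[i] = covered / max(1, hi - lo)

    # Gaussian-copula couplings against the realized conserved fraction.
    # Normal scores are taken within each length stratum (short/long first
    # introns) so the coupling is homogeneous across gene classes rather
    # than concentrated in the high-dispersion short-intron subgroup.
    s_cons = np.empty(n)
    for grp in (short_first, ~short_first):
        idx = np.flatnonzero(grp)
        if idx.size:
            r = np.empty(idx.size)
            r[np.argsort(realized_c1[idx], kind="stable")] = np.arange(
                1, idx.size + 1
            )
            s_cons[idx] = sps.norm.ppf(r / (idx.size + 1))
    rho_e = math.sin(math.pi * cfg.tau_exons / 2)
    rho_x = math.sin(math.pi * cfg.tau_expr / 2)
    x_exon = rho_e * s_cons + math.sqrt(1 - rho_e**2) * rng.standard_normal(n)
    w_expr = rho_x * s_cons + math.sqrt(1 - rho_x**2) * rng.standard_normal(n)

    nb = sps.nbinom(cfg.exon_nbinom_n, cfg.exon_nbinom_p)
    u = np.clip(sps.norm.cdf(x_exon), 1e-12, 1 - 1e-12)
    n_exons = 2 + np.minimum(nb.ppf(u).astype(np.int64), cfg.max_exons - 2)

    # expression: monotone in (coupled latent + tissue noise), log2(RPKM+1)
    expr = {}
    for t in TISSUES:
        wt = w_expr + cfg.tissue_noise * rng.standard_normal(n)
        rpkm = np.exp(1.0 + 1.2 * wt)
        expr[t] = np.log2(rpkm + 1)

    gene_ids = [f"G{i:05d}" for i in range(n)]
    chrom_of = [f"chr{1 + i % cfg.n_chromosomes}" for i in range(n)]
    cursor = {f"chr{c + 1}": 10_000 for c in range(cfg.n_chromosomes)}

    gtf_rows: list[tuple] = []
    cons_blocks: list[tuple[str, int, int, float]] = []
    first_intron_iv: dict[str, tuple[str, int, int, str]] = {}
    mark_rows: dict[str, list[tuple[str, int, int]]] = {m: [] for m in cfg.marks}
    truth_genes = []
    # (chrom, start, end, conserved starts, ends within) per first intron
    fi_registry = []

    overlap_hosts: set[int] = set()
    if cfg.n_overlap_genes:
        eligible = np.flatnonzero(~short_first)
        overlap_hosts = set(
            rng.choice(eligible, min(cfg.n_overlap_genes, eligible.size), False)
        )

    alt_tx = rng.random(n) < cfg.alt_transcript_fraction

    for i in range(n):
        gid = gene_ids[i]
        chrom = chrom_of[i]
        strand = strands[i]
        ne = int(n_exons[i])
        # lengths in transcript order
        exon_lens = np.empty(ne, np.int64)
        exon_lens[0] = _lognormal_int(rng, cfg.first_exon_median, cfg.first_exon_sigma)
        if ne > 2:
            exon_lens[1:-1] = _lognormal_int(
                rng, cfg.internal_exon_median, cfg.internal_exon_sigma, ne - 2
            )
        exon_lens[-1] = _lognormal_int(rng, cfg.last_exon_median, cfg.last_exon_sigma)
        intron_lens = np.empty(ne - 1, np.int64)
        intron_lens[0] = fi_lens[i]
        if ne > 2:
            intron_lens[1:] = _lognormal_int(
                rng, cfg.other_intron_median, cfg.other_intron_sigma, ne - 2
            )

        # lay out genomically left-to-right; transcript order reverses on '-'
        tx_order = np.arange(ne)
        if strand == "-":
            exon_g = exon_lens[::-1]
            intron_g = intron_lens[::-1]
            intron_ordinal_g = np.arange(ne - 1, 0, -1)
        else:
            exon_g = exon_lens
            intron_g = intron_lens
            intron_ordinal_g = np.arange(1, ne)

        start = cursor[chrom]
        pos = start
        exon_coords = []
        intron_coords = []
        for j in range(ne):
            exon_coords.append((pos, pos + int(exon_g[j])))
            pos += int(exon_g[j])
            if j < ne - 1:
                intron_coords.append((pos, pos + int(intron_g[j])))
                pos += int(intron_g[j])
        gene_end = pos
        cursor[chrom] = gene_end + cfg.intergenic_gap

        tid = f"{gid}.t1"
        for (es, ee) in exon_coords:
            gtf_rows.append((chrom, es, ee, strand, gid, tid))
        if alt_tx[i] and ne >= 3:
            # shorter isoform: drop one internal exon (genomic index ne//2)
            tid2 = f"{gid}.t2"
            for j, (es, ee) in enumerate(exon_coords):
                if j != ne // 2:
                    gtf_rows.append((chrom, es, ee, strand, gid, tid2))

        # conservation: pre-realized blocks for intron 1, fresh block
        # processes for every other region
        g_first = int(np.flatnonzero(intron_ordinal_g == 1)[0])
        fs, fe = intron_coords[g_first]
        regions = [(s_, e_, cfg.exon_cons_rate) for s_, e_ in exon_coords]
        for g_idx, (s_, e_) in enumerate(intron_coords):
            k = int(intron_ordinal_g[g_idx])
            if k != 1:
                regions.append((s_, e_, cfg.c_for_ordinal(k)))
        regions.append((max(0, start - 2000), start, cfg.flank_cons_rate))
        regions.append((gene_end, gene_end + 2000, cfg.flank_cons_rate))

        gene_cons: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for (s_, e_, c_rate) in regions:
            total_rate = c_rate + cfg.decoy_rate
            bs, be = _block_process(rng, s_, e_, total_rate, cfg.block_mean_length)
            if bs.size == 0:
                gene_cons[(s_, e_)] = (bs, be)
                continue
            q = c_rate / total_rate if total_rate > 0 else 0.0
            is_cons = rng.random(bs.size) < q
            scores = np.where(
                is_cons,
                rng.uniform(0.5, 1.0, bs.size),
                rng.uniform(0.05, 0.45, bs.size),
            )
            for b0, b1, sc in zip(bs, be, scores):
                cons_blocks.append((chrom, int(b0), int(b1), float(sc)))
            gene_cons[(s_, e_)] = (bs[is_cons], be[is_cons])

        # offset the pre-realized intron-1 blocks into genomic coordinates
        lbs, lbe, lscores, lcons = fi_blocks[i]
        for b0, b1, sc in zip(lbs + fs, lbe + fs, lscores):
            cons_blocks.append((chrom, int(b0), int(b1), float(sc)))

        # first intron registry + per-base mark placement inside it
        first_intron_iv[gid] = (chrom, fs, fe, strand)
        c_s, c_e = merge_arrays(
            np.minimum(lbs[lcons] + fs, fe), np.minimum(lbe[lcons] + fs, fe)
        )
        nc_s, nc_e = _complement_within((fs, fe), c_s, c_e)
        fi_registry.append((chrom, fs, fe))
        for mname, m in cfg.marks.items():
            p1 = m.conserved_rate()
            s1, e1 = _bernoulli_runs(rng, c_s, c_e, p1)
            s0, e0 = _bernoulli_runs(rng, nc_s, nc_e, m.first_intron_rate)
            rows = mark_rows[mname]
            rows.extend((chrom, int(a), int(b)) for a, b in zip(s1, e1))
            rows.extend((chrom, int(a), int(b)) for a, b in zip(s0, e0))

        truth_genes.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "n_exons": ne,
                "short_first_intron": bool(short_first[i]),
                "first_intron_length": int(fe - fs),
                "c1_rate": float(c1_rate[i]),
                "realized_c1": float(realized_c1[i]),
                "latent_z": float(z[i]),
                "mean_expression": float(np.mean([expr[t][i] for t in TISSUES])),
                "nested_gene": bool(i in overlap_hosts),
            }
        )

    # planted nested genes inside selected hosts' first introns
    for i in sorted(overlap_hosts):
        gid = gene_ids[i]
        chrom, fs, fe, strand = first_intron_iv[gid]
        mid = (fs + fe) // 2
        if mid + 500 >= fe:
            continue
        ngid = f"{gid}_nested"
        tid = f"{ngid}.t1"
        e1 = (mid, mid + 100)
        e2 = (mid + 300, mid + 450)
        for (es, ee) in (e1, e2):
            gtf_rows.append((chrom, es, ee, "+", ngid, tid))

    # chromosome lengths from final cursors
    chrom_len = {c: cursor[c] + 10_000 for c in cursor}

    # background peaks: blocky renewal everywhere, minus raw first introns
    fi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, fs, fe in fi_registry:
        fi_by_chrom.setdefault(chrom, []).append((fs, fe))
    fi_arrays = {}
    for chrom, ivs in fi_by_chrom.items():
        ivs.sort()
        fi_arrays[chrom] = merge_arrays(
            np.array([a for a, _ in ivs], np.int64),
            np.array([b for _, b in ivs], np.int64),
        )
    for mname, m in cfg.marks.items():
        rows = mark_rows[mname]
        for chrom in sorted(chrom_len):
            bs, be = _block_process(
                rng, 0, chrom_len[chrom], m.background_rate, m.peak_width
            )
            if chrom in fi_arrays:
                bs, be = subtract_arrays(bs, be, *fi_arrays[chrom])
            rows.extend((chrom, int(a), int(b)) for a, b in zip(bs, be))

    # repeat mask: uniform lognormal-width intervals across each chromosome
    repeat_rows = []
    for chrom in sorted(chrom_len):
        rs, re_ = _block_process(
            rng, 0, chrom_len[chrom], cfg.repeat_density, cfg.repeat_median
        )
        repeat_rows.extend((chrom, int(a), int(b)) for a, b in zip(rs, re_))

    # ------------------------------------------------------------------ emit
    gtf_path = outdir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for chrom, es, ee, strand, gid, tid in sorted(gtf_rows):
            fh.write(
                f"{chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";\n'
            )

    cons_path = outdir / "conservation.bedGraph"
    cons_blocks.sort()
    with open(cons_path, "w") as fh:
        for chrom, s_, e_, sc in cons_blocks:
            fh.write(f"{chrom}\t{s_}\t{e_}\t{sc:.4f}\n")

    rep_path = outdir / "repeats.bed"
    with open(rep_path, "w") as fh:
        for chrom, s_, e_ in sorted(repeat_rows):
            fh.write(f"{chrom}\t{s_}\t{e_}\trepeat\t0\t+\n")

    peak_files = {}
    for mname in cfg.marks:
        p = outdir / f"peaks_{mname}.bed"
        rows = sorted(mark_rows[mname])
        with open(p, "w") as fh:
            for chrom, s_, e_ in rows:
                fh.write(f"{chrom}\t{s_}\t{e_}\n")
        peak_files[mname] = p

    expr_path = outdir / "expression.tsv"
    expr_df = pd.DataFrame({"gene_id": gene_ids})
    for t in TISSUES:
        expr_df[t] = np.round(expr[t], 6)
    expr_df.to_csv(expr_path, sep="\t", index=False)

    truth = {
        "params": {
            "n_genes": n,
            "seed": cfg.seed,
            "c_ordinals": list(cfg.c_ordinals),
            "sigma_c1": cfg.sigma_c1,
            "tau_exons": cfg.tau_exons,
            "tau_expr": cfg.tau_expr,
            "marks": {
                mname: {
                    "background_rate": m.background_rate,
                    "first_intron_rate": m.first_intron_rate,
                    "log_odds": m.log_odds,
                    "peak_width": m.peak_width,
                }
                for mname, m in cfg.marks.items()
            },
        },
        "genes": truth_genes,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return SimBundle(
        outdir,
        gtf_path,
        cons_path,
        rep_path,
        peak_files,
        expr_path,
        truth_path,
        truth,
    )


def spike_spillover(
    bundle: SimBundle, genes: Sequence[str], mark: str = "DHS"
) -> SimBundle:
    """Extend promoter signal into the first intron for chosen genes.

    For every listed gene one synthetic peak is appended to ``mark``'s BED
    file covering the 2 kb promoter, the first exon and the 5' half of the
    first intron — after which the spillover filter must exclude the gene
    (promoter + first-exon coverage 1.0 is always at least as high as the
    intron coverage).
    """
    from .annotation import extract_introns, read_gtf

    if not genes:
        return bundle
    wanted = set(genes)
    extra = []
    for t in read_gtf(bundle.gtf):
        if t.gene_id not in wanted or len(t.exons) < 2:
            continue
        introns = extract_introns(t)
        first = introns[0].raw
        if t.strand == "+":
            s = max(0, t.span.start - 2000)
            e = first.start + first.length // 2
        else:
            s = first.end - first.length // 2
            e = t.span.end + 2000
        extra.append((t.chrom, s, e))
    path = bundle.peak_files[mark]
    rows = [line.rstrip("\n").split("\t") for line in path.read_text().splitlines()]
    rows = [(r[0], int(r[1]), int(r[2])) for r in rows if r and r[0]]
    rows.extend(extra)
    with open(path, "w") as fh:
        for chrom, s_, e_ in sorted(rows):
            fh.write(f"{chrom}\t{s_}\t{e_}\n")
    return bundle
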