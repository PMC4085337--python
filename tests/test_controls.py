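"""Promoter-confounder controls: filters, TSS matching, positional bias."""

import math

import numpy as np
import pytest

from firstintron.annotation import IntronRecord, TranscriptModel
from firstintron.controls import (
    DistanceBinSpec,
    overlap_filter,
    positional_bias,
    spillover_filter,
    tss_matched_compare,
)
from firstintron.coverage import PeakSet, ScoreTrack
from firstintron.intervals import GenomicInterval

R = lambda s, e: GenomicInterval("chr1", s, e)


def tx(exons, gid, strand="+", chrom="chr1"):
    return TranscriptModel(
        f"{gid}.t1", gid, chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


class TestSpilloverFilter:
    def test_intron_dominant_kept(self):
        kept, log = spillover_filter({"g": 0.3}, {"g": 0.1})
        assert kept == ["g"] and log.empty

    def test_equal_coverage_excluded(self):
        kept, log = spillover_filter({"g": 0.2}, {"g": 0.2})
        assert kept == []
        assert log.iloc[0]["reason"] == "promoter_spillover"

    def test_zero_everywhere_excluded(self):
        kept, _ = spillover_filter({"g": 0.0}, {"g": 0.0})
        assert kept == []

    def test_missing_data_logged(self):
        kept, log = spillover_filter({"a": 0.5}, {"b": 0.1})
        assert kept == []
        assert set(log["reason"]) == {"missing_data"}

    def test_idempotent(self):
        ic = {"a": 0.5, "b": 0.1, "c": 0.2}
        pc = {"a": 0.1, "b": 0.4, "c": 0.2}
        kept, _ = spillover_filter(ic, pc)
        again, _ = spillover_filter(
            {g: ic[g] for g in kept}, {g: pc[g] for g in kept}
        )
        assert again == kept


class TestOverlapFilter:
    def test_isolated_gene_kept(self):
        t = tx([(10_000, 10_100), (20_000, 20_100)], "g1")
        kept, _ = overlap_filter({"g1": R(10_100, 20_000)}, [t])
        assert kept == ["g1"]

    def test_nested_gene_exon_removes_host(self):
        host = tx([(10_000, 10_100), (30_000, 30_100)], "host")
        nested = tx([(15_000, 15_100), (15_400, 15_500)], "nested")
        kept, log = overlap_filter({"host": R(10_100, 30_000)}, [host, nested])
        assert kept == []
        assert log.iloc[0]["other_gene"] == "nested"

    def test_neighbour_flank_within_2kb_removes(self):
        g1 = tx([(10_000, 10_100), (20_000, 20_100)], "g1")
        # neighbour's first exon starts 1999 bases after g1's intron end
        g2 = tx([(21_999, 22_100), (25_000, 25_100)], "g2")
        kept, _ = overlap_filter({"g1": R(10_100, 20_000)}, [g1, g2])
        assert kept == []
        # at exactly 2000 bases the flank no longer reaches the intron
        g3 = tx([(22_000, 22_100), (25_000, 25_100)], "g3")
        kept2, _ = overlap_filter({"g1": R(10_100, 20_000)}, [g1, g3])
        assert kept2 == ["g1"]

    def test_order_commutes_with_spillover(self):
        genes = {"a": 0.5, "b": 0.5}
        promo = {"a": 0.1, "b": 0.9}
        t_a = tx([(10_000, 10_100), (20_000, 20_100)], "a")
        t_b = tx([(50_000, 50_100), (60_000, 60_100)], "b")
        ivs = {"a": R(10_100, 20_000), "b": R(50_100, 60_000)}
        s_first, _ = spillover_filter(genes, promo)
        o_then = [
            g for g in overlap_filter(
                {g: ivs[g] for g in s_first}, [t_a, t_b]
            )[0]
        ]
        o_first, _ = overlap_filter(ivs, [t_a, t_b])
        s_then = [
            g
            for g in spillover_filter(
                {g: genes[g] for g in o_first}, {g: promo[g] for g in o_first}
            )[0]
        ]
        assert sorted(o_then) == sorted(s_then)


class TestTssMatched:
    def test_identical_distributions_p_near_half(self):
        rng = np.random.default_rng(31)
        first = [(int(d), float(v)) for d, v in
                 zip(rng.integers(500, 1001, 400), rng.random(400))]
        second = [(int(d), float(v)) for d, v in
                  zip(rng.integers(500, 1001, 400), rng.random(400))]
        df = tss_matched_compare(first, second)
        assert np.all(df["p_greater"].between(0.05, 0.95))

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(32)
        first = [(int(d), float(v) + 0.3) for d, v in
                 zip(rng.integers(500, 1001, 500), rng.random(500))]
        second = [(int(d), float(v)) for d, v in
                  zip(rng.integers(500, 1001, 500), rng.random(500))]
        df = tss_matched_compare(first, second)
        assert np.all(df["p_greater"] < 0.01)

    def test_window_edges_inclusive(self):
        first = [(500, 1.0), (500, 2.0), (500, 3.0), (1000, 1.0)]
        second = [(499, 9.0), (1001, 9.0), (700, 0.5), (720, 0.4), (710, 0.3)]
        df = tss_matched_compare(first, second)
        assert df["n_first"].sum() == 4  # 499/1001 excluded from second
        assert df["n_second"].sum() == 3
        assert df.iloc[-1]["n_first"] == 1  # distance 1000 lands in last bin

    def test_underpowered_bins_flagged(self):
        df = tss_matched_compare([(510, 1.0)], [(510, 0.5)])
        assert bool(df.iloc[0]["underpowered"])
        assert math.isnan(df.iloc[0]["p_greater"])

    def test_custom_edges_validated(self):
        with pytest.raises(ValueError):
            DistanceBinSpec(edges=(500, 500, 1000)).bin_edges()


def intron_rec(start, end, strand="+", trim=300):
    raw = GenomicInterval("chr1", start, end, strand)
    body = GenomicInterval("chr1", start + trim, end - trim, strand)
    return IntronRecord("tx", "g", 1, raw, [body])


class TestPositionalBias:
    def test_signal_in_five_prime_fifth_only(self):
        recs = [intron_rec(0, 5600) for _ in range(4)]
        # analysis span [300,5300); first fifth is [300,1300)
        pk = PeakSet.from_intervals("m", [R(400, 900)])
        res = positional_bias(recs, pk)
        assert res.fraction_per_bin.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_uniform_signal_ties_to_first_bin(self):
        recs = [intron_rec(0, 5600)]
        pk = PeakSet.from_intervals("m", [R(0, 6000)])
        res = positional_bias(recs, pk)
        assert res.fraction_per_bin[0] == 1.0

    def test_minus_strand_reports_transcript_orientation(self):
        # genomically rightmost fifth = transcript 5' bin on the minus strand
        recs = [intron_rec(0, 5600, strand="-")]
        pk = PeakSet.from_intervals("m", [R(4500, 5200)])
        res = positional_bias(recs, pk)
        assert res.fraction_per_bin[0] == 1.0

    def test_all_zero_signal_skipped_and_counted(self):
        recs = [intron_rec(0, 5600), intron_rec(10_000, 15_600)]
        pk = PeakSet.from_intervals("m", [R(400, 500)])
        res = positional_bias(recs, pk)
        assert res.n_introns == 1 and res.n_skipped == 1

    def test_short_introns_excluded_by_cohort_median(self):
        long = [intron_rec(0, 9000)] * 3
        short = [intron_rec(20_000, 21_000, trim=300)] * 2
        pk = PeakSet.from_intervals("m", [R(0, 50_000)])
        res = positional_bias(long + short, pk)
        assert res.n_introns == 3  # only introns at/above the median length

    def test_fractions_sum_to_one_with_score_track(self):
        rng = np.random.default_rng(41)
        recs = [intron_rec(int(s), int(s) + 7000) for s in rng.integers(0, 1_000_000, 20) * 10]
        steps = []
        for r in recs:
            for _ in range(5):
                s = int(rng.integers(r.raw.start, r.raw.end - 50))
                steps.append(("chr1", s, s + int(rng.integers(5, 40)), float(rng.random())))
        steps.sort(key=lambda t: t[1])
        merged = []
        last_end = -1
        for c, s, e, v in steps:  # drop overlapping decoys for a valid track
            if s > last_end:
                merged.append((c, s, e, v))
                last_end = e
        track = ScoreTrack.from_steps(merged)
        res = positional_bias(recs, track)
        assert res.fraction_per_bin.sum() == pytest.approx(1.0)
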