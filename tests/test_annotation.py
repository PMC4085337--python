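"""Intron extraction, ordinal assignment and the cohort filtering rules."""

import numpy as np

from firstintron.annotation import (
    FilterConfig,
    IntronRecord,
    TranscriptModel,
    extract_introns,
    filter_introns,
    flank_regions,
    group_by_gene,
    length_ceiling,
    read_bed12,
    read_gtf,
    select_representative,
    trim_and_mask,
    tss_distance,
)
from firstintron.intervals import GenomicInterval


def make_tx(exons, strand="+", tid="tx1", gid="g1", chrom="chr1"):
    return TranscriptModel(
        tid, gid, chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


class TestExtractIntrons:
    def test_single_exon_has_no_introns(self):
        assert extract_introns(make_tx([(0, 100)])) == []

    def test_plus_strand_ordinals(self):
        t = make_tx([(0, 100), (200, 300), (450, 600)])
        introns = extract_introns(t)
        assert [(i.ordinal, i.raw.start, i.raw.end) for i in introns] == [
            (1, 100, 200),
            (2, 300, 450),
        ]

    def test_minus_strand_first_intron_is_rightmost(self):
        t = make_tx([(0, 100), (200, 300)], strand="-")
        (intron,) = extract_introns(t)
        assert intron.ordinal == 1
        assert (intron.raw.start, intron.raw.end) == (100, 200)

    def test_strand_symmetry_reverses_ordinals(self):
        exons = [(0, 50), (120, 180), (400, 480), (900, 1000)]
        plus = extract_introns(make_tx(exons))
        minus = extract_introns(make_tx(exons, strand="-"))
        assert [(i.raw.start, i.raw.end) for i in plus] == [
            (i.raw.start, i.raw.end) for i in reversed(minus)
        ]
        assert [i.ordinal for i in minus] == [1, 2, 3]

    def test_exons_and_introns_tile_the_span(self):
        t = make_tx([(10, 50), (80, 130), (200, 260)])
        pieces = sorted(
            [(e.start, e.end) for e in t.exons]
            + [(i.raw.start, i.raw.end) for i in extract_introns(t)]
        )
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2  # contiguous, no gaps or overlaps


def _introns_with_lengths(lengths):
    out = []
    pos = 0
    for k, L in enumerate(lengths):
        iv = GenomicInterval("chr1", pos, pos + L)
        out.append(IntronRecord("tx", "g", k + 1, iv))
        pos += L + 10
    return out


class TestFilterIntrons:
    def test_short_introns_removed(self):
        assert filter_introns(_introns_with_lengths([500, 900])) == []

    def test_outlier_rule_uses_post_floor_cohort(self):
        lengths = [1200, 1500, 2000, 2500, 100000]
        kept = filter_introns(_introns_with_lengths(lengths))
        ceiling = length_ceiling(lengths)  # Q3 + 1.5 * IQR, linear quartiles
        expected = [L for L in lengths if L <= ceiling]
        assert [i.raw_length for i in kept] == expected
        assert 100000 not in [i.raw_length for i in kept]

    def test_equal_lengths_all_retained(self):
        # IQR = 0 -> ceiling equals the common length; rule is strictly greater
        kept = filter_introns(_introns_with_lengths([2000] * 5))
        assert len(kept) == 5

    def test_floor_is_inclusive_and_order_preserved(self):
        recs = _introns_with_lengths([1000, 5000, 1200])
        kept = filter_introns(recs)
        assert [i.raw_length for i in kept] == [1000, 5000, 1200]

    def test_reapplication_only_shrinks(self):
        rng = np.random.default_rng(0)
        lengths = np.rint(np.exp(rng.normal(7.8, 0.8, 300))).astype(int)
        once = filter_introns(_introns_with_lengths(lengths))
        twice = filter_introns(once)
        assert set(id(i) for i in twice) <= set(id(i) for i in once)


class TestTrimAndMask:
    cfg = FilterConfig()

    def rec(self, start=0, end=1000):
        return IntronRecord("tx", "g", 1, GenomicInterval("chr1", start, end))

    def test_pure_trim(self):
        out = trim_and_mask(self.rec(), [], self.cfg)
        assert out.analysis_regions == [GenomicInterval("chr1", 300, 700)]
        assert out.effective_length == 400

    def test_mask_splits_regions(self):
        out = trim_and_mask(self.rec(), [GenomicInterval("chr1", 400, 500)], self.cfg)
        assert out.analysis_regions == [
            GenomicInterval("chr1", 300, 400),
            GenomicInterval("chr1", 500, 700),
        ]
        assert out.effective_length == 300

    def test_total_masking_flags_exclusion(self):
        out = trim_and_mask(self.rec(), [GenomicInterval("chr1", 0, 1000)], self.cfg)
        assert out.analysis_regions == []
        assert out.excluded

    def test_drop_mode_discards_repeat_overlapping_introns(self):
        cfg = FilterConfig(repeat_mode="drop")
        out = trim_and_mask(self.rec(), [GenomicInterval("chr1", 400, 410)], cfg)
        assert out.excluded
        # repeat outside the trimmed body does not trigger the drop
        out2 = trim_and_mask(self.rec(), [GenomicInterval("chr1", 10, 20)], cfg)
        assert not out2.excluded

    def test_effective_at_most_raw_minus_trims(self):
        out = trim_and_mask(self.rec(0, 1500), [], self.cfg)
        assert out.effective_length == out.raw_length - 600


class TestFlanksAndTss:
    def test_plus_strand_upstream(self):
        t = make_tx([(5000, 5100), (6000, 6200)])
        up, down = flank_regions(t)
        assert (up.start, up.end) == (3000, 5000)
        assert (down.start, down.end) == (6200, 8200)

    def test_upstream_clipped_at_zero(self):
        up, _ = flank_regions(make_tx([(800, 900), (1500, 1600)]))
        assert (up.start, up.end) == (0, 800)

    def test_minus_strand_mirror(self):
        t = make_tx([(5000, 5100), (6000, 6200)], strand="-")
        up, down = flank_regions(t)
        assert (up.start, up.end) == (6200, 8200)
        assert (down.start, down.end) == (3000, 5000)

    def test_tss_distance_examples(self):
        t = make_tx([(0, 100), (200, 300)])
        (i1,) = extract_introns(t)
        assert tss_distance(i1, t) == 100
        t2 = make_tx([(0, 100), (200, 300), (450, 600)])
        introns = extract_introns(t2)
        assert tss_distance(introns[1], t2) == 300  # genomic, unspliced

    def test_tss_distance_minus_strand_symmetric(self):
        t = make_tx([(0, 100), (200, 300)], strand="-")
        (i1,) = extract_introns(t)
        assert i1.ordinal == 1
        assert tss_distance(i1, t) == 100  # |300 - 200|


class TestRepresentative:
    def test_singleton(self):
        t = make_tx([(0, 100)])
        assert select_representative([t]) is t

    def test_most_exons_wins(self):
        t5 = make_tx([(i * 100, i * 100 + 50) for i in range(5)], tid="a")
        t3 = make_tx([(i * 100, i * 100 + 50) for i in range(3)], tid="b")
        assert select_representative([t3, t5]) is t5

    def test_ties_break_by_span_then_id(self):
        a = make_tx([(0, 50), (100, 200)], tid="tx_b")
        b = make_tx([(0, 50), (100, 200)], tid="tx_a")
        assert select_representative([a, b]) is b
        wide = make_tx([(0, 50), (300, 400)], tid="tx_c")
        assert select_representative([a, wide]) is wide


class TestReaders:
    def test_gtf_round_trip_coordinates(self, tmp_path):
        p = tmp_path / "x.gtf"
        p.write_text(
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "# a comment line\n"
            "chr1\tsrc\tCDS\t1\t50\t.\t+\t.\t"
            'gene_id "g"; transcript_id "t";\n'
        )
        (t,) = read_gtf(p)
        assert [(e.start, e.end) for e in t.exons] == [(0, 100), (200, 300)]
        assert t.gene_id == "g"

    def test_bed12_blocks_become_exons(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t1000\t2000\ttxA\t0\t-\t1000\t2000\t0\t2\t100,200,\t0,800,\n")
        (t,) = read_bed12(p)
        assert t.strand == "-"
        assert [(e.start, e.end) for e in t.exons] == [(1000, 1100), (1800, 2000)]

    def test_generator_gtf_satisfies_invariants(self, small_bundle):
        txs = read_gtf(small_bundle.gtf)
        assert len(txs) > 150
        for t in txs:
            assert len(t.exons) >= 1  # constructor enforces sort/overlap rules
        genes = group_by_gene(txs)
        reps = [select_representative(ts) for ts in genes.values()]
        assert len(reps) == len(genes)
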