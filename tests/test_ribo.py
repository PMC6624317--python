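"""P-site placement, triplet periodicity, uORF start selection, and
shifted-region quantification."""

import numpy as np
import pandas as pd
import pytest

from startshift.model import GenomicInterval, GenomicPosition, PipelineConfig
from startshift.ribo import (cumulative_coverage, filter_dominant_genes,
                             has_upstream_atg, phasing, psite_track,
                             region_rpkm, select_ectopic_atg, shifted_region,
                             shifted_region_rpkm, surrogate_region)
from startshift.tracks import FragmentSet, SignalTrack

CFG = PipelineConfig()


def frags(rows):
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                   "strand"]))


class TestPsiteTrack:
    def test_plus_strand_offset(self):
        t = psite_track(frags([("chr1", 100, 130, "+")]), CFG)
        assert t.window("chr1", "+", 112, 113)[0] == 1.0

    def test_minus_strand_reflects(self):
        # 5' end of a minus-strand fragment [171, 201) is genomic base 200
        t = psite_track(frags([("chr1", 171, 201, "-")]), CFG)
        assert t.window("chr1", "-", 188, 189)[0] == 1.0

    def test_count_conservation(self, rng):
        rows = [("chr1", int(s), int(s) + 30, "+")
                for s in rng.integers(100, 5000, 80)]
        assert psite_track(frags(rows), CFG).total() == 80


class TestPhasing:
    def _track(self, offsets, anchor=1000, strand="+"):
        t = SignalTrack()
        sgn = 1 if strand == "+" else -1
        for off, n in offsets.items():
            t.add("chr1", strand, anchor + sgn * off, float(n))
        return t

    def test_pure_frame0_gives_fraction_one(self):
        t = self._track({0: 50, 3: 50, 9: 20})
        r = phasing(t, GenomicPosition("chr1", 1000, "+"), CFG)
        assert r.frame0_fraction == 1.0
        assert sum(r.frame_counts) == 120

    def test_uniform_counts_give_chisq_zero(self):
        t = self._track({0: 100, 1: 100, 2: 100})
        r = phasing(t, GenomicPosition("chr1", 1000, "+"), CFG)
        assert r.chi_square == 0.0 and r.p == 1.0

    def test_closed_form_chi_square(self):
        """(180, 10, 10) against uniform: chi-square = 289."""
        t = self._track({0: 180, 1: 10, 2: 10})
        r = phasing(t, GenomicPosition("chr1", 1000, "+"), CFG)
        assert r.chi_square == pytest.approx(289.0)
        assert r.p < 1e-10

    def test_empty_span_is_neutral(self):
        r = phasing(SignalTrack(), GenomicPosition("chr1", 1000, "+"), CFG)
        assert r.p == 1.0 and r.total == 0

    def test_minus_strand_frames_follow_transcription(self):
        anchor = GenomicPosition("chr1", 5000, "-")
        t = self._track({0: 30, 3: 30, 6: 30}, anchor=5000, strand="-")
        r = phasing(t, anchor, CFG)
        assert r.frame0_fraction == 1.0


class TestAtgSelection:
    GENOME = {"chr1": "C" * 100 + "ATG" + "C" * 47 + "ATG" + "C" * 850}

    def test_highest_downstream_coverage_wins(self):
        psites = SignalTrack()
        for i in range(10):
            psites.add("chr1", "+", 103 + 3 * i, 10.0)  # feeds first ATG
        region = GenomicInterval("chr1", 90, 400, "+")
        a = select_ectopic_atg(self.GENOME, region, psites, CFG)
        assert a is not None and a.pos == 100

    def test_second_atg_wins_with_downstream_signal(self):
        psites = SignalTrack()
        # coverage beyond the first ATG's 60-nt window, inside the second's
        for i in range(10):
            psites.add("chr1", "+", 165 + 3 * i, 10.0)
        region = GenomicInterval("chr1", 90, 400, "+")
        a = select_ectopic_atg(self.GENOME, region, psites, CFG)
        assert a is not None and a.pos == 150

    def test_no_atg_returns_none(self):
        region = GenomicInterval("chr1", 0, 90, "+")
        assert select_ectopic_atg(self.GENOME, region, SignalTrack(),
                                  CFG) is None

    def test_coverage_tie_prefers_atg_nearest_region_start(self):
        region = GenomicInterval("chr1", 90, 400, "+")
        a = select_ectopic_atg(self.GENOME, region, SignalTrack(), CFG)
        assert a is not None and a.pos == 100


class TestUpstreamAtgScan:
    @pytest.mark.parametrize("seq,expected", [
        ("CCATGC", True),
        ("CCCCCC", False),
        ("CCCATC", False),   # CAT is reverse-complement ATG: sense-only scan
        ("atgCCC", True),
    ])
    def test_sense_strand_scan(self, seq, expected):
        assert has_upstream_atg(seq) is expected


class TestRegions:
    def test_shifted_region_plus_strand(self):
        r = shifted_region(ectopic_pos=900, observed_pos=1015, chrom="chr1",
                           strand="+", margin=25)
        assert (r.start, r.end) == (900, 991)   # inclusive of -25 base

    def test_shifted_region_minus_strand(self):
        r = shifted_region(ectopic_pos=1115, observed_pos=1000, chrom="chr1",
                           strand="-", margin=25)
        assert (r.start, r.end) == (1025, 1116)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            shifted_region(1000, 1010, "chr1", "+", margin=25)

    def test_surrogate_region_spans_115_to_25_upstream(self):
        r = surrogate_region(10_000, "chr1", "+", CFG)
        assert (r.start, r.end) == (10_000 - 115, 10_000 - 25 + 1)


class TestRpkm:
    def test_closed_form(self):
        assert region_rpkm(9, 90, 10_000_000) == pytest.approx(10.0)

    def test_zero_counts(self):
        assert region_rpkm(0, 90, 1_000_000) == 0.0

    def test_depth_doubling_halves(self):
        assert region_rpkm(9, 90, 20_000_000) == pytest.approx(5.0)

    def test_fragment_overlap_counting(self):
        region = GenomicInterval("chr1", 1000, 1090, "+")
        ctrl = frags([("chr1", 900, 1010, "+"),    # overlaps
                      ("chr1", 1089, 1150, "+"),   # overlaps by 1 base
                      ("chr1", 1090, 1200, "+")])  # abuts: no overlap
        kd = frags([("chr1", 1000, 1030, "+")])
        res = shifted_region_rpkm("g", region, ctrl, kd, 1e7, 1e7)
        assert res.control_count == 2 and res.kd_count == 1


class TestDominantGeneFilter:
    def test_strictly_above_five_percent_removed(self):
        counts = {"a": 60.0, "b": 50.0, "c": 1.0}
        kept = filter_dominant_genes(counts, 1000.0, CFG)
        assert kept == ["b", "c"]       # 6% out; exactly 5% stays

    def test_all_below_threshold_is_identity(self):
        counts = {"a": 1.0, "b": 2.0}
        assert filter_dominant_genes(counts, 1000.0, CFG) == ["a", "b"]


class TestCumulativeCoverage:
    def test_two_identical_anchors_double(self):
        t = SignalTrack()
        t.add("chr1", "+", 105, 4.0)
        t.add("chr1", "+", 205, 4.0)
        anchors = [GenomicPosition("chr1", 100, "+"),
                   GenomicPosition("chr1", 200, "+")]
        cov = cumulative_coverage(t, anchors, (0, 10))
        assert cov[5] == 8.0 and cov.sum() == 8.0

    def test_orientation_mirrors_on_minus(self):
        t = SignalTrack()
        t.add("chr1", "-", 95, 4.0)   # offset +5 of a minus anchor at 100
        cov = cumulative_coverage(t, [GenomicPosition("chr1", 100, "-")],
                                  (0, 10))
        assert cov[5] == 4.0
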