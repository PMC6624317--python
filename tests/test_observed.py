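"""Observed-TSS calling: hand traces, an exhaustive brute-force oracle,
call deduplication, and promoter binding classification."""

import numpy as np
import pytest

from startshift.model import (UNSTRANDED, GenomicInterval, GenomicPosition,
                              PipelineConfig)
from startshift.observed import (ObservedTssCall, call_observed_tss,
                                 classify_nfy_bound, deduplicate_calls)
from startshift.tracks import SignalTrack, TranscriptAnnotation

CFG = PipelineConfig()


def make_tx(tss=5000, strand="+", name="tx1", gene=None, low=False):
    start, end = (tss, tss + 2000) if strand == "+" else (tss - 1999, tss + 1)
    return TranscriptAnnotation(name, gene or name, "chr1", start, end,
                                strand, low_confidence=low)


def flat_polii(value=1.0, lo=0, hi=20000):
    t = SignalTrack()
    t.set_range("chr1", UNSTRANDED, lo, hi, value)
    return t


def track_with(entries, strand="+"):
    t = SignalTrack()
    for pos, val in entries:
        t.add("chr1", strand, pos, val)
    return t


class TestCallerRules:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_single_spike_moves_call(self, strand):
        tx = make_tx(strand=strand)
        pos = tx.tss + 50 if strand == "+" else tx.tss - 50
        t = track_with([(pos, 10.0)], strand)
        call = call_observed_tss(tx, t, flat_polii(), CFG)
        assert call.observed_pos == pos
        assert call.distance == 50
        assert call.source == "startseq_primary"

    def test_fewer_than_five_reads_keeps_annotation(self):
        tx = make_tx()
        t = track_with([(tx.tss + 50, 4.0)])
        call = call_observed_tss(tx, t, flat_polii(), CFG)
        assert call.observed_pos == tx.tss
        assert call.source == "annotation_lowreads"

    def test_five_reads_suffice(self):
        tx = make_tx()
        t = track_with([(tx.tss + 50, 5.0)])
        call = call_observed_tss(tx, t, flat_polii(), CFG)
        assert call.observed_pos == tx.tss + 50

    def test_polii_rescue_reselects_nearby(self):
        """A distal maximum in a Pol II desert falls back to the local best."""
        tx = make_tx()
        t = track_with([(tx.tss + 800, 50.0), (tx.tss + 30, 6.0)])
        polii = flat_polii(1.0)
        # starve Pol II around the distal site only
        polii.set_range("chr1", UNSTRANDED, tx.tss + 550, tx.tss + 1100, 0.0)
        call = call_observed_tss(tx, t, polii, CFG)
        assert call.observed_pos == tx.tss + 30
        assert call.source == "polII_rescued"

    def test_missing_chromosome_keeps_annotation(self):
        tx = make_tx()
        call = call_observed_tss(tx, SignalTrack(), flat_polii(), CFG)
        assert call.source == "annotation_kept"
        assert call.observed_pos == tx.tss

    def test_argmax_tie_prefers_position_nearest_annotation(self):
        tx = make_tx()
        t = track_with([(tx.tss + 200, 9.0), (tx.tss - 100, 9.0)])
        call = call_observed_tss(tx, t, flat_polii(), CFG)
        assert call.distance == -100


def oracle_observed(tx, start5p, polii, cfg):
    """Independent exhaustive re-implementation of the calling rules."""
    R = cfg.tss_search_radius
    sgn = 1 if tx.strand == "+" else -1

    def count_at(off):
        pos = tx.tss + sgn * off
        return float(start5p.window(tx.chrom, tx.strand, pos, pos + 1)[0])

    counts = {off: count_at(off) for off in range(-R, R + 1)}

    def best_in(offs):
        chosen = None
        for o in offs:
            if chosen is None:
                chosen = o
                continue
            if counts[o] > counts[chosen]:
                chosen = o
            elif counts[o] == counts[chosen]:
                if (abs(o), o) < (abs(chosen), chosen):
                    chosen = o
        return chosen

    cand_a = best_in(range(-R, R + 1))
    # densest 200-nt window, ties -> center closest to the annotation
    w = cfg.density_window
    best_start, best_key = None, None
    for s in range(-R, R - w + 2):
        total = sum(counts[o] for o in range(s, s + w))
        center = s + (w - 1) / 2
        key = (-total, abs(center), center)
        if best_key is None or key < best_key:
            best_start, best_key = s, key
    cand_b = best_in(range(best_start, best_start + w))

    sel = cand_a if abs(cand_a) <= abs(cand_b) else cand_b
    source = "startseq_primary" if sel == cand_a else "startseq_density"

    def polii_sum(center_off):
        total = 0.0
        for o in range(center_off - 250, center_off + 251):
            pos = tx.tss + sgn * o
            total += float(polii.window(tx.chrom, UNSTRANDED, pos, pos + 1)[0])
        return total

    if polii_sum(sel) < (2 / 3) * polii_sum(0):
        sel = best_in(range(-250, 251))
        source = "polII_rescued"

    if counts[sel] < cfg.min_tss_reads:
        return tx.tss, "annotation_lowreads"
    return tx.tss + sgn * sel, source


@pytest.fixture(scope="module")
def random_gene_fixture():
    """50 genes with random sparse 5'-end signal and patchy Pol II."""
    rng = np.random.default_rng(2024)
    start5p_p = SignalTrack()
    start5p_m = SignalTrack()
    polii = SignalTrack()
    txs = []
    for i in range(50):
        strand = "+" if i % 2 == 0 else "-"
        tss = 5000 + i * 4000
        tx = make_tx(tss=tss, strand=strand, name=f"t{i:03d}")
        txs.append(tx)
        track = start5p_p if strand == "+" else start5p_m
        n_sites = int(rng.integers(5, 40))
        offs = rng.integers(-1100, 1101, size=n_sites)
        scale = 1.0 if rng.random() > 0.2 else 0.2  # some low-read genes
        for off in offs:
            val = float(rng.integers(1, 20)) * scale
            pos = tss + off if strand == "+" else tss - off
            track.add("chr1", strand, int(pos), max(round(val), 1))
        # blocky Pol II coverage; occasional deserts trigger the rescue
        for block in range(-13, 13):
            v = float(rng.choice([0.0, 0.2, 1.0, 3.0]))
            lo = tss + block * 100
            polii.set_range("chr1", UNSTRANDED, lo, lo + 100, v)
    merged = SignalTrack()
    for src in (start5p_p, start5p_m):
        for chrom, strand, pos, val in src.items():
            merged.add(chrom, strand, pos, val)
    return txs, merged, polii


def test_caller_matches_exhaustive_oracle(random_gene_fixture):
    """Position and source label agree with an independent brute force."""
    txs, start5p, polii = random_gene_fixture
    sources = set()
    for tx in txs:
        call = call_observed_tss(tx, start5p, polii, CFG)
        exp_pos, exp_src = oracle_observed(tx, start5p, polii, CFG)
        assert (call.observed_pos, call.source) == (exp_pos, exp_src), tx
        sources.add(call.source)
    # the fixture must actually exercise the interesting rules
    assert "polII_rescued" in sources
    assert "startseq_primary" in sources


def make_call(name, observed, distance, strand="+", low=False,
              source="startseq_primary"):
    return ObservedTssCall(name, name, "chr1", strand, observed - distance,
                           observed, source, 10.0, distance,
                           low_confidence=low)


class TestDeduplication:
    def test_identical_position_keeps_shortest_distance(self):
        calls = [make_call("a", 1000, 300), make_call("b", 1000, 30)]
        kept = deduplicate_calls(calls, CFG)
        assert [c.transcript_id for c in kept] == ["b"]

    def test_cluster_drops_low_confidence(self):
        calls = [make_call("riken", 1000, 10, low=True),
                 make_call("normal", 1150, 40)]
        kept = deduplicate_calls(calls, CFG)
        assert [c.transcript_id for c in kept] == ["normal"]

    def test_cluster_drops_lowread_fallbacks(self):
        calls = [make_call("fallback", 1000, 0, source="annotation_lowreads"),
                 make_call("real", 1100, 80)]
        kept = deduplicate_calls(calls, CFG)
        assert [c.transcript_id for c in kept] == ["real"]

    def test_all_dropped_cluster_keeps_best_anyway(self):
        calls = [make_call("r1", 1000, 50, low=True),
                 make_call("r2", 1100, 20, low=True)]
        kept = deduplicate_calls(calls, CFG)
        assert [c.transcript_id for c in kept] == ["r2"]

    def test_far_apart_calls_untouched_and_idempotent(self, rng):
        calls = [make_call(f"t{i}", int(p), int(rng.integers(-500, 500)))
                 for i, p in enumerate(
                     np.cumsum(rng.integers(300, 2000, size=30)) + 10_000)]
        once = deduplicate_calls(calls, CFG)
        twice = deduplicate_calls(once, CFG)
        assert [c.transcript_id for c in once] == [c.transcript_id
                                                   for c in twice]
        positions = sorted(c.observed_pos for c in once)
        gaps = np.diff(positions)
        assert (gaps > CFG.dedup_group_radius).all()


class TestBoundClassification:
    @pytest.mark.parametrize("peak,expected", [
        ((950, 990), True),     # offset -50..-10
        ((0, 50), False),       # far upstream, outside -900
        ((1100, 1200), True),   # touches exactly offset +100 (inclusive)
        ((1101, 1200), False),  # starts at offset +101
    ])
    def test_window_intersection_plus_strand(self, peak, expected):
        call = make_call("x", 1000, 0)
        peaks = [GenomicInterval("chr1", *peak, "+")]
        assert classify_nfy_bound(call, peaks, CFG) is expected

    def test_minus_strand_window_reflects(self):
        call = make_call("x", 10_000, 0, strand="-")
        # -900..+100 on minus strand spans genomic [9900, 10901)
        assert classify_nfy_bound(
            call, [GenomicInterval("chr1", 10_800, 10_950, "+")], CFG)
        assert not classify_nfy_bound(
            call, [GenomicInterval("chr1", 8_000, 9_000, "+")], CFG)
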