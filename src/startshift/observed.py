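"""Observed (canonical) TSS resolution from control capped-RNA 5'-end signal.

For each annotated transcript the caller searches +/- 1 kb of the annotated
TSS for the empirically used start site:

1. candidate A — the single base with the highest 5'-end count; candidate B —
   the highest base inside the 200-nt window of greatest summed density; the
   candidate closer to the annotation wins.
2. Pol II occupancy check: if the 501-nt Pol II window at the selected base
   holds less than 2/3 of the signal of the same window at the annotated TSS,
   the call is re-anchored to the best base within +/- 250 nt.
3. If fewer than 5 reads support the selected base, the annotation is kept.

Calls sharing a base, or clustered within 200 nt, are reduced to a single
representative; a promoter is classified NF-Y-bound when a ChIP peak
intersects the observed TSS -900..+100 window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import UNSTRANDED, GenomicInterval, GenomicPosition, PipelineConfig
from .tracks import SignalTrack, TranscriptAnnotation

SOURCES = ("startseq_primary", "startseq_density", "polII_rescued",
           "annotation_lowreads", "annotation_kept")


@dataclass(frozen=True)
class ObservedTssCall:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    annotated_pos: int
    observed_pos: int
    source: str
    reads: float          # 5'-end reads at the called base
    distance: int         # strand-relative offset annotated -> observed
    low_confidence: bool = False

    @property
    def position(self) -> GenomicPosition:
        return GenomicPosition(self.chrom, self.observed_pos, self.strand)


def _argbest(counts: np.ndarray, offsets: np.ndarray) -> int:
    """Position of the maximum count with deterministic tie-breaking.

    Ties at equal counts go to the offset closest to the annotation
    (smallest |offset|); remaining ties to the upstream-most (most negative)
    offset.  Returns an index into ``counts``/``offsets``.
    """
    best = None
    best_key = None
    m = counts.max()
    for i in np.nonzero(counts == m)[0]:
        off = int(offsets[i])
        key = (abs(off), off)
        if best_key is None or key < best_key:
            best, best_key = int(i), key
    assert best is not None
    return best


def call_observed_tss(tx: TranscriptAnnotation, start5p: SignalTrack,
                      polii: Optional[SignalTrack],
                      cfg: PipelineConfig) -> ObservedTssCall:
    """Resolve the observed TSS of one transcript from raw control 5' ends."""
    anchor = tx.tss_position
    radius = cfg.tss_search_radius

    if not start5p.has_chrom(tx.chrom):
        return ObservedTssCall(
            tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
            annotated_pos=tx.tss, observed_pos=tx.tss,
            source="annotation_kept", reads=0.0, distance=0,
            low_confidence=tx.low_confidence)

    offsets = np.arange(-radius, radius + 1)
    counts = start5p.oriented_window(anchor, -radius, radius)

    # candidate A: global argmax
    ia = _argbest(counts, offsets)

    # candidate B: argmax within the densest sliding window
    w = cfg.density_window
    win_sums = np.convolve(counts, np.ones(w), mode="valid")
    centers = offsets[: win_sums.size] + (w - 1) / 2.0
    best_w = None
    best_wkey = None
    mw = win_sums.max()
    for i in np.nonzero(win_sums == mw)[0]:
        key = (abs(centers[i]), centers[i])
        if best_wkey is None or key < best_wkey:
            best_w, best_wkey = int(i), key
    sl = slice(best_w, best_w + w)
    ib = best_w + _argbest(counts[sl], offsets[sl])

    if abs(int(offsets[ia])) <= abs(int(offsets[ib])):
        sel, source = ia, "startseq_primary"
    else:
        sel, source = ib, "startseq_density"

    # Pol II occupancy rescue
    if polii is not None and polii.has_chrom(tx.chrom):
        h = cfg.polii_window_halfwidth
        sel_pos = _offset_to_pos(anchor, int(offsets[sel]))
        sel_anchor = GenomicPosition(tx.chrom, sel_pos, tx.strand)
        sig_sel = polii.oriented_window(sel_anchor, -h, h,
                                        strand=UNSTRANDED).sum()
        sig_ann = polii.oriented_window(anchor, -h, h,
                                        strand=UNSTRANDED).sum()
        if sig_ann > 0 and sig_sel < cfg.polii_ratio_threshold * sig_ann:
            r = cfg.polii_rescue_radius
            mask = np.abs(offsets) <= r
            sub_off = offsets[mask]
            sub_cnt = counts[mask]
            j = _argbest(sub_cnt, sub_off)
            sel = int(np.nonzero(mask)[0][j])
            source = "polII_rescued"

    reads = float(counts[sel])
    if reads < cfg.min_tss_reads:
        return ObservedTssCall(
            tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
            annotated_pos=tx.tss, observed_pos=tx.tss,
            source="annotation_lowreads", reads=float(counts[radius]),
            distance=0, low_confidence=tx.low_confidence)

    off = int(offsets[sel])
    return ObservedTssCall(
        tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
        annotated_pos=tx.tss, observed_pos=_offset_to_pos(anchor, off),
        source=source, reads=reads, distance=off,
        low_confidence=tx.low_confidence)


def _offset_to_pos(anchor: GenomicPosition, offset: int) -> int:
    return anchor.pos + offset if anchor.strand == "+" else anchor.pos - offset


def call_all_observed(transcripts: Sequence[TranscriptAnnotation],
                      start5p: SignalTrack, polii: Optional[SignalTrack],
                      cfg: PipelineConfig) -> list[ObservedTssCall]:
    return [call_observed_tss(t, start5p, polii, cfg) for t in transcripts]


# ---------------------------------------------------------------------------
# Deduplication


def _keep_representative(group: list[ObservedTssCall]) -> ObservedTssCall:
    return min(group, key=lambda c: (abs(c.distance), c.transcript_id))


def deduplicate_calls(calls: Sequence[ObservedTssCall],
                      cfg: PipelineConfig) -> list[ObservedTssCall]:
    """Reduce redundant observed-TSS calls to single representatives.

    (a) calls at an identical observed base keep the one with the shortest
    annotated-to-observed distance; (b) same-strand calls within 200 nt
    (single linkage) are clustered, low-confidence annotations and calls kept
    at the annotation for lack of reads are dropped (unless that would empty
    the cluster), and the shortest-distance survivor represents the cluster.
    """
    # (a) identical observed positions
    by_pos: dict[tuple[str, str, int], list[ObservedTssCall]] = {}
    for c in calls:
        by_pos.setdefault((c.chrom, c.strand, c.observed_pos), []).append(c)
    stage_a = [_keep_representative(g) for g in by_pos.values()]

    # (b) single-linkage clusters within the grouping radius
    out: list[ObservedTssCall] = []
    radius = cfg.dedup_group_radius
    key = lambda c: (c.chrom, c.strand, c.observed_pos, c.transcript_id)
    stage_a.sort(key=key)
    cluster: list[ObservedTssCall] = []
    for c in stage_a:
        if (cluster
                and c.chrom == cluster[-1].chrom
                and c.strand == cluster[-1].strand
                and c.observed_pos - cluster[-1].observed_pos <= radius):
            cluster.append(c)
        else:
            if cluster:
                out.append(_reduce_cluster(cluster))
            cluster = [c]
    if cluster:
        out.append(_reduce_cluster(cluster))
    out.sort(key=key)
    return out


def _reduce_cluster(cluster: list[ObservedTssCall]) -> ObservedTssCall:
    confident = [c for c in cluster
                 if not c.low_confidence and c.source != "annotation_lowreads"]
    return _keep_representative(confident or cluster)


# ---------------------------------------------------------------------------
# NF-Y bound classification


def classify_nfy_bound(call: ObservedTssCall,
                       peaks: Sequence[GenomicInterval],
                       cfg: PipelineConfig) -> bool:
    """True when a ChIP peak intersects the observed TSS -900..+100 window."""
    lo, hi = cfg.bound_window
    if call.strand == "+":
        w_start, w_end = call.observed_pos + lo, call.observed_pos + hi + 1
    else:
        w_start, w_end = call.observed_pos - hi, call.observed_pos - lo + 1
    for p in peaks:
        if p.chrom == call.chrom and p.start < w_end and w_start < p.end:
            return True
    return False


def calls_to_frame(calls: Sequence[ObservedTssCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "transcript_id": c.transcript_id, "gene_id": c.gene_id,
        "chrom": c.chrom, "strand": c.strand,
        "annotated_pos": c.annotated_pos, "observed_pos": c.observed_pos,
        "source": c.source, "reads": c.reads, "distance": c.distance,
        "low_confidence": c.low_confidence,
    } for c in calls])
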