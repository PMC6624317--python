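"""MNase-Seq nucleosome occupancy profiling and TSS-encroachment calls.

Mononucleosome-protected fragments (120-180 nt after filtering) are reduced
to single-base dyad proxies at their midpoints; depth-normalized center
counts summed over the TSS core window (-25..+24) quantify occupancy.  A
promoter is *encroached* when the knockdown/control occupancy ratio, with a
one-normalized-unit pseudocount, reaches the 1.5-fold threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import UNSTRANDED, GenomicPosition, PipelineConfig
from .observed import ObservedTssCall
from .tracks import FragmentSet, SignalTrack


def filter_fragments(frags: FragmentSet, cfg: PipelineConfig) -> FragmentSet:
    """Keep fragments of nucleosomal length and drop duplicates.

    Lengths outside [mnase_len_min, mnase_len_max] (inclusive) are removed;
    duplicates share (chrom, start, end).
    """
    return frags.filter_lengths(cfg.mnase_len_min, cfg.mnase_len_max).deduplicate()


def occupancy_profile(centers: SignalTrack,
                      anchors: Sequence[GenomicPosition],
                      window: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Strand-oriented metagene of center counts around the anchors.

    Returns ``(profile, matrix)``: the per-offset mean over anchors and the
    per-anchor matrix (rows in input order, columns = offsets lo..hi
    inclusive).
    """
    lo, hi = window
    rows = [centers.oriented_window(a, lo, hi, strand=UNSTRANDED)
            for a in anchors]
    matrix = np.array(rows) if rows else np.zeros((0, hi - lo + 1))
    profile = matrix.mean(axis=0) if len(rows) else np.zeros(hi - lo + 1)
    return profile, matrix


@dataclass(frozen=True)
class OccupancyChange:
    gene_id: str
    control_occupancy: float   # normalized center counts in the TSS window
    kd_occupancy: float
    fold_change: float
    log2fc: float
    encroached: bool


def tss_occupancy_change(control: SignalTrack, kd: SignalTrack,
                         call: ObservedTssCall,
                         cfg: PipelineConfig) -> OccupancyChange:
    """Occupancy fold change over the TSS core window for one gene.

    ``control``/``kd`` are depth-normalized fragment-center tracks; the fold
    change is (KD + c) / (control + c) with pseudocount c, and the promoter
    is flagged encroached at >= the configured threshold.
    """
    lo, hi = cfg.mnase_tss_window
    anchor = call.position
    occ_c = float(control.oriented_window(anchor, lo, hi,
                                          strand=UNSTRANDED).sum())
    occ_k = float(kd.oriented_window(anchor, lo, hi,
                                     strand=UNSTRANDED).sum())
    c = cfg.mnase_pseudocount
    fc = (occ_k + c) / (occ_c + c)
    return OccupancyChange(
        gene_id=call.gene_id, control_occupancy=occ_c, kd_occupancy=occ_k,
        fold_change=fc, log2fc=float(np.log2(fc)),
        encroached=fc >= cfg.mnase_fc_threshold)


def changes_to_frame(changes: Sequence[OccupancyChange]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "control_occupancy": c.control_occupancy,
        "kd_occupancy": c.kd_occupancy, "fold_change": c.fold_change,
        "log2fc": c.log2fc, "encroached": c.encroached,
    } for c in changes])
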