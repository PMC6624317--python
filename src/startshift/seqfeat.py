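"""Promoter sequence features: CCAAT boxes, initiator dinucleotides,
conservation profiles.

The CCAAT box is the NF-Y recognition motif; it is counted on both strands
(ATTGG is the reverse-strand occurrence) with overlaps allowed.  The
initiator context of a TSS is the dinucleotide at offsets (-1, 0) on the
sense strand; a pyrimidine-purine (YR) initiator is the canonical metazoan
signal.  Conservation profiles aggregate an externally supplied per-base
score track; bases without a score are excluded from means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import UNSTRANDED, GenomicPosition
from .ribo import get_sequence
from .tracks import SignalTrack

_CCAAT = re.compile("(?=CCAAT)")
_ATTGG = re.compile("(?=ATTGG)")


def count_ccaat(sequence: str) -> int:
    """CCAAT occurrences on either strand of ``sequence``, overlaps counted."""
    seq = sequence.upper()
    return len(_CCAAT.findall(seq)) + len(_ATTGG.findall(seq))


def initiator_at(genome, tss: GenomicPosition) -> tuple[str, bool]:
    """Sense-strand dinucleotide spanning offsets (-1, 0) of a TSS, + YR flag.

    YR means pyrimidine (C/T) at -1 followed by purine (A/G) at the TSS base.
    """
    if tss.strand == "+":
        dinuc = get_sequence(genome, tss.chrom, tss.pos - 1, tss.pos + 1, "+")
    else:
        dinuc = get_sequence(genome, tss.chrom, tss.pos, tss.pos + 2, "-")
    yr = len(dinuc) == 2 and dinuc[0] in "CT" and dinuc[1] in "AG"
    return dinuc, yr


def conservation_profile(scores: SignalTrack,
                         anchors: Sequence[GenomicPosition],
                         window: tuple[int, int]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-offset conservation over anchors and per-anchor window means.

    ``scores`` should carry NaN at unscored bases (load with ``fill=nan``);
    missing bases are dropped from every mean.  Returns ``(profile,
    per_anchor_means)``.
    """
    lo, hi = window
    rows = [scores.oriented_window(a, lo, hi, strand=UNSTRANDED)
            for a in anchors]
    if not rows:
        return np.full(hi - lo + 1, np.nan), np.zeros(0)
    matrix = np.array(rows)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        profile = np.nanmean(matrix, axis=0)
        per_anchor = np.nanmean(matrix, axis=1)
    return profile, per_anchor


@dataclass(frozen=True)
class PromoterFeatureRow:
    gene_id: str
    ccaat_count: int                      # in -1000..-1 of the canonical TSS
    canonical_initiator: str
    canonical_yr: bool
    ectopic_initiator: Optional[str] = None
    ectopic_yr: Optional[bool] = None
    mean_conservation: Optional[float] = None


def promoter_features(genome, gene_id: str, tss: GenomicPosition,
                      ectopic: Optional[GenomicPosition] = None,
                      conservation: Optional[SignalTrack] = None,
                      upstream: int = 1000,
                      conservation_window: tuple[int, int] = (-1000, -1)
                      ) -> PromoterFeatureRow:
    """Sequence features of one promoter (CCAAT count, initiators, scores)."""
    if tss.strand == "+":
        up_seq = get_sequence(genome, tss.chrom, max(tss.pos - upstream, 0),
                              tss.pos, "+")
    else:
        up_seq = get_sequence(genome, tss.chrom, tss.pos + 1,
                              tss.pos + 1 + upstream, "-")
    dinuc, yr = initiator_at(genome, tss)
    e_dinuc = e_yr = None
    if ectopic is not None:
        e_dinuc, e_yr = initiator_at(genome, ectopic)
    cons = None
    if conservation is not None:
        _, per = conservation_profile(conservation, [tss],
                                      conservation_window)
        cons = float(per[0])
    return PromoterFeatureRow(
        gene_id=gene_id, ccaat_count=count_ccaat(up_seq),
        canonical_initiator=dinuc, canonical_yr=yr,
        ectopic_initiator=e_dinuc, ectopic_yr=e_yr,
        mean_conservation=cons)


def features_to_frame(rows: Sequence[PromoterFeatureRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "ccaat_count": r.ccaat_count,
        "canonical_initiator": r.canonical_initiator,
        "canonical_yr": r.canonical_yr,
        "ectopic_initiator": r.ectopic_initiator,
        "ectopic_yr": r.ectopic_yr,
        "mean_conservation": r.mean_conservation,
    } for r in rows])
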