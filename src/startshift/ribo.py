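"""Ribosome-profiling analysis: P-sites, triplet periodicity, uORF starts.

A footprint's P-site is placed a fixed 12 nt downstream of its 5' end (in the
direction of transcription).  Translated regions show 3-nt periodicity of
P-sites in the reading frame of their start codon; RNA-Seq-like coverage does
not.  For genes whose transcription start has shifted upstream, candidate
start codons (ATG) in the newly transcribed region are scored by downstream
P-site coverage, and expression of the shifted region is quantified as RPKM.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomicInterval, GenomicPosition, PipelineConfig
from .tracks import FragmentSet, SignalTrack

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def get_sequence(genome: Union[Mapping[str, str], "object"], chrom: str,
                 start: int, end: int, strand: str = "+") -> str:
    """Sense-strand sequence of [start, end); works on dicts and FASTA handles."""
    record = genome[chrom]
    seq = str(record[start:end]).upper()
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# P-sites and phasing


def psite_track(frags: FragmentSet, cfg: PipelineConfig,
                label: str = "psites") -> SignalTrack:
    """One count at each footprint's P-site: 5' end + 12 nt, strandwise."""
    track = SignalTrack(label=label)
    df = frags.frame
    if len(df) == 0:
        return track
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    strands = df["strand"].to_numpy()
    chroms = df["chrom"].to_numpy()
    plus = strands == "+"
    psites = np.where(plus, starts + cfg.psite_offset,
                      (ends - 1) - cfg.psite_offset)
    for chrom in sorted(set(chroms)):
        for strand in ("+", "-"):
            mask = (chroms == chrom) & (strands == strand)
            if mask.any():
                track.add_at(str(chrom), strand, psites[mask])
    return track


@dataclass(frozen=True)
class PhasingResult:
    anchor: GenomicPosition   # the A of the start codon
    frame_counts: tuple[float, float, float]
    frame0_fraction: float
    chi_square: float
    p: float

    @property
    def total(self) -> float:
        return float(sum(self.frame_counts))


def phasing(psites: SignalTrack, anchor: GenomicPosition,
            cfg: PipelineConfig) -> PhasingResult:
    """Triplet-periodicity test of P-site counts downstream of a start codon.

    Counts P-sites over ``phasing_span_codons`` codons beginning at the
    anchor (the A of the ATG), splits them by reading frame (offset mod 3 in
    transcript orientation), and runs a chi-square goodness-of-fit test
    against the uniform (1/3, 1/3, 1/3) expectation.
    """
    span = 3 * cfg.phasing_span_codons
    vals = psites.oriented_window(anchor, 0, span - 1)
    frames = np.arange(span) % 3
    counts = tuple(float(vals[frames == f].sum()) for f in range(3))
    total = sum(counts)
    if total == 0:
        return PhasingResult(anchor, counts, 0.0, 0.0, 1.0)
    chi2, p = stats.chisquare(counts)
    return PhasingResult(anchor, counts, counts[0] / total,
                         float(chi2), float(p))


# ---------------------------------------------------------------------------
# Start-codon scanning in shifted regions


def shifted_region(ectopic_pos: int, observed_pos: int, chrom: str,
                   strand: str, margin: int) -> GenomicInterval:
    """Region from the ectopic TSS to ``margin`` nt upstream of the canonical
    TSS, in transcript orientation (genomic half-open interval)."""
    if strand == "+":
        start, end = ectopic_pos, observed_pos - margin + 1
    else:
        start, end = observed_pos + margin, ectopic_pos + 1
    if start >= end:
        raise ValueError("shifted region is empty")
    return GenomicInterval(chrom, start, end, strand)


def _atg_anchors(genome, region: GenomicInterval) -> list[GenomicPosition]:
    """Genomic positions of the A of every sense-strand ATG in the region."""
    seq = get_sequence(genome, region.chrom, region.start, region.end,
                       region.strand)
    anchors = []
    for m in re.finditer("(?=ATG)", seq):
        i = m.start()
        pos = (region.start + i if region.strand == "+"
               else region.end - 1 - i)
        anchors.append(GenomicPosition(region.chrom, pos, region.strand))
    return anchors


def has_upstream_atg(seq: str) -> bool:
    """Whether the sense-strand sequence contains a start codon."""
    return "ATG" in seq.upper()


def select_ectopic_atg(genome, region: GenomicInterval,
                       psites: SignalTrack,
                       cfg: PipelineConfig) -> Optional[GenomicPosition]:
    """Choose the start codon most plausibly used in the shifted region.

    Every sense-strand ATG is scored by summed P-site coverage over the
    ``atg_window`` nt downstream of its A; the highest-coverage ATG wins,
    ties going to the ATG nearest the ectopic (5') end of the region.
    """
    anchors = _atg_anchors(genome, region)
    if not anchors:
        return None
    best, best_score = None, -1.0
    for a in anchors:  # anchors are ordered 5' -> 3'; first win on ties
        score = float(psites.oriented_window(a, 0, cfg.atg_window - 1).sum())
        if score > best_score:
            best, best_score = a, score
    return best


# ---------------------------------------------------------------------------
# Region expression


@dataclass(frozen=True)
class RiboRegionResult:
    gene_id: str
    region: GenomicInterval
    control_rpkm: float
    kd_rpkm: float
    control_count: float
    kd_count: float
    excluded: bool = False    # dominant-gene (>5% of library) exclusion


def region_fragment_count(frags: FragmentSet, region: GenomicInterval) -> int:
    df = frags.frame
    hit = ((df["chrom"] == region.chrom)
           & (df["start"] < region.end) & (df["end"] > region.start))
    return int(hit.sum())


def region_rpkm(count: float, region_length: int, total_mapped: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0 or total_mapped <= 0:
        raise ValueError("region length and library size must be positive")
    return count / ((region_length / 1e3) * (total_mapped / 1e6))


def shifted_region_rpkm(gene_id: str, region: GenomicInterval,
                        control_frags: FragmentSet, kd_frags: FragmentSet,
                        control_total: float, kd_total: float) -> RiboRegionResult:
    """Control and knockdown footprint RPKM over a gene's shifted region.

    For genes without an ectopic call (the comparison population), pass the
    fixed surrogate region -115..-25 upstream of the TSS via
    :func:`surrogate_region`.
    """
    n_c = region_fragment_count(control_frags, region)
    n_k = region_fragment_count(kd_frags, region)
    return RiboRegionResult(
        gene_id=gene_id, region=region,
        control_rpkm=region_rpkm(n_c, region.length, control_total),
        kd_rpkm=region_rpkm(n_k, region.length, kd_total),
        control_count=float(n_c), kd_count=float(n_k))


def surrogate_region(observed_pos: int, chrom: str, strand: str,
                     cfg: PipelineConfig) -> GenomicInterval:
    """Fixed upstream region (-115..-25 by default) for unbound genes."""
    return shifted_region(
        observed_pos + (-cfg.control_region_upstream if strand == "+"
                        else cfg.control_region_upstream),
        observed_pos, chrom, strand, cfg.ribo_region_margin)


def filter_dominant_genes(region_counts: Mapping[str, float],
                          library_total: float,
                          cfg: PipelineConfig) -> list[str]:
    """Genes kept for phasing: shifted-region signal <= 5% of the library.

    Genes whose region holds strictly more than the configured fraction of
    all footprints are removed.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    cut = cfg.ribo_gene_read_fraction_max
    return [g for g, n in region_counts.items()
            if n / library_total <= cut]


def cumulative_coverage(psites: SignalTrack,
                        anchors: Sequence[GenomicPosition],
                        window: tuple[int, int]) -> np.ndarray:
    """Per-offset P-site coverage summed over anchors (A of each start codon).

    Offsets are transcript-oriented; index i of the result is offset
    ``window[0] + i``.
    """
    lo, hi = window
    out = np.zeros(hi - lo + 1)
    for a in anchors:
        out += psites.oriented_window(a, lo, hi)
    return out


def region_results_to_frame(results: Sequence[RiboRegionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "chrom": r.region.chrom,
        "start": r.region.start, "end": r.region.end,
        "strand": r.region.strand,
        "control_rpkm": r.control_rpkm, "kd_rpkm": r.kd_rpkm,
        "control_count": r.control_count, "kd_count": r.kd_count,
        "excluded": r.excluded,
    } for r in results])
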