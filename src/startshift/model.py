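"""Shared coordinate conventions and the pipeline configuration.

All genomic coordinates in this package are 0-based, half-open
(``start <= pos < end``), matching BED/bedGraph semantics.  Windows that the
analysis defines in strand-relative nucleotide offsets (e.g. the promoter
window -900..+100) are *inclusive* offset ranges: offset 0 is the anchor base
itself, positive offsets run downstream in the direction of transcription.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

STRANDS = ("+", "-")
#: strand slot used by unstranded tracks (conservation, ATAC insertions, ...)
UNSTRANDED = "."


@dataclass(frozen=True)
class GenomicPosition:
    chrom: str
    pos: int
    strand: str = "+"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def to_offset(pos: GenomicPosition, anchor: GenomicPosition) -> int:
    """Signed strand-relative offset of ``pos`` from ``anchor``.

    Positive offsets are downstream of the anchor in the anchor's strand
    direction; offset 0 is the anchor base itself.
    """
    if pos.chrom != anchor.chrom:
        raise ValueError(
            f"cannot compute offset across chromosomes "
            f"({pos.chrom!r} vs {anchor.chrom!r})"
        )
    delta = pos.pos - anchor.pos
    return delta if anchor.strand == "+" else -delta


def to_position(offset: int, anchor: GenomicPosition) -> GenomicPosition:
    """Inverse of :func:`to_offset` for a given anchor."""
    delta = offset if anchor.strand == "+" else -offset
    return GenomicPosition(anchor.chrom, anchor.pos + delta, anchor.strand)


@dataclass
class PipelineConfig:
    """Every fixed constant of the analysis, with its unit and default.

    Offsets are strand-relative nucleotides; ``(lo, hi)`` pairs are inclusive
    offset ranges.
    """

    #: search radius around the annotated TSS for the observed-TSS caller (nt)
    tss_search_radius: int = 1000
    #: width of the sliding read-density window in the observed-TSS caller (nt)
    density_window: int = 200
    #: Pol II window-signal ratio below which the call is re-anchored
    polii_ratio_threshold: float = 2.0 / 3.0
    #: re-selection radius used by the Pol II rescue rule (nt)
    polii_rescue_radius: int = 250
    #: half-width of the Pol II signal window (window length = 2*h + 1 = 501)
    polii_window_halfwidth: int = 250
    #: minimum 5'-end reads at a called TSS; below this the annotation is kept
    min_tss_reads: int = 5
    #: single-linkage radius for collapsing nearby observed-TSS calls (nt)
    dedup_group_radius: int = 200
    #: promoter window (inclusive offsets) for NF-Y-bound classification
    bound_window: tuple[int, int] = (-900, 100)
    #: region tiled by differential bins, inclusive offsets from observed TSS
    bin_region: tuple[int, int] = (-995, 995)
    #: width of each differential bin (nt)
    bin_width: int = 10
    #: core region around the observed TSS excluded from ectopic calling
    core_exclusion: tuple[int, int] = (-25, 24)
    #: BH-adjusted p-value threshold for significant bins
    padj_threshold: float = 0.1
    #: minimum |shift| of any ectopic call (guaranteed by core_exclusion)
    shift_min_distance: int = 25
    #: retained MNase fragment lengths, inclusive (nt)
    mnase_len_min: int = 120
    mnase_len_max: int = 180
    #: fold-change threshold for calling TSS nucleosome encroachment
    mnase_fc_threshold: float = 1.5
    #: occupancy fold-change window around the observed TSS (inclusive offsets)
    mnase_tss_window: tuple[int, int] = (-25, 24)
    #: pseudocount (normalized units) in the occupancy fold change
    mnase_pseudocount: float = 1.0
    #: fixed P-site offset from the footprint 5' end (nt)
    psite_offset: int = 12
    #: downstream span used to score candidate start codons (nt)
    atg_window: int = 60
    #: codons scored when testing triplet periodicity at a start codon
    phasing_span_codons: int = 60
    #: genes whose shifted region holds more than this fraction of the library
    #: are dropped from phasing analysis
    ribo_gene_read_fraction_max: float = 0.05
    #: surrogate upstream bound for genes without a promoter-proximal peak (nt)
    control_region_upstream: int = 115
    #: margin upstream of the canonical TSS closing the quantified region (nt)
    ribo_region_margin: int = 25
    #: sliding window for the maximum Start-Seq difference statistic (nt)
    sliding_window: int = 10
    #: offset range scanned by the sliding-difference statistic (inclusive)
    sliding_region: tuple[int, int] = (-900, -25)
    #: denominator of depth normalization (reads)
    norm_denominator: float = 10_000_000.0
    #: pseudocount (normalized units) for reported log2 fold changes
    log2fc_pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mnase_len_min > self.mnase_len_max:
            raise ValueError("mnase_len_min must be <= mnase_len_max")
        lo, hi = self.bin_region
        clo, chi = self.core_exclusion
        if not (lo <= clo and chi <= hi):
            raise ValueError("bin_region must contain core_exclusion")
        for name in ("tss_search_radius", "density_window", "bin_width",
                     "psite_offset", "atg_window", "sliding_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.norm_denominator <= 0:
            raise ValueError("norm_denominator must be positive")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Load overrides from a YAML or TOML key-value file."""
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # lists from YAML/TOML become the tuple fields expect
        for key, value in list(raw.items()):
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)

    def describe(self) -> str:
        """Resolved configuration, one ``key = value`` line per field."""
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines)


DEFAULT_CONFIG = PipelineConfig()
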