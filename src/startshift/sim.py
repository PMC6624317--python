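"""Synthetic multi-omics data with known ground truth.

The generator emits a small synthetic genome (by default 200 genes in 6-kb
loci on two chromosomes) together with every assay the pipeline consumes:

* replicate capped-RNA 5'-end count tracks in two conditions, with ectopic
  initiation sites planted upstream of the canonical TSS (knockdown only);
* a spike-in count table whose per-sample scale factors are known;
* nucleosome-protected fragment sets with a planted TSS-overlapping
  nucleosome gain (knockdown only);
* ribosome footprints with 3-nt periodic P-sites from canonical ORFs and
  planted upstream ORFs;
* a uniform Pol II occupancy track and promoter-proximal ChIP peak intervals.

Every random draw comes from one seeded generator, so a fixed seed yields
byte-identical output files.  ``SimTruth`` (the ``truth`` frame) records the
planted ectopic offsets, nucleosome gains, uORF positions and per-sample
scale factors, enabling parameter-recovery tests of every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import UNSTRANDED, GenomicInterval, GenomicPosition, PipelineConfig
from .tracks import (FragmentSet, SignalTrack, TranscriptAnnotation,
                     write_annotation_bed12, write_bed6, write_bedgraph)

PathLike = Union[str, Path]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment."""

    n_genes: int = 200
    #: fraction of genes given a planted upstream ectopic TSS (knockdown only)
    fraction_shifted: float = 0.3
    #: planted shift offsets drawn uniformly from this inclusive range (nt,
    #: negative = upstream); the default range has median 170 upstream and
    #: is the regime the recovery experiments probe
    shift_offset_range: tuple[int, int] = (-300, -40)
    #: replicates per condition
    replicates: int = 3
    #: per-sample true scale factors, controls first then knockdowns
    true_scale_factors: tuple[float, ...] = (1.0, 1.15, 0.9, 1.05, 0.8, 1.2)
    #: number of synthetic capped spike-in RNAs
    n_spikes: int = 15
    #: mean reads per spike at scale factor 1
    spike_mean_reads: float = 300.0
    #: capped-RNA 5'-end background (reads per nt per sample)
    background_rate: float = 0.5
    #: mean 5'-end count at the canonical TSS per sample
    canonical_mean: float = 100.0
    #: mean 5'-end count at the planted ectopic base (knockdown samples only);
    #: the default is 10x the 10-nt-bin background mean
    ectopic_mean: float = 50.0
    #: negative-binomial dispersion of all 5'-end counts
    nb_dispersion: float = 0.05
    #: nominal sequencing depth reported per sample (reads)
    nominal_depth: float = 10_000_000.0
    #: genome geometry
    n_chroms: int = 2
    locus_size: int = 6000
    #: promoter half-width over which background signal is laid down (nt)
    promoter_halfwidth: int = 1000
    #: fraction of non-shifted genes that still carry a promoter ChIP peak
    bound_extra_fraction: float = 0.2
    #: ChIP peak placement, inclusive offsets from the canonical TSS
    peak_offsets: tuple[int, int] = (-150, -50)
    #: MNase: fragments per flanking nucleosome per condition
    mnase_nuc_frags: int = 50
    #: dyad offsets of the -1 and +1 nucleosomes (nt from TSS)
    nuc_minus1_offset: int = -200
    nuc_plus1_offset: int = 120
    #: s.d. of fragment centers around a dyad (nt)
    dyad_sd: float = 20.0
    #: emitted MNase fragment lengths, drawn uniformly from this range (nt)
    mnase_len_range: tuple[int, int] = (120, 180)
    #: uniform MNase background (fragments per nt per condition, +/-500 nt)
    mnase_bg_rate: float = 0.6
    #: fragments of the planted TSS-overlapping nucleosome (knockdown only);
    #: roughly 2x the background fragment density over the TSS window
    tss_nuc_frags: int = 60
    #: Ribo-Seq: CDS starts this far downstream of the canonical TSS (nt)
    cds_offset: int = 200
    #: P-sites emitted over the canonical ORF per condition
    canonical_psites: int = 300
    canonical_orf_codons: int = 100
    #: probability a shifted gene carries a translated uORF (knockdown only)
    uorf_probability: float = 0.7
    #: P-sites emitted over a planted uORF (knockdown condition)
    uorf_psites: int = 150
    #: length of the planted uORF's translated span (nt)
    uorf_span: int = 60
    #: fraction of uORF P-sites landing in frame 0
    frame0_purity: float = 0.85
    #: canonical ORF frame-0 purity
    canonical_frame0_purity: float = 0.9
    #: scattered background P-sites (per nt per condition)
    ribo_bg_rate: float = 0.005
    #: footprint length written to fragment BEDs (nt)
    footprint_length: int = 30

    def __post_init__(self) -> None:
        lo, hi = self.shift_offset_range
        if lo > hi:
            raise ValueError("shift_offset_range reversed")
        if hi > -26:
            raise ValueError(
                "shift offsets must stay outside the TSS core (-25..+24)")
        if len(self.true_scale_factors) != 2 * self.replicates:
            raise ValueError(
                "true_scale_factors must list controls then knockdowns "
                f"({2 * self.replicates} values)")
        if not 0 <= self.fraction_shifted <= 1:
            raise ValueError("fraction_shifted must be in [0, 1]")

    @property
    def sample_names(self) -> list[str]:
        r = self.replicates
        return ([f"ctrl_{i + 1}" for i in range(r)]
                + [f"kd_{i + 1}" for i in range(r)])

    @property
    def conditions(self) -> dict[str, str]:
        return {s: ("control" if s.startswith("ctrl") else "kd")
                for s in self.sample_names}


@dataclass
class SimDataset:
    """In-memory result of :func:`simulate`, with text-format export."""

    cfg: SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptAnnotation]
    startseq: dict[str, SignalTrack]          # sample -> raw 5'-end counts
    totals: pd.Series                         # sample -> nominal depth
    spike_counts: pd.DataFrame                # spikes x samples
    polii: SignalTrack
    peaks: list[GenomicInterval]
    mnase: dict[str, FragmentSet]             # condition -> merged fragments
    ribo: dict[str, FragmentSet]              # condition -> merged fragments
    truth: pd.DataFrame
    scale_factors: pd.Series

    @property
    def conditions(self) -> dict[str, str]:
        return self.cfg.conditions

    @property
    def control_samples(self) -> list[str]:
        return [s for s, c in self.conditions.items() if c == "control"]

    @property
    def kd_samples(self) -> list[str]:
        return [s for s, c in self.conditions.items() if c == "kd"]

    def write(self, outdir: PathLike) -> None:
        """Emit every component in its standard text format."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        write_annotation_bed12(self.transcripts, out / "annotation.bed")
        for sample, track in self.startseq.items():
            for strand, tag in (("+", "plus"), ("-", "minus")):
                write_bedgraph(track, out / f"startseq_{sample}_{tag}.bedgraph",
                               strand=strand)
        self.spike_counts.to_csv(out / "spikes.tsv", sep="\t")
        self.totals.rename("total_mapped").to_frame().to_csv(
            out / "totals.tsv", sep="\t")
        write_bedgraph(self.polii, out / "polii.bedgraph", strand=UNSTRANDED)
        with open(out / "nfya_peaks.bed", "w") as fh:
            for p in self.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t0\t+\n")
        for cond, frags in self.mnase.items():
            write_bed6(frags, out / f"mnase_{cond}.bed")
        for cond, frags in self.ribo.items():
            write_bed6(frags, out / f"ribo_{cond}.bed")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.scale_factors.rename("true_scale_factor").to_frame().to_csv(
            out / "scale_factors.tsv", sep="\t")


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draws with mean/dispersion parametrization."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _plant(seq: np.ndarray, pos: int, motif: str, strand: str) -> None:
    """Write a sense-strand motif into the + strand genome array."""
    if strand == "+":
        for i, b in enumerate(motif):
            seq[pos + i] = b
    else:
        for i, b in enumerate(motif):
            seq[pos - i] = _COMP[b]


def simulate(cfg: Optional[SimConfig] = None, seed: int = 0) -> SimDataset:
    """Generate the full synthetic dataset; the seed fixes every byte."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)

    samples = cfg.sample_names
    factors = pd.Series(dict(zip(samples, cfg.true_scale_factors)),
                        name="true_scale_factor")

    # -- genome & gene placement ------------------------------------------
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    chrom_len = per_chrom * cfg.locus_size
    chrom_names = [f"chrS{i + 1}" for i in range(cfg.n_chroms)]
    genome_arr = {c: rng.choice(np.array(list("ACGT")), size=chrom_len)
                  for c in chrom_names}

    genes = []
    for g in range(cfg.n_genes):
        chrom = chrom_names[g % cfg.n_chroms]
        slot = g // cfg.n_chroms
        strand = "+" if g % 2 == 0 else "-"
        tss = slot * cfg.locus_size + cfg.locus_size // 2
        genes.append((f"gene{g:04d}", chrom, strand, tss))

    # -- planted truth -----------------------------------------------------
    n_shift = int(round(cfg.fraction_shifted * cfg.n_genes))
    shifted_idx = np.sort(rng.choice(cfg.n_genes, size=n_shift, replace=False))
    lo, hi = cfg.shift_offset_range
    shift_offsets = rng.integers(lo, hi + 1, size=n_shift)

    is_shifted = np.zeros(cfg.n_genes, dtype=bool)
    is_shifted[shifted_idx] = True
    ect_offset = np.full(cfg.n_genes, 0, dtype=int)
    ect_offset[shifted_idx] = shift_offsets

    unshifted = np.nonzero(~is_shifted)[0]
    n_extra = int(round(cfg.bound_extra_fraction * unshifted.size))
    extra_bound = rng.choice(unshifted, size=n_extra, replace=False)
    is_bound = is_shifted.copy()
    is_bound[extra_bound] = True

    has_uorf = np.zeros(cfg.n_genes, dtype=bool)
    for i in shifted_idx:
        if rng.random() < cfg.uorf_probability:
            has_uorf[i] = True

    # -- sequence planting -------------------------------------------------
    def offset_pos(tss: int, strand: str, off: int) -> int:
        return tss + off if strand == "+" else tss - off

    uorf_off = np.full(cfg.n_genes, 0, dtype=int)
    for i, (gid, chrom, strand, tss) in enumerate(genes):
        seq = genome_arr[chrom]
        _plant(seq, offset_pos(tss, strand, -80), "CCAAT", strand)
        _plant(seq, offset_pos(tss, strand, -1), "CA", strand)
        if is_shifted[i]:
            _plant(seq, offset_pos(tss, strand, int(ect_offset[i]) - 1),
                   "CA", strand)
        if has_uorf[i]:
            off = int(ect_offset[i]) + 5
            uorf_off[i] = off
            _plant(seq, offset_pos(tss, strand, off), "ATG", strand)
        # canonical ORF start codon
        _plant(seq, offset_pos(tss, strand, cfg.cds_offset), "ATG", strand)

    genome = {c: "".join(a) for c, a in genome_arr.items()}

    transcripts = []
    for i, (gid, chrom, strand, tss) in enumerate(genes):
        if strand == "+":
            start, end = tss, tss + 2500
            cds = tss + cfg.cds_offset
        else:
            start, end = tss - 2499, tss + 1
            cds = tss - cfg.cds_offset
        transcripts.append(TranscriptAnnotation(
            transcript_id=gid + ".t1", gene_id=gid, chrom=chrom,
            start=start, end=end, strand=strand, cds_start=cds))

    # -- Start-Seq 5'-end tracks ------------------------------------------
    hw = cfg.promoter_halfwidth
    startseq = {s: SignalTrack(label=f"startseq_{s}") for s in samples}
    for s in samples:
        t = factors[s]
        kd = cfg.conditions[s] == "kd"
        track = startseq[s]
        for i, (gid, chrom, strand, tss) in enumerate(genes):
            counts = _nb_draw(rng, np.full(2 * hw + 1,
                                           cfg.background_rate * t),
                              cfg.nb_dispersion).astype(float)
            counts[hw] += _nb_draw(rng, cfg.canonical_mean * t,
                                   cfg.nb_dispersion)
            if kd and is_shifted[i]:
                counts[hw + int(ect_offset[i])] += _nb_draw(
                    rng, cfg.ectopic_mean * t, cfg.nb_dispersion)
            offs = np.nonzero(counts)[0] - hw
            if strand == "+":
                positions = tss + offs
            else:
                positions = tss - offs
            track.add_at(chrom, strand, positions,
                         counts[np.nonzero(counts)[0]])

    totals = pd.Series({s: cfg.nominal_depth for s in samples},
                       name="total_mapped")

    # -- spike-ins ---------------------------------------------------------
    ratio = 1.3
    k = np.arange(cfg.n_spikes) - (cfg.n_spikes - 1) / 2.0
    abundance = cfg.spike_mean_reads * ratio ** k
    abundance *= cfg.spike_mean_reads / abundance.mean()
    spike_counts = pd.DataFrame(
        {s: rng.poisson(abundance * factors[s]) for s in samples},
        index=[f"spike{i + 1:02d}" for i in range(cfg.n_spikes)])

    # -- Pol II and ChIP peaks ---------------------------------------------
    polii = SignalTrack(label="polii")
    peaks = []
    plo, phi = cfg.peak_offsets
    for i, (gid, chrom, strand, tss) in enumerate(genes):
        polii.add_range(chrom, UNSTRANDED, tss - hw, tss + hw + 1, 1.0)
        if is_bound[i]:
            if strand == "+":
                start, end = tss + plo, tss + phi + 1
            else:
                start, end = tss - phi, tss - plo + 1
            peaks.append(GenomicInterval(chrom, start, end, "+"))

    # -- MNase fragments ----------------------------------------------------
    def mnase_condition(kd: bool) -> FragmentSet:
        rows_chrom, rows_start, rows_end = [], [], []

        def emit(chrom: str, centers: np.ndarray) -> None:
            lengths = rng.integers(cfg.mnase_len_range[0],
                                   cfg.mnase_len_range[1] + 1,
                                   size=centers.size)
            starts = centers - lengths // 2
            rows_chrom.append(np.full(centers.size, chrom, dtype=object))
            rows_start.append(starts)
            rows_end.append(starts + lengths)

        for i, (gid, chrom, strand, tss) in enumerate(genes):
            for dyad_off, n in ((cfg.nuc_minus1_offset, cfg.mnase_nuc_frags),
                                (cfg.nuc_plus1_offset, cfg.mnase_nuc_frags)):
                dyad = offset_pos(tss, strand, dyad_off)
                centers = np.rint(rng.normal(dyad, cfg.dyad_sd, size=n)
                                  ).astype(int)
                emit(chrom, centers)
            n_bg = rng.poisson(cfg.mnase_bg_rate * 1000)
            centers = rng.integers(tss - 500, tss + 500, size=n_bg)
            emit(chrom, centers)
            if kd and is_shifted[i]:
                centers = np.rint(rng.normal(tss, cfg.dyad_sd,
                                             size=cfg.tss_nuc_frags)
                                  ).astype(int)
                emit(chrom, centers)
        df = pd.DataFrame({
            "chrom": np.concatenate(rows_chrom),
            "start": np.concatenate(rows_start).astype(int),
            "end": np.concatenate(rows_end).astype(int),
            "strand": "+",
            "sample": "kd" if kd else "ctrl",
        })
        return FragmentSet(df)

    mnase = {"control": mnase_condition(False), "kd": mnase_condition(True)}

    # -- Ribo-Seq fragments --------------------------------------------------
    fp = cfg.footprint_length
    po = PipelineConfig().psite_offset

    def frame_jitter(n: int, purity: float) -> np.ndarray:
        """0 with prob purity, else +1/+2 within the codon."""
        u = rng.random(n)
        out = np.zeros(n, dtype=int)
        off_frame = u >= purity
        out[off_frame] = rng.integers(1, 3, size=int(off_frame.sum()))
        return out

    def ribo_condition(kd: bool) -> FragmentSet:
        rows_chrom, rows_start, rows_end, rows_strand = [], [], [], []

        def emit(chrom: str, strand: str, psites: np.ndarray) -> None:
            if strand == "+":
                starts = psites - po
            else:
                starts = psites + po - (fp - 1)
            rows_chrom.append(np.full(psites.size, chrom, dtype=object))
            rows_start.append(starts)
            rows_end.append(starts + fp)
            rows_strand.append(np.full(psites.size, strand, dtype=object))

        for i, (gid, chrom, strand, tss) in enumerate(genes):
            # canonical ORF
            codons = rng.integers(0, cfg.canonical_orf_codons,
                                  size=cfg.canonical_psites)
            offs = (cfg.cds_offset + 3 * codons
                    + frame_jitter(cfg.canonical_psites,
                                   cfg.canonical_frame0_purity))
            sign = 1 if strand == "+" else -1
            emit(chrom, strand, tss + sign * offs)
            # planted uORF (knockdown only)
            if kd and has_uorf[i]:
                codons = rng.integers(0, cfg.uorf_span // 3,
                                      size=cfg.uorf_psites)
                offs = (int(uorf_off[i]) + 3 * codons
                        + frame_jitter(cfg.uorf_psites, cfg.frame0_purity))
                emit(chrom, strand, tss + sign * offs)
            # scattered background
            n_bg = rng.poisson(cfg.ribo_bg_rate * 2 * hw)
            offs = rng.integers(-hw, hw, size=n_bg)
            emit(chrom, strand, tss + sign * offs)
        df = pd.DataFrame({
            "chrom": np.concatenate(rows_chrom),
            "start": np.concatenate(rows_start).astype(int),
            "end": np.concatenate(rows_end).astype(int),
            "strand": np.concatenate(rows_strand),
            "sample": "kd" if kd else "ctrl",
        })
        return FragmentSet(df)

    ribo = {"control": ribo_condition(False), "kd": ribo_condition(True)}

    # -- truth table ---------------------------------------------------------
    truth = pd.DataFrame({
        "gene_id": [g[0] for g in genes],
        "chrom": [g[1] for g in genes],
        "strand": [g[2] for g in genes],
        "tss": [g[3] for g in genes],
        "bound": is_bound,
        "shifted": is_shifted,
        "ectopic_offset": np.where(is_shifted, ect_offset, np.nan),
        "ectopic_pos": [
            offset_pos(g[3], g[2], int(ect_offset[i])) if is_shifted[i]
            else np.nan
            for i, g in enumerate(genes)],
        "nucleosome_gain": is_shifted,
        "uorf": has_uorf,
        "uorf_atg_offset": np.where(has_uorf, uorf_off, np.nan),
        "uorf_atg_pos": [
            offset_pos(g[3], g[2], int(uorf_off[i])) if has_uorf[i]
            else np.nan
            for i, g in enumerate(genes)],
    })

    return SimDataset(
        cfg=cfg, genome=genome, transcripts=transcripts, startseq=startseq,
        totals=totals, spike_counts=spike_counts, polii=polii, peaks=peaks,
        mnase=mnase, ribo=ribo, truth=truth, scale_factors=factors)
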