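"""End-to-end orchestration: from raw tracks to the summary report.

``run_all`` wires the stages together: spike-anchored normalization, observed
TSS calling, the binned differential test for ectopic initiation, nucleosome
encroachment, shifted-region translation, and promoter sequence features.
Every artefact is written as a plain-text table under the report directory;
given identical inputs the report is byte-identical between runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import ectopic as ect
from . import nucleosome as nuc
from . import observed as obs
from . import ribo as rb
from . import seqfeat as sf
from .model import UNSTRANDED, GenomicInterval, GenomicPosition, PipelineConfig
from .sim import SimDataset
from .spikes import SpikeInSet
from .tracks import (SignalTrack, fragment_center_track,
                     mean_replicate_track, normalize_per_ten_million,
                     read_annotation_bed12, read_bed6, read_bedgraph,
                     sum_tracks)

log = logging.getLogger("startshift")

PathLike = Union[str, Path]


def load_dataset(datadir: PathLike) -> SimDataset:
    """Read a dataset directory written by :meth:`SimDataset.write`."""
    from .sim import SimConfig

    d = Path(datadir)
    genome: dict[str, str] = {}
    name, chunks = None, []
    with open(d / "genome.fa") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)

    transcripts = read_annotation_bed12(d / "annotation.bed")
    spikes = pd.read_csv(d / "spikes.tsv", sep="\t", index_col=0)
    totals = pd.read_csv(d / "totals.tsv", sep="\t", index_col=0).iloc[:, 0]
    samples = list(spikes.columns)

    startseq = {}
    for s in samples:
        track = read_bedgraph(d / f"startseq_{s}_plus.bedgraph", strand="+",
                              label=f"startseq_{s}")
        minus = read_bedgraph(d / f"startseq_{s}_minus.bedgraph", strand="-")
        for chrom, strand, pos, val in minus.items():
            track.add(chrom, strand, pos, val)
        startseq[s] = track

    polii = read_bedgraph(d / "polii.bedgraph", strand=UNSTRANDED,
                          label="polii")
    peaks = []
    with open(d / "nfya_peaks.bed") as fh:
        for line in fh:
            p = line.split()
            if len(p) >= 3:
                peaks.append(GenomicInterval(p[0], int(p[1]), int(p[2]), "+"))
    mnase = {c: read_bed6(d / f"mnase_{c}.bed", sample=c)
             for c in ("control", "kd")}
    ribo = {c: read_bed6(d / f"ribo_{c}.bed", sample=c)
            for c in ("control", "kd")}
    truth_path = d / "truth.tsv"
    truth = (pd.read_csv(truth_path, sep="\t") if truth_path.exists()
             else pd.DataFrame())
    sf_path = d / "scale_factors.tsv"
    factors = (pd.read_csv(sf_path, sep="\t", index_col=0).iloc[:, 0]
               if sf_path.exists()
               else pd.Series(1.0, index=samples))

    n_rep = sum(1 for s in samples if s.startswith("ctrl"))
    cfg = SimConfig(replicates=n_rep,
                    true_scale_factors=tuple(factors.reindex(samples)))
    return SimDataset(cfg=cfg, genome=genome, transcripts=transcripts,
                      startseq=startseq, totals=totals.astype(float),
                      spike_counts=spikes, polii=polii, peaks=peaks,
                      mnase=mnase, ribo=ribo, truth=truth,
                      scale_factors=factors.astype(float))


# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


@dataclass
class PipelineResult:
    observed_calls: list
    ectopic_calls: list
    bins: pd.DataFrame
    occupancy: pd.DataFrame
    ribo_regions: pd.DataFrame
    summary: dict


def run_all(data: Union[SimDataset, PathLike], cfg: Optional[PipelineConfig],
            outdir: PathLike) -> PipelineResult:
    """Run every stage on a dataset and write the report directory."""
    cfg = cfg or PipelineConfig()
    if not isinstance(data, SimDataset):
        data = load_dataset(data)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.txt").write_text(cfg.describe() + "\n")
    log.info("resolved configuration:\n%s", cfg.describe())

    conditions = data.conditions
    ctrl_samples = data.control_samples
    kd_samples = data.kd_samples

    # -- spike-in normalization -------------------------------------------
    spikeset = SpikeInSet(counts=data.spike_counts,
                          total_mapped=data.totals).compute(
        denominator=cfg.norm_denominator)
    spike_frame = spikeset.to_frame().reset_index(names="sample")
    _write_tsv(spike_frame, out / "spike_factors.tsv")
    log.info("spike reference sample: %s; tracks are divided by each "
             "sample's regression factor", spikeset.reference)

    # normalized tracks: per-10M depth, then divided by the spike factor
    norm_tracks = {}
    for s, track in data.startseq.items():
        per10m = normalize_per_ten_million(track, float(data.totals[s]),
                                           cfg.norm_denominator)
        norm_tracks[s] = per10m.scaled(
            1.0 / float(spikeset.normalization_factors[s]),
            normalization="spike-normalized")
    mean_ctrl = mean_replicate_track([norm_tracks[s] for s in ctrl_samples])
    mean_kd = mean_replicate_track([norm_tracks[s] for s in kd_samples])

    # -- observed TSS calling ----------------------------------------------
    raw_ctrl = sum_tracks([data.startseq[s] for s in ctrl_samples],
                          label="control_raw_5p")
    calls = obs.call_all_observed(data.transcripts, raw_ctrl, data.polii, cfg)
    calls = obs.deduplicate_calls(calls, cfg)
    bound = {c.transcript_id: obs.classify_nfy_bound(c, data.peaks, cfg)
             for c in calls}
    obs_frame = obs.calls_to_frame(calls)
    if len(obs_frame):
        obs_frame["nfy_bound"] = [bound[t] for t in obs_frame["transcript_id"]]
    else:
        obs_frame["nfy_bound"] = pd.Series(dtype=bool)
    _write_tsv(obs_frame, out / "observed_tss.tsv")
    _write_bed_positions(obs_frame, out / "observed_tss.bed",
                         pos_col="observed_pos", name_col="transcript_id")

    # -- ectopic TSS calling -------------------------------------------------
    tss_index = _tss_index(calls)
    bin_frames = []
    for c in calls:
        b = ect.bin_counts(c, data.startseq, cfg)
        bin_frames.append(ect.exclude_bins(b, c, tss_index, cfg))
    if bin_frames:
        bins = pd.concat(bin_frames, ignore_index=True)
        bins = ect.nb_bin_test(bins, spikeset.size_factors, conditions, cfg)
    else:
        bins = pd.DataFrame()
    _write_tsv(bins, out / "ectopic_bins.tsv")

    kd_raw = [data.startseq[s] for s in kd_samples]
    ectopic_calls = []
    for c in calls:
        gene_bins = bins[bins["gene_id"] == c.gene_id] if len(bins) else bins
        if len(gene_bins) == 0:
            continue
        call = ect.select_ectopic(gene_bins, c, kd_raw, cfg)
        if call is not None:
            ectopic_calls.append(call)
    ect_frame = ect.calls_to_frame(ectopic_calls)
    _write_tsv(ect_frame, out / "ectopic_calls.tsv")
    _write_bed_positions(ect_frame, out / "ectopic_tss.bed",
                         pos_col="ectopic_pos", name_col="gene_id")

    summary_stats = ect.shift_summary(ectopic_calls)
    shifted_genes = {c.gene_id for c in ectopic_calls}

    # -- nucleosome encroachment ---------------------------------------------
    occ_frame, encroach_summary = _nucleosome_stage(
        data, calls, bound, shifted_genes, cfg, out)

    # -- ribosome footprints ---------------------------------------------------
    ribo_frame, ribo_summary = _ribo_stage(
        data, calls, bound, ectopic_calls, cfg, out)

    # -- promoter sequence features -------------------------------------------
    ect_by_gene = {c.gene_id: c for c in ectopic_calls}
    feature_rows = []
    for c in calls:
        e = ect_by_gene.get(c.gene_id)
        feature_rows.append(sf.promoter_features(
            data.genome, c.gene_id, c.position,
            ectopic=e.position if e is not None else None))
    _write_tsv(sf.features_to_frame(feature_rows),
               out / "promoter_features.tsv")

    # -- metagene matrices ------------------------------------------------------
    _metagene_stage(mean_ctrl, mean_kd, calls, bound, shifted_genes, cfg, out)

    summary = {
        "n_transcripts": len(data.transcripts),
        "n_observed_tss": len(calls),
        "n_nfy_bound": int(sum(bound.values())),
        "n_ectopic_calls": len(ectopic_calls),
        "median_shift_distance": (summary_stats.median_shift
                                  if summary_stats else None),
        "upstream_fraction": (summary_stats.upstream_fraction
                              if summary_stats else None),
        **encroach_summary,
        **ribo_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(observed_calls=calls, ectopic_calls=ectopic_calls,
                          bins=bins, occupancy=occ_frame,
                          ribo_regions=ribo_frame, summary=summary)


# ---------------------------------------------------------------------------
# stage helpers


def _tss_index(calls) -> dict[tuple[str, str], np.ndarray]:
    index: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        index.setdefault((c.chrom, c.strand), []).append(c.observed_pos)
    return {k: np.array(sorted(v)) for k, v in index.items()}


def _write_bed_positions(frame: pd.DataFrame, path: Path, pos_col: str,
                         name_col: str) -> None:
    with open(path, "w") as fh:
        if len(frame) == 0:
            return
        rows = frame.sort_values(["chrom", pos_col, name_col], kind="stable")
        for r in rows.itertuples(index=False):
            pos = int(getattr(r, pos_col))
            fh.write(f"{r.chrom}\t{pos}\t{pos + 1}\t{getattr(r, name_col)}"
                     f"\t0\t{r.strand}\n")


def _nucleosome_stage(data, calls, bound, shifted_genes, cfg, out):
    tracks = {}
    for cond, frags in data.mnase.items():
        filtered = nuc.filter_fragments(frags, cfg)
        centers = fragment_center_track(filtered, label=f"mnase_{cond}")
        tracks[cond] = normalize_per_ten_million(
            centers, max(len(filtered), 1), cfg.norm_denominator)
    changes = [nuc.tss_occupancy_change(tracks["control"], tracks["kd"],
                                        c, cfg) for c in calls]
    occ_frame = nuc.changes_to_frame(changes)
    if len(occ_frame):
        occ_frame["nfy_bound"] = [bound[c.transcript_id] for c in calls]
        occ_frame["tss_shifted"] = [c.gene_id in shifted_genes for c in calls]
    else:
        occ_frame["nfy_bound"] = pd.Series(dtype=bool)
        occ_frame["tss_shifted"] = pd.Series(dtype=bool)
    _write_tsv(occ_frame, out / "encroachment.tsv")

    def frac(mask: pd.Series) -> Optional[float]:
        sub = occ_frame[mask]
        return float(sub["encroached"].mean()) if len(sub) else None

    summary = {
        "encroached_fraction_shifted_bound":
            frac(occ_frame["nfy_bound"] & occ_frame["tss_shifted"]),
        "encroached_fraction_nonshifted_bound":
            frac(occ_frame["nfy_bound"] & ~occ_frame["tss_shifted"]),
    }
    return occ_frame, summary


def _ribo_stage(data, calls, bound, ectopic_calls, cfg, out):
    psites = {cond: rb.psite_track(frags, cfg, label=f"psites_{cond}")
              for cond, frags in data.ribo.items()}
    totals = {cond: float(len(frags)) for cond, frags in data.ribo.items()}

    ect_by_gene = {c.gene_id: c for c in ectopic_calls}
    results = []
    phasing_rows = []
    for c in calls:
        e = ect_by_gene.get(c.gene_id)
        try:
            if e is not None:
                region = rb.shifted_region(e.ectopic_pos, c.observed_pos,
                                           c.chrom, c.strand,
                                           cfg.ribo_region_margin)
            elif not bound[c.transcript_id]:
                region = rb.surrogate_region(c.observed_pos, c.chrom,
                                             c.strand, cfg)
            else:
                continue
        except ValueError:
            continue
        results.append(rb.shifted_region_rpkm(
            c.gene_id, region, data.ribo["control"], data.ribo["kd"],
            max(totals["control"], 1.0), max(totals["kd"], 1.0)))
        if e is not None:
            atg = rb.select_ectopic_atg(data.genome, region, psites["kd"], cfg)
            if atg is not None:
                ph = rb.phasing(psites["kd"], atg, cfg)
                phasing_rows.append({
                    "gene_id": c.gene_id, "anchor_pos": atg.pos,
                    "context": "ectopic_atg_kd",
                    "f0": ph.frame_counts[0], "f1": ph.frame_counts[1],
                    "f2": ph.frame_counts[2],
                    "frame0_fraction": ph.frame0_fraction,
                    "chi_square": ph.chi_square, "p": ph.p,
                })

    # dominant-gene exclusion for the phasing analysis
    region_counts = {r.gene_id: r.kd_count for r in results
                     if r.gene_id in ect_by_gene}
    kept = set(rb.filter_dominant_genes(region_counts, totals["kd"], cfg)) \
        if region_counts else set()
    results = [
        rb.RiboRegionResult(r.gene_id, r.region, r.control_rpkm, r.kd_rpkm,
                            r.control_count, r.kd_count,
                            excluded=(r.gene_id in ect_by_gene
                                      and r.gene_id not in kept))
        for r in results]
    ribo_frame = rb.region_results_to_frame(results)
    _write_tsv(ribo_frame, out / "ribo_regions.tsv")
    _write_tsv(pd.DataFrame(phasing_rows), out / "ribo_phasing.tsv")

    shifted = ribo_frame[ribo_frame["gene_id"].isin(ect_by_gene)] \
        if len(ribo_frame) else ribo_frame
    covered = shifted[(shifted["control_count"] + shifted["kd_count"]) > 0] \
        if len(shifted) else shifted
    frac = (float((covered["kd_rpkm"] > covered["control_rpkm"]).mean())
            if len(covered) else None)
    return ribo_frame, {
        "ribo_fraction_kd_above_control": frac,
        "n_ribo_regions": int(len(ribo_frame)),
    }


def _metagene_stage(mean_ctrl, mean_kd, calls, bound, shifted_genes, cfg, out):
    lo, hi = -cfg.tss_search_radius, cfg.tss_search_radius
    offsets = np.arange(lo, hi + 1)
    groups = {
        "shifted": [c for c in calls if c.gene_id in shifted_genes],
        "bound": [c for c in calls if bound[c.transcript_id]],
        "unbound": [c for c in calls if not bound[c.transcript_id]],
    }
    pc = cfg.log2fc_pseudocount
    cols = {"offset": offsets}
    for name, members in groups.items():
        if not members:
            cols[f"log2fc_{name}"] = np.full(offsets.size, np.nan)
            continue
        rows = []
        for c in members:
            a = c.position
            num = mean_kd.oriented_window(a, lo, hi) + pc
            den = mean_ctrl.oriented_window(a, lo, hi) + pc
            rows.append(np.log2(num / den))
        cols[f"log2fc_{name}"] = np.mean(rows, axis=0)
    _write_tsv(pd.DataFrame(cols), out / "metagene_start_log2fc.tsv")


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item())
    return obj
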