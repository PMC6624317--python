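"""Parameter-recovery experiments on synthetic data.

Each function generates a dataset with :mod:`startshift.sim`, runs the
relevant pipeline stage, and scores the result against the planted truth.
They are the package's own validation harness: because the generator's truth
is known exactly, recovery rates, calibration and positional error measure
the methods directly, without reference data.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import ectopic as ect
from . import nucleosome as nuc
from . import ribo as rb
from .model import GenomicPosition, PipelineConfig
from .observed import ObservedTssCall
from .pipeline import run_all
from .sim import SimConfig, SimDataset, simulate
from .spikes import SpikeInSet
from .tracks import fragment_center_track, normalize_per_ten_million


def _truth_calls(data: SimDataset) -> list[ObservedTssCall]:
    """Observed-TSS calls anchored at the generator's true TSS positions."""
    return [
        ObservedTssCall(row.gene_id + ".t", row.gene_id, row.chrom,
                        row.strand, int(row.tss), int(row.tss),
                        "startseq_primary", 100.0, 0)
        for row in data.truth.itertuples()
    ]


def run_ectopic_caller(data: SimDataset,
                       cfg: Optional[PipelineConfig] = None
                       ) -> list[ect.EctopicTssCall]:
    """The ectopic-calling chain (binning, test, selection) on a dataset."""
    cfg = cfg or PipelineConfig()
    spikeset = SpikeInSet(counts=data.spike_counts,
                          total_mapped=data.totals).compute(
        denominator=cfg.norm_denominator)
    calls = _truth_calls(data)
    index: dict = {}
    for c in calls:
        index.setdefault((c.chrom, c.strand), []).append(c.observed_pos)
    index = {k: np.array(sorted(v)) for k, v in index.items()}

    frames = []
    for c in calls:
        b = ect.bin_counts(c, data.startseq, cfg)
        frames.append(ect.exclude_bins(b, c, index, cfg))
    bins = pd.concat(frames, ignore_index=True)
    bins = ect.nb_bin_test(bins, spikeset.size_factors, data.conditions, cfg)

    kd_tracks = [data.startseq[s] for s in data.kd_samples]
    out = []
    for c in calls:
        res = ect.select_ectopic(bins[bins["gene_id"] == c.gene_id], c,
                                 kd_tracks, cfg)
        if res is not None:
            out.append(res)
    return out


def ectopic_recovery(seed: int, sim_cfg: Optional[SimConfig] = None) -> dict:
    """Recovery of planted ectopic TSSs on the default 200-gene dataset.

    Reports the fraction of planted genes called (padj < 0.1), positional
    error against the planted base, the null-gene call rate, and the shift
    summary.
    """
    data = simulate(sim_cfg or SimConfig(), seed=seed)
    calls = {c.gene_id: c for c in run_ectopic_caller(data)}
    truth = data.truth
    planted = truth[truth["shifted"]]
    null = truth[~truth["shifted"]]
    hits = [g for g in planted["gene_id"] if g in calls]
    errors = [abs(calls[g].ectopic_pos - int(p))
              for g, p in zip(planted["gene_id"], planted["ectopic_pos"])
              if g in calls]
    summary = ect.shift_summary(list(calls.values()))
    return {
        "n_planted": int(len(planted)),
        "recall": len(hits) / max(len(planted), 1),
        "max_position_error": float(max(errors)) if errors else float("nan"),
        "median_position_error": float(np.median(errors)) if errors else
            float("nan"),
        "null_call_rate": float(null["gene_id"].isin(calls).mean()),
        "median_shift": summary.median_shift if summary else float("nan"),
        "upstream_fraction": (summary.upstream_fraction if summary
                              else float("nan")),
        "min_abs_offset": (min(abs(c.offset) for c in calls.values())
                           if calls else float("nan")),
    }


def nb_calibration(seed: int, n_bins: int = 10_000, mean: float = 20.0,
                   dispersion: float = 0.05, replicates: int = 3) -> dict:
    """Empirical type-I error of the NB exact test on matched null bins."""
    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion
    p = r / (r + mean)
    n = 2 * replicates
    counts = rng.negative_binomial(r, p, size=(n_bins, n)).astype(float)
    samples = ([f"c{i}" for i in range(replicates)]
               + [f"k{i}" for i in range(replicates)])
    df = pd.DataFrame({"gene_id": "null", "bin_index": np.arange(n_bins),
                       "off_lo": 0, "off_hi": 9, "excluded": False})
    for j, s in enumerate(samples):
        df[f"count:{s}"] = counts[:, j]
    cond = {s: ("control" if s.startswith("c") else "kd") for s in samples}
    res = ect.nb_bin_test(df, pd.Series(1.0, index=samples), cond)
    return {
        "type1_at_005": float((res["p"] < 0.05).mean()),
        "type1_at_001": float((res["p"] < 0.01).mean()),
        "fdr_hits_at_01": float((res["padj"] < 0.1).mean()),
    }


def spike_recovery(seed: int,
                   true_factors: tuple[float, ...] = (1.0, 1.7, 0.6, 2.4),
                   n_spikes: int = 15, mean_reads: float = 300.0) -> dict:
    """Recovery of known global scale factors from Poisson spike counts."""
    rng = np.random.default_rng(seed)
    true = np.asarray(true_factors, dtype=float)
    k = np.arange(n_spikes) - (n_spikes - 1) / 2.0
    abundance = mean_reads * 1.3 ** k
    abundance *= mean_reads / abundance.mean()
    counts = pd.DataFrame(
        {f"s{i}": rng.poisson(abundance * t) for i, t in enumerate(true)},
        index=[f"spike{i:02d}" for i in range(n_spikes)])
    totals = pd.Series(1e7, index=counts.columns)
    spikeset = SpikeInSet(counts=counts, total_mapped=totals).compute()

    ref_idx = list(counts.columns).index(spikeset.reference)
    reg_truth = true / true[ref_idx]
    reg_err = np.abs(spikeset.normalization_factors.to_numpy()
                     / reg_truth - 1)
    sf_truth = true / np.exp(np.mean(np.log(true)))
    sf_err = np.abs(spikeset.size_factors.to_numpy() / sf_truth - 1)
    return {
        "reference": spikeset.reference,
        "max_regression_rel_error": float(reg_err.max()),
        "max_size_factor_rel_error": float(sf_err.max()),
    }


def mnase_recovery(seed: int, sim_cfg: Optional[SimConfig] = None) -> dict:
    """Encroachment classification against the planted nucleosome gains."""
    cfg = PipelineConfig()
    data = simulate(sim_cfg or SimConfig(), seed=seed)
    tracks = {}
    for cond, frags in data.mnase.items():
        filtered = nuc.filter_fragments(frags, cfg)
        centers = fragment_center_track(filtered)
        tracks[cond] = normalize_per_ten_million(centers, len(filtered),
                                                 cfg.norm_denominator)
    calls = _truth_calls(data)
    flags = {}
    for c in calls:
        oc = nuc.tss_occupancy_change(tracks["control"], tracks["kd"], c, cfg)
        flags[c.gene_id] = oc.encroached
    truth = data.truth
    planted = truth.loc[truth["nucleosome_gain"], "gene_id"]
    unplanted = truth.loc[~truth["nucleosome_gain"], "gene_id"]
    return {
        "planted_encroached_fraction":
            float(np.mean([flags[g] for g in planted])) if len(planted)
            else float("nan"),
        "unplanted_encroached_fraction":
            float(np.mean([flags[g] for g in unplanted])) if len(unplanted)
            else float("nan"),
    }


def ribo_phasing_recovery(seed: int,
                          sim_cfg: Optional[SimConfig] = None) -> dict:
    """uORF start selection and triplet periodicity against planted truth.

    Also scores an RNA-Seq-like control: P-sites drawn uniformly over the
    same spans, whose frame-0 fraction should sit near 1/3.
    """
    cfg = PipelineConfig()
    data = simulate(sim_cfg or SimConfig(), seed=seed)
    psites_kd = rb.psite_track(data.ribo["kd"], cfg)
    truth = data.truth
    uorf = truth[truth["uorf"]]

    correct = 0
    pvals = []
    rpkm_kd_higher = 0
    n_regions = 0
    ctrl_total = max(len(data.ribo["control"]), 1)
    kd_total = max(len(data.ribo["kd"]), 1)
    for row in uorf.itertuples():
        region = rb.shifted_region(int(row.ectopic_pos), int(row.tss),
                                   row.chrom, row.strand,
                                   cfg.ribo_region_margin)
        atg = rb.select_ectopic_atg(data.genome, region, psites_kd, cfg)
        if atg is not None and atg.pos == int(row.uorf_atg_pos):
            correct += 1
        anchor = GenomicPosition(row.chrom, int(row.uorf_atg_pos), row.strand)
        pvals.append(rb.phasing(psites_kd, anchor, cfg).p)
        res = rb.shifted_region_rpkm(row.gene_id, region,
                                     data.ribo["control"], data.ribo["kd"],
                                     ctrl_total, kd_total)
        n_regions += 1
        if res.kd_rpkm > res.control_rpkm:
            rpkm_kd_higher += 1

    # matched RNA-Seq-like control: uniform P-sites over the scored spans
    rng = np.random.default_rng(seed + 1)
    span = 3 * cfg.phasing_span_codons
    frame0 = []
    for row in uorf.itertuples():
        offs = rng.integers(0, span, size=150)
        f0 = np.mean(offs % 3 == 0)
        frame0.append(f0)
    return {
        "n_uorf_genes": int(len(uorf)),
        "selector_accuracy": correct / max(len(uorf), 1),
        "max_phasing_p": float(max(pvals)) if pvals else float("nan"),
        "uniform_frame0_fraction": float(np.mean(frame0)) if frame0 else
            float("nan"),
        "fraction_kd_rpkm_above_control":
            rpkm_kd_higher / max(n_regions, 1),
    }


def core_exclusion_guarantee(seed: int, n_runs: int = 100,
                             n_genes: int = 12) -> dict:
    """No ectopic call may ever fall within +/-25 nt of the observed TSS."""
    violations = 0
    n_calls = 0
    for i in range(n_runs):
        data = simulate(SimConfig(n_genes=n_genes), seed=seed + i)
        for call in run_ectopic_caller(data):
            n_calls += 1
            if abs(call.offset) <= 25:
                violations += 1
    return {"n_runs": n_runs, "n_calls": n_calls, "violations": violations}


def determinism_check(seed: int, n_genes: int = 16) -> dict:
    """Two pipeline runs with the same seed must write identical bytes."""
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data = simulate(SimConfig(n_genes=n_genes), seed=seed)
        run_all(data, PipelineConfig(), tmp / "a")
        data2 = simulate(SimConfig(n_genes=n_genes), seed=seed)
        run_all(data2, PipelineConfig(), tmp / "b")
        files = sorted(p.name for p in (tmp / "a").iterdir())
        same_names = files == sorted(p.name for p in (tmp / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(tmp / "a", tmp / "b",
                                                   files, shallow=False)
    return {"identical": bool(same_names and not mismatch and not errors),
            "n_files": len(files)}
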