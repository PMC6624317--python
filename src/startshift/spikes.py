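"""Spike-in anchored cross-sample normalization.

Synthetic capped RNAs spiked in at a fixed amount per cell anchor two
estimators:

* a per-sample *normalization factor* — the least-squares slope (through the
  origin) of the sample's depth-normalized spike counts against the reference
  sample (the one with the lowest total spike count).  Signal tracks are
  **divided** by this factor to bring all samples onto the reference scale.
* per-sample *size factors* for the count-based differential test — the
  median-of-ratios estimator computed on the spike count matrix alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]


def spike_normalization_factor(sample_counts: np.ndarray,
                               ref_counts: np.ndarray) -> float:
    """Least-squares slope through the origin of sample vs reference counts.

    Counts should be depth-normalized before the fit.  Requires at least two
    spikes with nonzero reference counts.
    """
    x = np.asarray(ref_counts, dtype=float)
    y = np.asarray(sample_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sample and reference count vectors differ in length")
    if np.count_nonzero(x) < 2:
        raise ValueError("need >= 2 spikes with nonzero reference counts")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("all-zero reference spike counts")
    return float(np.sum(x * y) / denom)


def size_factors_from_spikes(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a spikes x samples count matrix.

    For each spike present in every sample (no zero counts), its geometric
    mean across samples is the pseudo-reference; a sample's factor is the
    median over those spikes of count / geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    nonzero = (mat > 0).all(axis=1)
    if nonzero.sum() < 1:
        raise ValueError("no spike has nonzero counts in every sample")
    sub = mat[nonzero]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class SpikeInSet:
    """Spike-in count table with derived normalization state."""

    counts: pd.DataFrame              # rows = spikes, columns = samples
    total_mapped: pd.Series           # per-sample total mapped reads
    reference: str = ""
    normalization_factors: Optional[pd.Series] = None
    size_factors: Optional[pd.Series] = None

    @classmethod
    def from_tsv(cls, spikes_path: PathLike,
                 totals: Union[pd.Series, PathLike]) -> "SpikeInSet":
        counts = pd.read_csv(spikes_path, sep="\t", index_col=0)
        if not isinstance(totals, pd.Series):
            tdf = pd.read_csv(totals, sep="\t", index_col=0)
            totals = tdf.iloc[:, 0]
        totals = totals.reindex(counts.columns)
        if totals.isna().any():
            missing = list(totals[totals.isna()].index)
            raise ValueError(f"no total mapped reads for samples {missing}")
        return cls(counts=counts, total_mapped=totals.astype(float))

    def depth_normalized(self, denominator: float = 1e7) -> pd.DataFrame:
        return self.counts * (denominator / self.total_mapped)

    def compute(self, reference: str = "auto",
                denominator: float = 1e7) -> "SpikeInSet":
        """Fill in the reference sample, regression factors and size factors."""
        if reference == "auto":
            # reference = sample with the lowest total spike-in read count
            reference = str(self.counts.sum(axis=0).idxmin())
        if reference not in self.counts.columns:
            raise ValueError(f"unknown reference sample {reference!r}")
        depth_norm = self.depth_normalized(denominator)
        ref = depth_norm[reference].to_numpy()
        factors = {
            sample: spike_normalization_factor(depth_norm[sample].to_numpy(), ref)
            for sample in self.counts.columns
        }
        self.reference = reference
        self.normalization_factors = pd.Series(factors, name="norm_factor")
        self.size_factors = size_factors_from_spikes(self.counts)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Per-sample summary of the derived factors."""
        if self.normalization_factors is None:
            raise ValueError("call compute() first")
        return pd.DataFrame({
            "total_spike_reads": self.counts.sum(axis=0),
            "total_mapped": self.total_mapped,
            "norm_factor": self.normalization_factors,
            "size_factor": self.size_factors,
            "is_reference": [
                c == self.reference for c in self.counts.columns],
        })
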