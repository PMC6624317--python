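"""Signal tracks, fragment sets, annotations, and their text-format I/O.

``SignalTrack`` is the universal per-base signal carrier (Start-Seq 5' ends,
MNase fragment centers, Ribo-Seq P-sites, conservation scores).  It stores a
dense float array per (chromosome, strand) slot, grown lazily; unstranded
tracks use the ``"."`` strand slot.  All I/O is plain-text bedGraph/BED with
0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import UNSTRANDED, GenomicPosition

PathLike = Union[str, Path]


class SignalTrack:
    """Per-base numeric signal keyed by (chromosome, strand)."""

    def __init__(self, label: str = "", normalization: str = "raw",
                 fill: float = 0.0):
        self.label = label
        #: one of {"raw", "per10M", "spike-normalized"} (informational)
        self.normalization = normalization
        #: value at positions never written (0 for counts, NaN for scores)
        self.fill = fill
        self._data: dict[tuple[str, str], np.ndarray] = {}

    # -- construction -----------------------------------------------------

    def _slot(self, chrom: str, strand: str, min_len: int) -> np.ndarray:
        key = (chrom, strand)
        arr = self._data.get(key)
        if arr is None:
            arr = np.full(max(min_len, 256), self.fill, dtype=float)
            self._data[key] = arr
        elif arr.size < min_len:
            grown = np.full(max(min_len, 2 * arr.size), self.fill, dtype=float)
            grown[: arr.size] = arr
            self._data[key] = arr = grown
        return arr

    def add(self, chrom: str, strand: str, pos: int, value: float = 1.0) -> None:
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        arr = self._slot(chrom, strand, pos + 1)
        if np.isnan(arr[pos]):
            arr[pos] = 0.0
        arr[pos] += value

    def set_range(self, chrom: str, strand: str, start: int, end: int,
                  value: float) -> None:
        arr = self._slot(chrom, strand, end)
        arr[start:end] = value

    def add_range(self, chrom: str, strand: str, start: int, end: int,
                  value: float = 1.0) -> None:
        arr = self._slot(chrom, strand, end)
        seg = arr[start:end]
        seg[np.isnan(seg)] = 0.0
        seg += value

    def add_at(self, chrom: str, strand: str, positions: np.ndarray,
               values: Optional[np.ndarray] = None) -> None:
        """Accumulate counts at many positions (repeated positions add up)."""
        positions = np.asarray(positions, dtype=int)
        if positions.size == 0:
            return
        if (positions < 0).any():
            raise ValueError("negative positions")
        arr = self._slot(chrom, strand, int(positions.max()) + 1)
        np.add.at(arr, positions,
                  1.0 if values is None else np.asarray(values, dtype=float))

    # -- access ------------------------------------------------------------

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def has_chrom(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self._data)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        return self._data.get((chrom, strand),
                              np.full(0, self.fill, dtype=float))

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); out-of-range bases read as ``fill``."""
        out = np.full(end - start, self.fill, dtype=float)
        arr = self._data.get((chrom, strand))
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, arr.size)
        if lo < hi:
            out[lo - start: hi - start] = arr[lo:hi]
        return out

    def oriented_window(self, anchor: GenomicPosition, lo: int, hi: int,
                        strand: Optional[str] = None) -> np.ndarray:
        """Values at strand-relative offsets ``lo..hi`` inclusive.

        Index ``i`` of the result is offset ``lo + i`` from the anchor in the
        anchor's strand direction.  ``strand`` selects the track slot (defaults
        to the anchor strand; pass ``"."`` for unstranded tracks).
        """
        slot = anchor.strand if strand is None else strand
        if anchor.strand == "+":
            vals = self.window(anchor.chrom, slot, anchor.pos + lo,
                               anchor.pos + hi + 1)
        else:
            vals = self.window(anchor.chrom, slot, anchor.pos - hi,
                               anchor.pos - lo + 1)[::-1]
        return vals

    def total(self) -> float:
        return float(sum(np.nansum(a) for a in self._data.values()))

    # -- transforms ---------------------------------------------------------

    def scaled(self, factor: float, normalization: Optional[str] = None,
               label: Optional[str] = None) -> "SignalTrack":
        out = SignalTrack(label if label is not None else self.label,
                          normalization or self.normalization, self.fill)
        for key, arr in self._data.items():
            out._data[key] = arr * factor
        return out

    def copy(self) -> "SignalTrack":
        return self.scaled(1.0)

    def items(self) -> Iterator[tuple[str, str, int, float]]:
        """Yield (chrom, strand, pos, value) for nonzero, non-fill bases."""
        for (chrom, strand) in self.keys():
            arr = self._data[(chrom, strand)]
            if np.isnan(self.fill):
                idx = np.nonzero(~np.isnan(arr))[0]
            else:
                idx = np.nonzero(arr != self.fill)[0]
            for pos in idx:
                yield chrom, strand, int(pos), float(arr[pos])


def normalize_per_ten_million(track: SignalTrack, total_mapped: float,
                              denominator: float = 1e7) -> SignalTrack:
    """Scale every value by ``denominator / total_mapped``."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return track.scaled(denominator / total_mapped, normalization="per10M")


def mean_replicate_track(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Genome-wide per-base mean of replicate tracks."""
    if not tracks:
        raise ValueError("no tracks to average")
    out = SignalTrack(tracks[0].label, tracks[0].normalization, tracks[0].fill)
    keys = sorted({k for t in tracks for k in t._data})
    n = len(tracks)
    for chrom, strand in keys:
        size = max(t._data[(chrom, strand)].size
                   for t in tracks if (chrom, strand) in t._data)
        acc = np.zeros(size, dtype=float)
        for t in tracks:
            arr = t._data.get((chrom, strand))
            if arr is not None:
                acc[: arr.size] += arr
            # tracks missing the slot contribute zeros
        out._data[(chrom, strand)] = acc / n
    return out


def sum_tracks(tracks: Sequence[SignalTrack], label: str = "") -> SignalTrack:
    avg = mean_replicate_track(tracks)
    return avg.scaled(len(tracks), label=label)


# ---------------------------------------------------------------------------
# bedGraph I/O


def read_bedgraph(path: PathLike, strand: str = UNSTRANDED,
                  label: str = "", fill: float = 0.0) -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open) into a per-base track."""
    track = SignalTrack(label=label or Path(path).stem, fill=fill)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, "
                    f"got {len(parts)}")
            chrom, s, e, v = parts
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: bad interval {s}..{e}")
            track.set_range(chrom, strand, start, end, value)
    return track


def write_bedgraph(track: SignalTrack, path: PathLike,
                   strand: Optional[str] = None) -> None:
    """Write one strand slot (or the only slot) as 4-column bedGraph.

    Adjacent equal-valued bases are merged into runs; fill-valued bases are
    omitted.  Output order is (chrom, position), so a write is byte-stable.
    """
    keys = track.keys()
    if strand is not None:
        keys = [k for k in keys if k[1] == strand]
    with open(path, "w") as fh:
        for chrom, st in keys:
            arr = track._data[(chrom, st)]
            if np.isnan(track.fill):
                mask = ~np.isnan(arr)
            else:
                mask = arr != track.fill
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                continue
            run_start = int(idx[0])
            run_val = arr[run_start]
            prev = run_start
            for pos in idx[1:]:
                pos = int(pos)
                if pos == prev + 1 and arr[pos] == run_val:
                    prev = pos
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")
                run_start = prev = pos
                run_val = arr[pos]
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")


# ---------------------------------------------------------------------------
# Fragments


@dataclass
class FragmentSet:
    """Paired-end fragments as a DataFrame (chrom, start, end, strand, sample).

    ``deduplicated``/``length_filtered`` record which cleanups have run.
    """

    frame: pd.DataFrame
    deduplicated: bool = False
    length_filtered: bool = False

    COLUMNS = ("chrom", "start", "end", "strand", "sample")

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.frame.columns:
                raise ValueError(f"fragment frame missing column {col!r}")
        if "strand" not in self.frame.columns:
            self.frame = self.frame.assign(strand="+")
        if "sample" not in self.frame.columns:
            self.frame = self.frame.assign(sample="")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def filter_lengths(self, lo: int, hi: int) -> "FragmentSet":
        """Keep fragments with ``lo <= length <= hi`` (inclusive bounds)."""
        keep = (self.lengths >= lo) & (self.lengths <= hi)
        return FragmentSet(self.frame.loc[keep].reset_index(drop=True),
                           deduplicated=self.deduplicated,
                           length_filtered=True)

    def deduplicate(self) -> "FragmentSet":
        """Drop fragments sharing (chrom, start, end); strand not consulted."""
        df = self.frame.drop_duplicates(
            subset=["chrom", "start", "end"]).reset_index(drop=True)
        return FragmentSet(df, deduplicated=True,
                           length_filtered=self.length_filtered)


def read_bed6(path: PathLike, sample: str = "") -> FragmentSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "+"
            rows.append((chrom, start, end, strand, sample))
    df = pd.DataFrame(rows, columns=list(FragmentSet.COLUMNS))
    return FragmentSet(df)


def write_bed6(frags: FragmentSet, path: PathLike) -> None:
    df = frags.frame.sort_values(
        ["chrom", "start", "end", "strand"], kind="stable")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = row.sample or "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t"
                     f"{row.strand}\n")


def fragment_center_track(frags: FragmentSet, label: str = "centers") -> SignalTrack:
    """One count at each fragment midpoint.

    The midpoint is ``(start + end) // 2`` in 0-based coordinates — exact for
    odd-length fragments, rounded toward the 3' half for even lengths — a
    deterministic, strand-independent convention.
    """
    track = SignalTrack(label=label)
    df = frags.frame
    if len(df) == 0:
        return track
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    chroms = df["chrom"].to_numpy()
    for chrom in sorted(set(chroms)):
        track.add_at(str(chrom), UNSTRANDED, mids[chroms == chrom])
    return track


def atac_insertion_track(frags: FragmentSet, smooth: bool = False,
                         core: int = 9, smoothed_width: int = 51) -> SignalTrack:
    """Coverage over the transposase-bound ends of each fragment.

    Raw mode covers the first ``core`` bases of both mates ([start, start+9)
    and [end-9, end)).  Smooth mode symmetrically extends each core region to
    ``smoothed_width`` before accumulating.
    """
    pad = (smoothed_width - core) // 2 if smooth else 0
    track = SignalTrack(label="atac_insertions",
                        normalization="raw")
    for row in frags.frame.itertuples(index=False):
        for lo, hi in ((row.start, row.start + core), (row.end - core, row.end)):
            track.add_range(row.chrom, UNSTRANDED, max(lo - pad, 0), hi + pad)
    return track


# ---------------------------------------------------------------------------
# Transcript annotation


_LOW_CONFIDENCE_MARKERS = ("Rik", "Gm")


def _looks_low_confidence(name: str) -> bool:
    """RIKEN cDNA (…Rik) and predicted-gene (Gm####) naming conventions."""
    if name.endswith("Rik"):
        return True
    if name.startswith("Gm") and name[2:].isdigit():
        return True
    return False


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: Optional[int] = None  # genomic coordinate of first CDS base
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty transcript interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Annotated TSS: 5' end of the interval on its strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tss_position(self) -> GenomicPosition:
        return GenomicPosition(self.chrom, self.tss, self.strand)


def read_annotation_bed12(path: PathLike) -> list[TranscriptAnnotation]:
    """Read transcripts from BED12 (or BED6+); thickStart marks the CDS."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            p = line.split()
            if len(p) < 6:
                raise ValueError(f"{path}:{lineno}: need >= 6 BED columns")
            chrom, start, end, name, _score, strand = p[:6]
            start, end = int(start), int(end)
            cds_start: Optional[int] = None
            if len(p) >= 8:
                thick_s, thick_e = int(p[6]), int(p[7])
                if thick_s < thick_e:
                    cds_start = thick_s if strand == "+" else thick_e - 1
            gene = name.rsplit(".", 1)[0]
            out.append(TranscriptAnnotation(
                transcript_id=name, gene_id=gene, chrom=chrom,
                start=start, end=end, strand=strand, cds_start=cds_start,
                low_confidence=_looks_low_confidence(gene)))
    return out


def write_annotation_bed12(transcripts: Sequence[TranscriptAnnotation],
                           path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            if t.cds_start is None:
                thick_s = thick_e = t.start
            elif t.strand == "+":
                thick_s, thick_e = t.cds_start, t.end
            else:
                thick_s, thick_e = t.start, t.cds_start + 1
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t"
                     f"{t.strand}\t{thick_s}\t{thick_e}\n")
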