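"""Binned coverage statistics for CUT&RUN / RAP-style tracks.

Tracks are handled as fixed-width genomic bins (default 10 kb) tiling each
chromosome half-open, with the last bin possibly short.  Supported
statistics: per-chromosome mean enrichment, enrichment over a control
(IgG/input) track with a pseudocount, thresholded percent occupancy,
strand-aware TSS counts and meta-profiles, track correlation and
per-chromosome read percentages.  bedGraph (0-based half-open) is the
interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("xdamp.coverage")

__all__ = [
    "BinnedTrack",
    "bin_track",
    "read_bedgraph",
    "write_bedgraph",
    "mean_enrichment_per_chromosome",
    "enrichment_over_control",
    "percent_occupancy",
    "tss_counts",
    "tss_profile",
    "track_correlation",
    "percent_reads_per_chromosome",
]


@dataclass
class BinnedTrack:
    """Per-chromosome binned signal values.

    ``values[chrom][i]`` is the signal of bin [i*w, min((i+1)*w, L)); bins
    tile the chromosome without gaps.
    """

    bin_width: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    label: str = "target"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        for chrom, L in self.chrom_lengths.items():
            n = -(-L // self.bin_width)
            v = np.asarray(self.values.get(chrom, np.zeros(n)), dtype=float)
            if len(v) != n:
                raise ValueError(f"{chrom}: expected {n} bins, got {len(v)}")
            if not np.isfinite(v).all():
                raise ValueError(f"{chrom}: bin values must be finite")
            self.values[chrom] = v

    def bin_lengths(self, chrom: str) -> np.ndarray:
        L, w = self.chrom_lengths[chrom], self.bin_width
        n = -(-L // w)
        lens = np.full(n, w, dtype=float)
        if L % w:
            lens[-1] = L % w
        return lens

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chrom_lengths == other.chrom_lengths
        )


def bin_track(
    intervals: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_width: int = 10_000,
    label: str = "target",
) -> BinnedTrack:
    """Bin interval signal: each bin gets the length-weighted mean of the
    overlapping interval values, uncovered bases contributing 0."""
    values: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        n = -(-L // bin_width)
        acc = np.zeros(n)
        sub = intervals[intervals["chrom"] == chrom]
        for r in sub.itertuples():
            if not (0 <= r.start < r.end <= L):
                raise ValueError(f"interval {chrom}:{r.start}-{r.end} outside chromosome")
            b0, b1 = int(r.start // bin_width), int((r.end - 1) // bin_width)
            for b in range(b0, b1 + 1):
                lo = max(r.start, b * bin_width)
                hi = min(r.end, (b + 1) * bin_width, L)
                acc[b] += r.value * (hi - lo)
        lens = np.full(n, bin_width, dtype=float)
        if L % bin_width:
            lens[-1] = L % bin_width
        values[chrom] = acc / lens
    return BinnedTrack(bin_width=bin_width, chrom_lengths=dict(chrom_lengths), values=values, label=label)


def read_bedgraph(
    path: str | Path,
    chrom_lengths: dict[str, int],
    bin_width: int = 10_000,
    label: str = "target",
) -> BinnedTrack:
    """Read a bedGraph file and bin it.

    Intervals must be sorted within each chromosome, non-overlapping and
    within chromosome bounds (overlap would make the signal ambiguous).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    for chrom, sub in df.groupby("chrom"):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"{path}: intervals on {chrom} are not sorted")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
    return bin_track(df, chrom_lengths, bin_width, label=label)


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write a binned track as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            v = track.values[chrom]
            L, w = track.chrom_lengths[chrom], track.bin_width
            start = 0
            for i in range(len(v)):
                end = min((i + 1) * w, L)
                if i + 1 < len(v) and v[i + 1] == v[i]:
                    continue
                fh.write(f"{chrom}\t{start}\t{end}\t{v[i]:g}\n")
                start = end


def mean_enrichment_per_chromosome(track: BinnedTrack) -> dict[str, float]:
    """Mean bin value per chromosome."""
    return {c: float(np.mean(v)) for c, v in track.values.items()}


def enrichment_over_control(
    target: BinnedTrack,
    control: BinnedTrack,
    pseudocount: float = 0.01,
    log2: bool = False,
) -> BinnedTrack:
    """Per-bin (target + pc) / (control + pc), optionally log2."""
    if not target.same_grid(control):
        raise ValueError("target and control tracks are on different bin grids")
    values = {}
    for chrom in target.values:
        fc = (target.values[chrom] + pseudocount) / (control.values[chrom] + pseudocount)
        values[chrom] = np.log2(fc) if log2 else fc
    return BinnedTrack(
        bin_width=target.bin_width,
        chrom_lengths=dict(target.chrom_lengths),
        values=values,
        label="log2fc" if log2 else "fc",
    )


def percent_occupancy(fc_track: BinnedTrack, threshold: float) -> dict[str, float]:
    """Percent of each chromosome covered by bins at FC >= threshold.

    The threshold is inclusive ("minimum threshold" read as >=): the
    cumulative length of covered bins over the chromosome size, x100.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = {}
    for chrom, v in fc_track.values.items():
        lens = fc_track.bin_lengths(chrom)
        out[chrom] = 100.0 * float(lens[v >= threshold].sum()) / fc_track.chrom_lengths[chrom]
    return out


def _tss_positions(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware TSS (0-based): gene start on '+', gene end - 1 on '-'."""
    return pd.Series(
        np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1),
        index=genes["gene_id"],
    )


def _window_signal(track: BinnedTrack, chrom: str, lo: int, hi: int) -> float:
    """Sum of per-base signal over [lo, hi), clipped at chromosome edges."""
    L, w = track.chrom_lengths[chrom], track.bin_width
    lo, hi = max(lo, 0), min(hi, L)
    if hi <= lo:
        return 0.0
    v = track.values[chrom]
    b0, b1 = lo // w, (hi - 1) // w
    total = 0.0
    for b in range(b0, b1 + 1):
        s = max(lo, b * w)
        e = min(hi, (b + 1) * w, L)
        total += v[b] * (e - s)
    return total


def tss_counts(track: BinnedTrack, genes: pd.DataFrame, flank: int = 5000) -> pd.Series:
    """Per-gene summed signal in TSS +/- flank (strand-aware, edge-clipped)."""
    tss = _tss_positions(genes)
    out = {}
    for r in genes.itertuples():
        t = int(tss[r.gene_id])
        out[r.gene_id] = _window_signal(track, r.chrom, t - flank, t + flank + 1)
    return pd.Series(out, name="tss_counts")


def tss_profile(
    track: BinnedTrack, genes: pd.DataFrame, flank: int = 5000, step: int | None = None
) -> pd.DataFrame:
    """Meta-profile of mean signal per offset around TSSs.

    Minus-strand genes are reversed so upstream is on the left.  Offsets
    outside the chromosome are excluded from the mean for that gene.
    """
    step = step or track.bin_width
    offsets = np.arange(-flank, flank + 1, step)
    tss = _tss_positions(genes)
    acc = np.zeros(len(offsets))
    cnt = np.zeros(len(offsets))
    for r in genes.itertuples():
        t = int(tss[r.gene_id])
        L = track.chrom_lengths[r.chrom]
        v = track.values[r.chrom]
        sign = 1 if r.strand == "+" else -1
        for i, off in enumerate(offsets):
            pos = t + sign * int(off)
            if 0 <= pos < L:
                acc[i] += v[pos // track.bin_width]
                cnt[i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_signal": mean, "n_genes": cnt.astype(int)})


def track_correlation(a: BinnedTrack, b: BinnedTrack, method: str = "pearson") -> float:
    """Pearson or Spearman correlation over all shared bins."""
    if not a.same_grid(b):
        raise ValueError("tracks are on different bin grids")
    x = np.concatenate([a.values[c] for c in sorted(a.values)])
    y = np.concatenate([b.values[c] for c in sorted(b.values)])
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def percent_reads_per_chromosome(read_assignments) -> dict[str, float]:
    """Percent of reads per chromosome (sums to 100).

    ``read_assignments`` is either an iterable of chromosome names (one
    per read) or a mapping chromosome -> read count.
    """
    if isinstance(read_assignments, dict):
        counts = pd.Series(read_assignments, dtype=float)
    else:
        counts = pd.Series(list(read_assignments)).value_counts().astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no reads to assign")
    return (100.0 * counts / total).to_dict()
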