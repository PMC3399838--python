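"""Genome partitioning into bins and unweighted bin-average covariates.

Bins are half-open intervals [start, start + size) anchored at position 0 on
each chromosome; the final interval is truncated at the chromosome end, and a
marker sitting exactly on the chromosome end belongs to the last bin.  Every
marker therefore belongs to exactly one bin (the tiling invariant), and
refining the bin size regroups markers without gaining or losing any.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MarkerMap
from .simulate import f2_covariance

__all__ = [
    "BinPartition",
    "BinFeatureMatrix",
    "make_bins",
    "bin_average",
    "theoretical_bin_variance",
]

UNITS = ("cM", "bp", "markers", "log10_bp")


@dataclass(frozen=True)
class BinPartition:
    """The genome cut into m intervals, each owning a contiguous marker range."""

    unit: str
    bin_size: float
    chromosome: np.ndarray       # per bin
    start: np.ndarray
    end: np.ndarray
    first_marker: np.ndarray     # -1 for empty bins
    last_marker: np.ndarray      # inclusive; -1 for empty bins
    p_k: np.ndarray              # markers per bin
    marker_bin: np.ndarray       # per-marker bin index (length p)

    @property
    def m(self) -> int:
        return len(self.p_k)

    @property
    def n_markers(self) -> int:
        return len(self.marker_bin)

    @property
    def empty(self) -> np.ndarray:
        """Boolean mask of bins containing no marker (kept for stable indexing,
        excluded from fitting)."""
        return self.p_k == 0

    def to_frame(self) -> pd.DataFrame:
        """BED-like table: chromosome, start, end, p_k."""
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "start": self.start,
                "end": self.end,
                "first_marker": self.first_marker,
                "last_marker": self.last_marker,
                "p_k": self.p_k,
            }
        )


@dataclass
class BinFeatureMatrix:
    """n x m bin covariates: unweighted averages or adaptive weighted scores."""

    values: np.ndarray
    partition: BinPartition
    mode: str  # "unweighted" | "adaptive"

    def __post_init__(self):
        if self.values.shape[1] != self.partition.m:
            raise ValueError("column count does not match partition")
        if self.mode not in ("unweighted", "adaptive"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def design_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """(matrix restricted to nonempty bins, their bin indices)."""
        keep = np.flatnonzero(~self.partition.empty)
        return self.values[:, keep], keep


def make_bins(mmap: MarkerMap, bin_size: float, unit: str = "cM") -> BinPartition:
    """Partition each chromosome into bins of ``bin_size`` in ``unit``.

    Units: 'cM' (genetic), 'bp' (physical), 'log10_bp' (bin width 10**bin_size
    base pairs on the physical map), 'markers' (fixed marker count per bin).
    Empty bins are retained in the partition but flagged.
    """
    if unit not in UNITS:
        raise ValueError(f"unit must be one of {UNITS}")
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")

    if unit == "markers":
        return _make_marker_count_bins(mmap, int(bin_size))

    if unit == "cM":
        pos = mmap.positions("cM")
        width = float(bin_size)
    else:  # bp or log10_bp both partition the physical map
        pos = mmap.positions("bp")
        width = float(10.0 ** bin_size) if unit == "log10_bp" else float(bin_size)

    chroms, starts, ends = [], [], []
    first, last, counts, marker_bin = [], [], [], np.empty(mmap.n_markers, int)
    offset = 0
    for c, sl in mmap.chromosome_slices().items():
        cpos = pos[sl]
        chrom_end = float(cpos[-1])
        n_bins = max(1, int(np.ceil(chrom_end / width))) if chrom_end > 0 else 1
        idx = np.minimum((cpos // width).astype(int), n_bins - 1)
        marker_bin[sl] = idx + offset
        cnt = np.bincount(idx, minlength=n_bins)
        # markers are map-sorted, so each bin's range is contiguous
        cum = np.concatenate([[0], np.cumsum(cnt)])
        for k in range(n_bins):
            chroms.append(c)
            starts.append(k * width)
            ends.append(min((k + 1) * width, chrom_end))
            if cnt[k]:
                first.append(sl.start + cum[k])
                last.append(sl.start + cum[k + 1] - 1)
            else:
                first.append(-1)
                last.append(-1)
            counts.append(int(cnt[k]))
        offset += n_bins
    size = float(bin_size) if unit != "log10_bp" else width
    return BinPartition(
        unit=unit, bin_size=size,
        chromosome=np.array(chroms, dtype=object),
        start=np.array(starts, float), end=np.array(ends, float),
        first_marker=np.array(first, int), last_marker=np.array(last, int),
        p_k=np.array(counts, int), marker_bin=marker_bin,
    )


def _make_marker_count_bins(mmap: MarkerMap, per_bin: int) -> BinPartition:
    pos = (
        mmap.genetic_pos if mmap.genetic_pos is not None else mmap.physical_pos
    )
    chroms, starts, ends = [], [], []
    first, last, counts = [], [], []
    marker_bin = np.empty(mmap.n_markers, int)
    offset = 0
    for c, sl in mmap.chromosome_slices().items():
        n = sl.stop - sl.start
        n_bins = int(np.ceil(n / per_bin))
        for k in range(n_bins):
            lo = sl.start + k * per_bin
            hi = min(sl.start + (k + 1) * per_bin, sl.stop)
            marker_bin[lo:hi] = offset + k
            chroms.append(c)
            starts.append(float(pos[lo]))
            ends.append(float(pos[hi - 1]))
            first.append(lo)
            last.append(hi - 1)
            counts.append(hi - lo)
        offset += n_bins
    return BinPartition(
        unit="markers", bin_size=float(per_bin),
        chromosome=np.array(chroms, dtype=object),
        start=np.array(starts, float), end=np.array(ends, float),
        first_marker=np.array(first, int), last_marker=np.array(last, int),
        p_k=np.array(counts, int), marker_bin=marker_bin,
    )


def bin_average(G: GenotypeMatrix, part: BinPartition) -> BinFeatureMatrix:
    """Unweighted bin covariates: entry (j, k) = mean of Z_jhk over the p_k
    markers of bin k.  Empty bins yield all-zero columns (flagged)."""
    return _bin_aggregate(G.values, part, None)


def _bin_aggregate(
    V: np.ndarray, part: BinPartition, weights: np.ndarray | None
) -> BinFeatureMatrix:
    if V.shape[1] != part.n_markers:
        raise ValueError("genotype column count does not match partition")
    X = V if weights is None else V * weights[None, :]
    out = np.zeros((V.shape[0], part.m))
    nonempty = np.flatnonzero(~part.empty)
    if nonempty.size:
        # contiguous marker ranges allow a single segmented reduction
        seg_starts = part.first_marker[nonempty]
        sums = np.add.reduceat(X, seg_starts, axis=1)
        out[:, nonempty] = sums / part.p_k[nonempty][None, :]
    mode = "unweighted" if weights is None else "adaptive"
    return BinFeatureMatrix(out, part, mode)


def theoretical_bin_variance(positions_cM) -> float:
    """Variance across F2 individuals of the bin-average genotype indicator.

    For p markers at the given cM positions within one bin,
    Var(Zbar) = (1/p^2) [ p/2 + 2 sum_{h<l} (1 - 2 r_hl)/2 ]
    with r_hl the Haldane recombination fraction.  Equals 1/2 under complete
    linkage (all positions identical) and decays toward 1/(2p) as the markers
    become unlinked.
    """
    pos = np.asarray(positions_cM, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one marker position")
    C = f2_covariance(np.abs(pos[:, None] - pos[None, :]))
    return float(C.sum() / pos.size**2)
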