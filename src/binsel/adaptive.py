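"""Adaptive infinitesimal model: marker scan, signed weights, weighted scores.

In low-LD populations the unweighted bin average cancels marker effects of
opposite sign.  The adaptive model first runs a single-marker least-squares
scan, then weights each marker by its estimate relative to the mean absolute
estimate in its bin, w_hk = b_hk / mean_h |b_hk|, so that within-bin effects
are homogenized (aligned in sign and magnitude).  The weighted average
S_jk = (1/p_k) sum_h w_hk Z_jhk replaces the plain bin average as the
covariate.  Because the weights are estimated from the data, the model is
"adaptive"; by default they are re-estimated inside each training fold during
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinFeatureMatrix, BinPartition, _bin_aggregate
from .data import GenotypeMatrix, PhenotypeVector

__all__ = [
    "MarkerScan",
    "WeightSet",
    "single_marker_scan",
    "compute_weights",
    "weighted_bin_score",
]

LOD_PER_WALD = 1.0 / (2.0 * np.log(10.0))
_ZERO_TOL = 1e-12


@dataclass
class MarkerScan:
    """Per-marker simple-regression results: estimate, standard error, LOD."""

    beta: np.ndarray
    se: np.ndarray
    lod: np.ndarray
    zero_variance: np.ndarray  # flagged markers with no genotype variation

    def __len__(self) -> int:
        return len(self.beta)


@dataclass
class WeightSet:
    """Signed per-marker weights; within every nonempty bin with signal,
    mean |w| = 1 (equivalently sum |w| = p_k)."""

    weights: np.ndarray
    bin_mean_abs: np.ndarray     # mean |b| per bin (Eq-style normalizer)
    partition: BinPartition

    def to_frame(self, mmap=None, scan: MarkerScan | None = None) -> pd.DataFrame:
        d = {"bin": self.partition.marker_bin, "weight": self.weights}
        if scan is not None:
            d["beta"] = scan.beta
        df = pd.DataFrame(d)
        if mmap is not None:
            df.insert(0, "marker_id", mmap.marker_id)
        return df


def single_marker_scan(G: GenotypeMatrix, y: PhenotypeVector) -> MarkerScan:
    """Least-squares simple regression y = mu + b Z_h + e for every marker.

    Vectorized over markers; genotypes must be missing-free (impute first).
    Zero-variance columns get b = 0 and are flagged.  The LOD score is the
    marker Wald statistic b^2 / se(b)^2 divided by 2 ln 10.
    """
    Z = G.values
    if np.isnan(Z).any():
        raise ValueError("scan requires missing-free genotypes; impute first")
    yv = y.values
    n = len(yv)
    if Z.shape[0] != n:
        raise ValueError("genotype/phenotype length mismatch")
    yc = yv - yv.mean()
    Zc = Z - Z.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", Zc, Zc)
    sxy = yc @ Zc
    syy = float(yc @ yc)
    zero = sxx <= _ZERO_TOL * n
    sxx_safe = np.where(zero, 1.0, sxx)
    beta = np.where(zero, 0.0, sxy / sxx_safe)
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    dof = max(n - 2, 1)
    s2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(zero, np.inf, s2 / sxx_safe))
        wald = np.where(zero, 0.0, beta**2 / np.maximum(se, _ZERO_TOL) ** 2)
    lod = wald * LOD_PER_WALD
    return MarkerScan(beta=beta, se=se, lod=lod, zero_variance=zero)


def compute_weights(scan: MarkerScan, part: BinPartition) -> WeightSet:
    """w_hk = b_hk / mean_h |b_hk| within bin k (signed).

    Bins whose mean absolute estimate is below 1e-12 (degenerate null bins)
    get all-zero weights rather than dividing by ~0.
    """
    if len(scan) != part.n_markers:
        raise ValueError("scan length does not match partition")
    absb = np.abs(scan.beta)
    sums = np.bincount(part.marker_bin, weights=absb, minlength=part.m)
    mean_abs = np.zeros(part.m)
    nonempty = part.p_k > 0
    mean_abs[nonempty] = sums[nonempty] / part.p_k[nonempty]
    denom = mean_abs[part.marker_bin]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > _ZERO_TOL, scan.beta / np.where(denom > 0, denom, 1.0), 0.0)
    return WeightSet(weights=w, bin_mean_abs=mean_abs, partition=part)


def weighted_bin_score(
    G: GenotypeMatrix, part: BinPartition, w: WeightSet
) -> BinFeatureMatrix:
    """Adaptive covariates: entry (j, k) = (1/p_k) sum_h w_hk Z_jhk.

    With all weights equal to 1 this reduces exactly to the unweighted bin
    average, and per-marker sign flips of the genotype coding (which flip the
    scan estimates and hence the weights) leave the scores invariant.
    """
    if w.partition is not part and w.partition.m != part.m:
        raise ValueError("weight set built on a different partition")
    return _bin_aggregate(G.values, part, w.weights)
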