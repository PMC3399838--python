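"""Pre-analysis quality control: MAF filtering, covariate pre-adjustment and
marker-mean imputation of missing genotypes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import CovariateTable, GenotypeMatrix, MarkerMap, PhenotypeVector

__all__ = ["filter_maf", "adjust_covariates", "impute_missing", "MafReport"]

logger = logging.getLogger(__name__)


@dataclass
class MafReport:
    threshold: float
    maf: np.ndarray                       # per input marker, NaN if no calls
    removed_ids: list = field(default_factory=list)
    zero_call_ids: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def filter_maf(
    G: GenotypeMatrix, mmap: MarkerMap, threshold: float = 0.05
) -> tuple[GenotypeMatrix, MarkerMap, MafReport]:
    """Remove markers with minor allele frequency below ``threshold``.

    The allele frequency of each marker is computed from non-missing calls as
    f = (2*count(+1) + count(0)) / (2*n_nonmissing), i.e. the frequency of the
    allele coded +1; MAF = min(f, 1-f).  Markers with no non-missing calls are
    removed and flagged separately.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    V = G.values
    nonmiss = ~np.isnan(V)
    n_calls = nonmiss.sum(axis=0)
    n_plus = np.nansum(V == 1, axis=0)
    n_het = np.nansum(V == 0, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (2.0 * n_plus + n_het) / (2.0 * n_calls)
    maf = np.minimum(f, 1.0 - f)
    zero_call = n_calls == 0
    keep = ~zero_call & (maf >= threshold)
    report = MafReport(
        threshold=threshold,
        maf=np.where(zero_call, np.nan, maf),
        removed_ids=list(mmap.marker_id[~keep]),
        zero_call_ids=list(mmap.marker_id[zero_call]),
    )
    if keep.sum() == 0:
        raise ValueError("MAF filter removed every marker")
    G2 = GenotypeMatrix(V[:, keep], G.individual_ids)
    return G2, mmap.subset(keep), report


def adjust_covariates(y: PhenotypeVector, X: CovariateTable) -> PhenotypeVector:
    """Pre-adjust the trait for fixed effects by OLS; return the residuals.

    Categorical covariates are treatment-coded with an intercept.  Aliased
    (rank-deficient) columns are dropped with a warning rather than raising;
    the residuals are orthogonal to every retained column and have zero mean.
    """
    if len(y) != len(X):
        raise ValueError("phenotype and covariate table lengths differ")
    D, names = X.design_matrix()
    # drop aliased columns via pivoted QR-style rank detection
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    tol = max(D.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        # greedy: keep columns that increase rank
        keep, rank = [], 0
        for j in range(D.shape[1]):
            cand = D[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > rank:
                keep.append(j)
                rank += 1
        dropped = [names[j] for j in range(D.shape[1]) if j not in keep]
        logger.warning("dropping aliased covariate columns: %s", dropped)
        D = D[:, keep]
    beta, *_ = np.linalg.lstsq(D, y.values, rcond=None)
    resid = y.values - D @ beta
    return PhenotypeVector(resid, y.individual_ids, adjusted=True)


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its marker's non-missing mean.

    The fill value is a real number in [-1, 1]; column means are preserved.
    Markers with no non-missing calls violate the precondition (filter them
    first) and raise.
    """
    V = G.values
    miss = np.isnan(V)
    if not miss.any():
        return G
    n_calls = (~miss).sum(axis=0)
    if np.any(n_calls == 0):
        raise ValueError(
            "marker(s) with zero non-missing calls; run filter_maf first"
        )
    col_mean = np.nansum(V, axis=0) / n_calls
    out = np.where(miss, col_mean[None, :], V)
    return GenotypeMatrix(out, G.individual_ids, imputed=True)
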