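"""Out-of-sample evaluation: k-fold CV, predictability R2, bin-size scans.

Predictability is measured by the mean squared error of 10-fold
cross-validation, MSE = (1/n) sum_j (y_j - yhat_j)^2 with yhat_j predicted
from a model whose every data-dependent step (marker scan, weights, bin
scores, penalty selection, fit) was run on the folds excluding j, and by
R2 = 1 - MSE / var(y): the proportion of phenotypic variance the model
predicts out of sample.  MSE >= var(y) means no predictability (clipped R2
of 0).

``scan_bin_sizes`` repeats the CV over a grid of bin sizes and modes on a
shared fold partition, so that MSE differences between entries are paired;
the minimum-MSE entry locates the optimal bin size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .adaptive import compute_weights, single_marker_scan, weighted_bin_score
from .binning import bin_average, make_bins
from .data import GenotypeMatrix, MarkerMap, PhenotypeVector
from .fit import FitResult, fit_bins, select_lambda

__all__ = [
    "Predictability",
    "predictability",
    "CVResult",
    "kfold_cv",
    "make_folds",
    "BinModelBuilder",
    "BinSizeProfile",
    "scan_bin_sizes",
]


class Predictability(NamedTuple):
    r2: float
    r2_clipped: float


def predictability(mse: float, var_y: float) -> Predictability:
    """R2 = 1 - MSE/var(y), plus the value clipped at zero (MSE at or above
    the phenotypic variance counts as no predictability)."""
    if var_y <= 0:
        raise ValueError("phenotypic variance must be > 0")
    r2 = 1.0 - mse / var_y
    return Predictability(r2, max(0.0, r2))


@dataclass
class CVResult:
    """One cross-validation run: fold assignment, out-of-fold predictions,
    MSE and predictability."""

    fold: np.ndarray                  # fold index per individual
    predictions: np.ndarray
    mse: float
    var_y: float
    r2: float
    r2_clipped: float
    seed: int
    fold_mse: np.ndarray = field(default=None, repr=False)
    fold_models: list = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return int(self.fold.max()) + 1

    @property
    def mse_se(self) -> float:
        """Standard error of the MSE across folds."""
        return float(np.std(self.fold_mse, ddof=1) / np.sqrt(len(self.fold_mse)))


def make_folds(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Seeded balanced fold assignment: sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(perm, k)):
        if len(chunk) < 2:
            raise ValueError(f"fold {i} has fewer than 2 individuals")
        fold[chunk] = i
    return fold


def kfold_cv(
    builder: Callable,
    G: GenotypeMatrix,
    mmap: MarkerMap,
    y: PhenotypeVector,
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
    keep_models: bool = False,
) -> CVResult:
    """k-fold cross-validation of a covariate-construction + fit pipeline.

    ``builder(G_train, mmap, y_train)`` must return a fitted object with a
    ``predict(G_test, mmap)`` method; it encapsulates the full pipeline so
    every data-dependent step runs inside the training folds.  If the builder
    has a ``setup_full`` method it is called once with the complete dataset
    before the folds run (used for deliberate whole-data weighting or penalty
    pre-tuning; see the builder docs).
    """
    n = G.n_individuals
    yv = y.values
    if folds is None:
        folds = make_folds(n, k, seed)
    if hasattr(builder, "setup_full"):
        builder.setup_full(G, mmap, y)
    yhat = np.empty(n)
    fold_mse = []
    models = [] if keep_models else None
    for f in range(int(folds.max()) + 1):
        test = folds == f
        train = ~test
        Gtr = GenotypeMatrix(
            G.values[train], G.individual_ids[train], imputed=G.imputed
        )
        Gte = GenotypeMatrix(
            G.values[test], G.individual_ids[test], imputed=G.imputed
        )
        ytr = PhenotypeVector(yv[train], adjusted=y.adjusted)
        model = builder(Gtr, mmap, ytr)
        yhat[test] = model.predict(Gte, mmap)
        fold_mse.append(float(np.mean((yv[test] - yhat[test]) ** 2)))
        if keep_models:
            models.append(model)
    mse = float(np.mean((yv - yhat) ** 2))
    var_y = y.variance
    r2, r2c = predictability(mse, var_y)
    return CVResult(
        fold=folds, predictions=yhat, mse=mse, var_y=var_y,
        r2=r2, r2_clipped=r2c, seed=seed,
        fold_mse=np.array(fold_mse), fold_models=models,
    )


@dataclass
class _FittedBinModel:
    partition_args: tuple              # (bin_size, unit)
    mode: str
    weights: object                    # WeightSet or None
    fit: FitResult

    def predict(self, G: GenotypeMatrix, mmap: MarkerMap) -> np.ndarray:
        part = make_bins(mmap, *self.partition_args)
        if self.mode == "unweighted":
            B = bin_average(G, part)
        else:
            B = weighted_bin_score(G, part, self.weights)
        return self.fit.predict(B)


class BinModelBuilder:
    """Pipeline builder for one (bin size, mode) combination.

    mode:     'unweighted' (plain bin averages) or 'adaptive' (scan-weighted
              scores).
    weights:  'fold' re-estimates the adaptive weights inside each training
              fold (default, leakage-free); 'whole-data' estimates them once
              from the full sample, reproducing the penalized-regression
              workflow in which the preliminary marker scan precedes the
              cross-validation.
    lam:      a number (fixed penalty), 'cv' (selected inside each training
              fold), or 'pretune' (selected once on the full sample, then held
              fixed — the predetermined-lambda workflow).
    """

    def __init__(
        self,
        bin_size: float,
        unit: str = "cM",
        mode: str = "unweighted",
        lam: float | str = "pretune",
        weights: str = "fold",
        cv_folds: int = 10,
        seed: int = 0,
        n_lambda: int = 50,
    ):
        if mode not in ("unweighted", "adaptive"):
            raise ValueError(f"unknown mode {mode!r}")
        if weights not in ("fold", "whole-data"):
            raise ValueError(f"unknown weights policy {weights!r}")
        self.bin_size = bin_size
        self.unit = unit
        self.mode = mode
        self.lam = lam
        self.weights_policy = weights
        self.cv_folds = cv_folds
        self.seed = seed
        self.n_lambda = n_lambda
        self._full_weights = None
        self._pretuned_lam = None

    # -- full-data preparation (only for the deliberately non-nested options)
    def setup_full(self, G, mmap, y):
        if self.weights_policy == "whole-data" and self.mode == "adaptive":
            part = make_bins(mmap, self.bin_size, self.unit)
            self._full_weights = compute_weights(
                single_marker_scan(G, y), part
            )
        if self.lam == "pretune":
            B = self._features(G, mmap, y, self._full_weights)
            X, _ = B.design_columns()
            X = X[:, X.std(axis=0) > 0]
            self._pretuned_lam = select_lambda(
                X, y.values, folds=self.cv_folds, seed=self.seed,
                n_lambda=self.n_lambda,
            )

    def _features(self, G, mmap, y, wset):
        part = make_bins(mmap, self.bin_size, self.unit)
        if self.mode == "unweighted":
            return bin_average(G, part)
        if wset is None:
            wset = compute_weights(single_marker_scan(G, y), part)
        return weighted_bin_score(G, part, wset)

    def __call__(self, G, mmap, y) -> _FittedBinModel:
        wset = self._full_weights if self.weights_policy == "whole-data" else None
        part = make_bins(mmap, self.bin_size, self.unit)
        if self.mode == "adaptive" and wset is None:
            wset = compute_weights(single_marker_scan(G, y), part)
        if self.mode == "unweighted":
            B = bin_average(G, part)
        else:
            B = weighted_bin_score(G, part, wset)
        lam = self.lam
        if lam == "pretune":
            if self._pretuned_lam is None:
                raise RuntimeError("pretune requires setup_full before fitting")
            lam = self._pretuned_lam
        fit = fit_bins(
            B, y, lam=lam, cv_folds=self.cv_folds, cv_seed=self.seed,
            n_lambda=self.n_lambda,
        )
        return _FittedBinModel(
            partition_args=(self.bin_size, self.unit),
            mode=self.mode, weights=wset, fit=fit,
        )


@dataclass
class BinSizeProfile:
    """MSE/R2 of every (bin size, mode) combination on shared folds."""

    entries: list                      # dicts: size, unit, mode, m, cv
    unit: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            cv = e["cv"]
            rows.append(
                {
                    "bin_size": e["size"],
                    "unit": self.unit,
                    "mode": e["mode"],
                    "m": e["m"],
                    "mse": cv.mse,
                    "mse_se": cv.mse_se,
                    "r2": cv.r2,
                    "r2_clipped": cv.r2_clipped,
                }
            )
        return pd.DataFrame(rows)

    def best(self, mode: str | None = None) -> dict:
        """Minimum-MSE entry (optionally within one mode), with the one-SE
        band of its fold-wise MSE."""
        cand = [
            e for e in self.entries if mode is None or e["mode"] == mode
        ]
        e = min(cand, key=lambda e: e["cv"].mse)
        return {
            "size": e["size"], "mode": e["mode"], "m": e["m"],
            "mse": e["cv"].mse, "mse_se": e["cv"].mse_se,
            "r2": e["cv"].r2, "r2_clipped": e["cv"].r2_clipped,
        }


def scan_bin_sizes(
    G: GenotypeMatrix,
    mmap: MarkerMap,
    y: PhenotypeVector,
    sizes,
    unit: str = "cM",
    modes=("unweighted", "adaptive"),
    k: int = 10,
    seed: int = 0,
    lam: float | str = "pretune",
    weights: str = "fold",
    cv_folds_inner: int = 10,
    n_lambda: int = 50,
) -> BinSizeProfile:
    """Cross-validate every (bin size, mode) pair on one shared fold split."""
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be nonempty")
    folds = make_folds(G.n_individuals, k, seed)
    entries = []
    for size in sizes:
        part_m = int((make_bins(mmap, size, unit).p_k > 0).sum())
        for mode in modes:
            builder = BinModelBuilder(
                size, unit=unit, mode=mode, lam=lam, weights=weights,
                cv_folds=cv_folds_inner, seed=seed, n_lambda=n_lambda,
            )
            cv = kfold_cv(builder, G, mmap, y, k=k, seed=seed, folds=folds)
            entries.append({"size": size, "mode": mode, "m": part_m, "cv": cv})
    return BinSizeProfile(entries=entries, unit=unit, seed=seed)
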