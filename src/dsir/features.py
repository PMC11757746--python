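"""Univariate feature scoring and n-best selection.

Every wavenumber is scored by the Pearson correlation rho_i between its
column and the reference DS across samples, converted to the F-statistic

    F_i = rho_i^2 / (1 - rho_i^2) * (S - 2)

which is monotone in |rho_i| and therefore ranks strong negative correlations
as highly as positive ones.  Selecting the n largest F values keeps only the
wavenumbers most linearly related to DS, which reduces overfitting when the
number of samples is far below the number of wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedCorrelationError, ValidationError
from .io import DSVector, SpectraSet

__all__ = [
    "FeatureScores",
    "pearson_per_feature",
    "f_statistic",
    "score_features",
    "select_n_best",
    "sweep_n",
]


@dataclass
class FeatureScores:
    """Per-wavenumber Pearson rho and F values for one training set."""

    rho: np.ndarray
    f: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.rho.shape != self.f.shape:
            raise ValidationError("rho and f must have equal length")


def pearson_per_feature(T: SpectraSet, D: DSVector) -> np.ndarray:
    """Sample Pearson correlation of every wavenumber column with DS.

    Constant columns get rho = 0 by convention (zero variance carries no DS
    information); values are clamped to [-1, 1] against floating-point spill.
    """
    if len(D) != T.n_samples:
        raise ValidationError("spectra and DS vector lengths differ")
    S = T.n_samples
    if S < 3:
        raise ValidationError(f"need at least 3 samples for correlation, got {S}")
    d = D.values - D.values.mean()
    sd_d = np.sqrt(np.sum(d**2) / (S - 1))
    if sd_d == 0:
        raise UndefinedCorrelationError("reference DS values are constant")
    X = T.matrix - T.matrix.mean(axis=0, keepdims=True)
    sd_x = np.sqrt(np.sum(X**2, axis=0) / (S - 1))
    cov = X.T @ d / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = cov / (sd_x * sd_d)
    rho[sd_x == 0] = 0.0
    return np.clip(rho, -1.0, 1.0)


def f_statistic(rho, S: int) -> np.ndarray:
    """F = rho^2 / (1 - rho^2) * (S - 2); |rho| = 1 maps to +inf (ranks first)."""
    if S < 3:
        raise ValidationError(f"F-statistic needs S >= 3 samples, got {S}")
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1):
        raise ValidationError("correlations must lie in [-1, 1]")
    r2 = rho**2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = r2 / (1.0 - r2) * (S - 2)
    f[r2 == 1.0] = np.inf
    return f


def score_features(T: SpectraSet, D: DSVector) -> FeatureScores:
    rho = pearson_per_feature(T, D)
    return FeatureScores(rho=rho, f=f_statistic(rho, T.n_samples), n_samples=T.n_samples)


def select_n_best(scores: FeatureScores, n: int) -> np.ndarray:
    """Indices of the n largest F values, in ascending wavenumber order.

    Ties in F are broken toward the smaller index, so the result is
    deterministic.
    """
    m = scores.f.size
    if not 1 <= n <= m:
        raise ValidationError(f"n must be in [1, {m}], got {n}")
    # stable sort on -F keeps the smaller index first among ties
    order = np.argsort(-scores.f, kind="stable")
    return np.sort(order[:n])


def sweep_n(
    T: SpectraSet,
    D: DSVector,
    cv,
    n_grid: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-CV error as a function of the number of selected features.

    For each n the repeated k-fold of the validation module is run with
    feature selection refitted inside every training fold (or per ``cv``'s
    selection_scope).  Returns a long-format table of fold MAEs and a summary
    with box statistics per n; the summary's ``is_optimum`` column marks the
    argmin of the mean fold MAE.
    """
    from dataclasses import replace

    from .validation import box_stats, repeated_kfold

    if n_grid is None:
        n_grid = [n for n in range(50, 1751, 100) if n <= T.n_features]
        if T.n_features not in n_grid:
            n_grid = list(n_grid) + [T.n_features]
    n_grid = [int(n) for n in n_grid]
    for n in n_grid:
        if not 1 <= n <= T.n_features:
            raise ValidationError(f"n={n} outside [1, {T.n_features}]")

    long_rows = []
    summaries = []
    for n in n_grid:
        scope = cv.selection_scope if cv.selection_scope != "none" else "per_fold"
        cfg = replace(cv, n_best=n, selection_scope=scope)
        res = repeated_kfold(T, D, cfg)
        fold = res.fold_metrics.assign(n=n)
        long_rows.append(fold)
        bs = box_stats(fold["mae"].to_numpy())
        summaries.append(
            {
                "n": n,
                "mean_mae": fold["mae"].mean(),
                "median_mae": bs.median,
                "q1": bs.q1,
                "q3": bs.q3,
                "whisker_low": bs.whisker_low,
                "whisker_high": bs.whisker_high,
                "n_outliers": len(bs.outliers),
            }
        )
    long_df = pd.concat(long_rows, ignore_index=True)
    summary = pd.DataFrame(summaries)
    summary["is_optimum"] = summary["mean_mae"] == summary["mean_mae"].min()
    return long_df, summary
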