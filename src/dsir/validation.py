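"""Quality metrics and the repeated k-fold cross-validation engine.

Accuracy is quantified by the mean absolute error (MAE, in DS units) and the
mean relative error (MRE, reported in percent).  Because a single random
test/train split of a 16-sample calibration set is dominated by chance, the
k-fold CV is repeated N times with reshuffled fold assignment; per-fold,
per-repetition and pooled errors are all recorded.

Seed schedule: repetition r shuffles the sample indices with a fresh
``numpy.random.default_rng(base_seed + r)``, so the whole CVResult is
bit-reproducible from one integer and any single repetition can be re-run in
isolation.  Fold sizes differ by at most one when k does not divide S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DivisionDomainError, ValidationError
from .features import score_features, select_n_best
from .io import DSVector, SpectraSet
from .model import fit_mlr, predict
from .preprocess import RegionMask, apply_mask, parse_region

__all__ = [
    "CVConfig",
    "CVResult",
    "BoxStats",
    "mae",
    "mre",
    "repeated_kfold",
    "aggregate_predictions",
    "box_stats",
    "sweep_k",
]


def _as_array(v) -> np.ndarray:
    if isinstance(v, DSVector):
        return v.values
    return np.asarray(v, dtype=float)


def mae(eval_values, ref_values) -> float:
    """Mean absolute error (1/S) * sum |eval_i - ref_i|, in DS units."""
    e, r = _as_array(eval_values), _as_array(ref_values)
    if e.size != r.size or e.size == 0:
        raise ValidationError(f"length mismatch or empty: {e.size} vs {r.size}")
    return float(np.mean(np.abs(e - r)))


def mre(eval_values, ref_values) -> float:
    """Mean relative error (1/S) * sum |eval_i - ref_i| / ref_i, in percent."""
    e, r = _as_array(eval_values), _as_array(ref_values)
    if e.size != r.size or e.size == 0:
        raise ValidationError(f"length mismatch or empty: {e.size} vs {r.size}")
    if np.any(r == 0):
        raise DivisionDomainError("MRE undefined: reference contains a zero DS value")
    return float(np.mean(np.abs(e - r) / r) * 100.0)


def _fold_mre_or_nan(pred, ref) -> float:
    """Fold MRE; NaN when the fold's reference contains a zero (documented)."""
    ref = np.asarray(ref, dtype=float)
    if np.any(ref == 0):
        return float("nan")
    return mre(pred, ref)


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold configuration.

    ``selection_scope``: ``none`` (no feature selection), ``per_fold``
    (scores computed on each training partition only — leakage-free default
    when ``n_best`` is set) or ``global`` (scores computed once on all data,
    the leaky alternative reading, kept for comparison).
    """

    k: int = 8
    n_repeats: int = 1000
    base_seed: int = 0
    selection_scope: str = "none"
    n_best: int | None = None
    region: str | RegionMask | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError(f"k must be >= 2, got {self.k}")
        if self.n_repeats < 1:
            raise ConfigurationError(f"N must be >= 1, got {self.n_repeats}")
        if self.selection_scope not in {"none", "per_fold", "global"}:
            raise ConfigurationError(
                f"selection_scope must be none|per_fold|global, got {self.selection_scope!r}"
            )
        if self.selection_scope != "none" and self.n_best is None:
            raise ConfigurationError("selection_scope set but n_best is None")


@dataclass
class CVResult:
    """Everything a repeated k-fold run produced.

    ``predictions``: one row per (repetition, fold, test sample);
    ``fold_metrics``: MAE/MRE per (repetition, fold);
    ``repetition_metrics``: MAE/MRE on predictions pooled within a repetition;
    ``overall_mae``/``overall_mre``: pooled over every test prediction made.
    """

    config: CVConfig
    predictions: pd.DataFrame
    fold_metrics: pd.DataFrame
    repetition_metrics: pd.DataFrame
    overall_mae: float
    overall_mre: float
    sample_ids: list[str] = field(default_factory=list)


def _fold_indices(rng: np.random.Generator, n: int, k: int) -> list[np.ndarray]:
    """Shuffle 0..n-1 and split into k folds with sizes differing by <= 1."""
    perm = rng.permutation(n)
    return np.array_split(perm, k)


def repeated_kfold(T: SpectraSet, D: DSVector, cfg: CVConfig) -> CVResult:
    """Run the repeated k-fold CV and record every test prediction.

    Within each repetition the test folds partition the sample set, so each
    sample is predicted exactly ``n_repeats`` times in total.  Feature
    selection, when requested per fold, sees only the training partition.
    """
    if not T.normalized:
        raise ValidationError("repeated_kfold expects normalized spectra")
    if len(D) != T.n_samples:
        raise ValidationError("spectra and DS vector lengths differ")
    S = T.n_samples
    if cfg.k > S:
        raise ConfigurationError(f"k={cfg.k} exceeds the {S} available samples")

    if cfg.region is not None:
        mask = cfg.region if isinstance(cfg.region, RegionMask) else parse_region(cfg.region)
        T = apply_mask(T, mask)

    M = T.n_features
    if cfg.selection_scope != "none":
        if not 1 <= cfg.n_best <= M:
            raise ValidationError(
                f"n_best={cfg.n_best} outside [1, {M}] for this grid/region"
            )

    global_idx = None
    if cfg.selection_scope == "global":
        global_idx = select_n_best(score_features(T, D), cfg.n_best)

    pred_rows = []
    fold_rows = []
    rep_rows = []
    for r in range(cfg.n_repeats):
        rng = np.random.default_rng(cfg.base_seed + r)
        folds = _fold_indices(rng, S, cfg.k)
        rep_pred = np.empty(S)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(S), test_idx)
            T_train = T.select_rows(train_idx)
            D_train = DSVector(D.values[train_idx], D.source_label)
            if cfg.selection_scope == "per_fold":
                sel = select_n_best(score_features(T_train, D_train), cfg.n_best)
            else:
                sel = global_idx
            model = fit_mlr(T_train, D_train, feature_indices=sel)
            pred = predict(model, T.select_rows(test_idx)).values
            rep_pred[test_idx] = pred
            ref = D.values[test_idx]
            fold_rows.append(
                {
                    "repetition": r,
                    "fold": f,
                    "mae": mae(pred, ref),
                    "mre": _fold_mre_or_nan(pred, ref),
                    "n_test": int(test_idx.size),
                }
            )
            for i, p in zip(test_idx, pred):
                pred_rows.append(
                    {
                        "repetition": r,
                        "fold": f,
                        "sample_id": T.sample_ids[i],
                        "ds_ref": D.values[i],
                        "ds_pred": p,
                    }
                )
        rep_rows.append(
            {
                "repetition": r,
                "mae": mae(rep_pred, D.values),
                "mre": _fold_mre_or_nan(rep_pred, D.values),
            }
        )

    predictions = pd.DataFrame(pred_rows)
    return CVResult(
        config=cfg,
        predictions=predictions,
        fold_metrics=pd.DataFrame(fold_rows),
        repetition_metrics=pd.DataFrame(rep_rows),
        overall_mae=mae(predictions["ds_pred"], predictions["ds_ref"]),
        overall_mre=_fold_mre_or_nan(
            predictions["ds_pred"].to_numpy(), predictions["ds_ref"].to_numpy()
        ),
        sample_ids=list(T.sample_ids),
    )


def aggregate_predictions(res: CVResult) -> pd.DataFrame:
    """Per-sample mean and sample standard deviation of its N test predictions."""
    g = res.predictions.groupby("sample_id", sort=False)["ds_pred"]
    out = pd.DataFrame(
        {
            "mean": g.mean(),
            "sd": g.std(ddof=1).fillna(0.0),  # N = 1 -> sd 0
            "n": g.size(),
        }
    )
    ref = res.predictions.groupby("sample_id", sort=False)["ds_ref"].first()
    out.insert(0, "ds_ref", ref)
    return out.reset_index()


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot statistics: quartiles, mean, 1.5*IQR whiskers, outliers."""

    q1: float
    median: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def box_stats(values) -> BoxStats:
    """Quartiles by linear interpolation of order statistics; whiskers are the
    farthest data points within 1.5*IQR beyond the quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("box_stats needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValidationError("box_stats values must be finite")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_low = v[v >= q1 - 1.5 * iqr]
    in_high = v[v <= q3 + 1.5 * iqr]
    wlo = float(in_low.min())
    whi = float(in_high.max())
    outliers = tuple(sorted(v[(v < wlo) | (v > whi)]))
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        mean=float(v.mean()),
        whisker_low=wlo,
        whisker_high=whi,
        outliers=outliers,
    )


def sweep_k(
    T: SpectraSet,
    D: DSVector,
    n_repeats: int,
    base_seed: int,
    k_grid: Sequence[int] | None = None,
    **cfg_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-MAE distribution as a function of k (shared seed schedule).

    Default k grid is 2..16 intersected with k <= S.  Returns a long table of
    (k, repetition, fold, mae, mre) and a per-k summary with box statistics.
    """
    if k_grid is None:
        k_grid = [k for k in range(2, 17) if k <= T.n_samples]
    long_rows = []
    summaries = []
    for k in k_grid:
        cfg = CVConfig(k=int(k), n_repeats=n_repeats, base_seed=base_seed, **cfg_kwargs)
        res = repeated_kfold(T, D, cfg)
        fold = res.fold_metrics.assign(k=int(k))
        long_rows.append(fold)
        bs = box_stats(fold["mae"].to_numpy())
        summaries.append(
            {
                "k": int(k),
                "mean_mae": fold["mae"].mean(),
                "median_mae": bs.median,
                "q1": bs.q1,
                "q3": bs.q3,
                "whisker_low": bs.whisker_low,
                "whisker_high": bs.whisker_high,
                "n_outliers": len(bs.outliers),
                "overall_mae": res.overall_mae,
            }
        )
    return pd.concat(long_rows, ignore_index=True), pd.DataFrame(summaries)
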