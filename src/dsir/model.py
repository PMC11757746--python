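"""Intercept-free multiple linear regression with non-negative predictions.

The model is a single weight per retained wavenumber: DS_pred = T w, with w
minimizing ||T w - D||_2^2 and no intercept column.  With S samples and M
wavenumbers the calibration regime is S << M, so the least-squares problem is
underdetermined; the minimum-Euclidean-norm solution is returned (SVD-based,
rank-revealing).  Because a degree of substitution is physically non-negative,
a ReLU max(0, .) is applied to the model output at prediction time — never
inside the training objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import GridMismatchError, ValidationError
from .io import DSVector, ModelFile, SpectraSet

__all__ = ["MLRModel", "fit_mlr", "predict", "to_model_file", "from_model_file"]

# SVD cutoff for rank determination: singular values below
# RCOND * max(S, M) * sigma_max are treated as zero (numpy/scipy default).
RCOND = None


@dataclass
class MLRModel:
    """Fitted weight vector plus the grid/selection metadata needed to predict."""

    weights: np.ndarray
    grid: np.ndarray
    feature_indices: np.ndarray | None = None  # None means all columns
    trained_on: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.feature_indices is not None:
            self.feature_indices = np.asarray(self.feature_indices, dtype=int)
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("model weights must be finite")
        n_sel = (
            self.grid.size if self.feature_indices is None else self.feature_indices.size
        )
        if self.weights.size != n_sel:
            raise ValidationError(
                f"weights length {self.weights.size} != {n_sel} selected features"
            )

    @property
    def selected_grid(self) -> np.ndarray:
        if self.feature_indices is None:
            return self.grid
        return self.grid[self.feature_indices]


def fit_mlr(
    T: SpectraSet, D: DSVector, feature_indices=None
) -> MLRModel:
    """Fit w = argmin ||T w - D||^2 without intercept (minimum-norm solution).

    Parameters
    ----------
    T
        Normalized (and optionally region-masked) spectra.
    D
        Reference DS values, one per row of ``T``.
    feature_indices
        Optional strictly increasing column indices into ``T.grid``; when
        given, only those columns enter the fit and the indices are stored on
        the model so prediction can restrict full-grid inputs internally.
    """
    if len(D) != T.n_samples:
        raise ValidationError(
            f"{T.n_samples} spectra but {len(D)} DS values"
        )
    X = T.matrix
    if feature_indices is not None:
        feature_indices = np.asarray(feature_indices, dtype=int)
        if feature_indices.size == 0:
            raise ValidationError("feature_indices must select at least one column")
        if np.any(np.diff(feature_indices) <= 0):
            raise ValidationError("feature_indices must be strictly increasing")
        if feature_indices[0] < 0 or feature_indices[-1] >= T.n_features:
            raise ValidationError("feature_indices out of range")
        if feature_indices.size == T.n_features:
            feature_indices = None  # selecting everything == no selection, exactly
        else:
            X = X[:, feature_indices]
    if not np.all(np.isfinite(X)):
        raise ValidationError("spectra contain non-finite values")

    w, _, rank, sv = linalg.lstsq(X, D.values, cond=RCOND, lapack_driver="gelsd")
    return MLRModel(
        weights=w,
        grid=T.grid,
        feature_indices=feature_indices,
        trained_on=list(T.sample_ids),
        meta={
            "rank": int(rank),
            "rcond": "machine-eps * max(S, M) (LAPACK gelsd default)",
            "n_samples": T.n_samples,
            "n_features": int(X.shape[1]),
        },
    )


def _restrict(m: MLRModel, T: SpectraSet) -> np.ndarray:
    """Return the feature matrix of T restricted to the model's columns."""
    sel = m.selected_grid
    rtol = 1e-9

    def _match(grid_a, grid_b):
        return grid_a.size == grid_b.size and np.allclose(
            grid_a, grid_b, rtol=rtol, atol=0.0
        )

    if _match(T.grid, m.grid):
        return T.matrix if m.feature_indices is None else T.matrix[:, m.feature_indices]
    if _match(T.grid, sel):
        return T.matrix
    raise GridMismatchError(
        f"prediction grid ({T.grid.size} points, [{T.grid[0]}, {T.grid[-1]}]) matches "
        f"neither the model's training grid ({m.grid.size} points) nor its "
        f"selected subset ({sel.size} points)"
    )


def predict(m: MLRModel, T: SpectraSet) -> DSVector:
    """Predict DS = max(0, T w) for each sample (ReLU non-negativity)."""
    if not T.normalized:
        raise ValidationError("predict expects normalized spectra")
    X = _restrict(m, T)
    raw = X @ m.weights
    return DSVector(np.maximum(0.0, raw), source_label="IR,ML")


def to_model_file(m: MLRModel, provenance: dict | None = None) -> ModelFile:
    return ModelFile(
        grid=m.grid,
        selected_indices="all" if m.feature_indices is None else m.feature_indices,
        weights=m.weights,
        provenance={**m.meta, "trained_on": list(m.trained_on), **(provenance or {})},
    )


def from_model_file(f: ModelFile) -> MLRModel:
    return MLRModel(
        weights=f.weights,
        grid=f.grid,
        feature_indices=None if isinstance(f.selected_indices, str) else f.selected_indices,
        trained_on=list(f.provenance.get("trained_on", [])),
        meta=dict(f.provenance),
    )
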