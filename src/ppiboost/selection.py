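"""L1-regularized logistic-regression feature selection.

Fits the sparse logistic model

    min_ω  ‖ω‖₁ + C · Σ_i log(1 + exp(−s_i ωᵀx_i)),   s_i ∈ {−1, +1}

via LIBLINEAR's coordinate descent (scikit-learn's ``liblinear`` solver,
which uses exactly this parameterization: larger C weakens the relative
penalty and selects more features). The nonzero-weight support defines the
selected feature subset; downstream matrices are projected onto it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

#: Weights with absolute value at or below this are treated as exactly zero
#: when extracting the support (solver output carries float dust).
ZERO_TOL = 1e-8


@dataclass
class SelectionModel:
    """A fitted L1-logistic selector: weights, intercept and sparse support."""

    C: float
    weights: np.ndarray
    intercept: float
    feature_names: tuple[str, ...]
    zero_tol: float = ZERO_TOL
    standardize: bool = False
    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.support = np.flatnonzero(np.abs(self.weights) > self.zero_tol)

    @property
    def support_names(self) -> tuple[str, ...]:
        return tuple(self.feature_names[j] for j in self.support)

    @property
    def n_selected(self) -> int:
        return len(self.support)


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"f{j}" for j in range(arr.shape[1]))


def fit_l1rlr(
    X,
    y,
    C: float = 1.0,
    seed: int = 0,
    *,
    standardize: bool = False,
    zero_tol: float = ZERO_TOL,
    max_iter: int = 5000,
) -> SelectionModel:
    """Fit the L1-penalized logistic selector.

    Parameters
    ----------
    X : DataFrame or array, n_samples x n_features; must be finite.
    y : binary labels in {0, 1}; both classes must be present.
    C : penalty trade-off; larger C = weaker relative penalty, default 1.
    standardize : optionally z-score columns before fitting (off by default;
        features are otherwise used exactly as encoded). When on, weights and
        support refer to the standardized columns.
    """
    arr, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature matrix contains non-finite values")
    if arr.shape[0] != len(y) or arr.shape[0] < 2:
        raise ValueError("need at least 2 samples with matching labels")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes.tolist()}")
    if C <= 0:
        raise ValueError("C must be positive")

    means = scales = None
    if standardize:
        means = arr.mean(axis=0)
        scales = arr.std(axis=0)
        scales[scales == 0] = 1.0
        arr = (arr - means) / scales

    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=C,
        solver="liblinear",
        random_state=seed,
        max_iter=max_iter,
        tol=1e-6,
    )
    clf.fit(arr, y)
    return SelectionModel(
        C=C,
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        feature_names=names,
        zero_tol=zero_tol,
        standardize=standardize,
        means=means,
        scales=scales,
    )


def apply_selection(X, model: SelectionModel):
    """Project a feature matrix onto the selected support, names preserved.

    The matrix must have the same column count (and order) as the one the
    selector was fitted on. Refuses to emit a zero-column matrix.
    """
    n_cols = X.shape[1]
    if n_cols != len(model.weights):
        raise ValueError(
            f"column-count mismatch: matrix has {n_cols}, selector expects {len(model.weights)}"
        )
    if model.n_selected == 0:
        raise ValueError("no features selected")
    if isinstance(X, pd.DataFrame):
        return X.iloc[:, model.support]
    return np.asarray(X)[:, model.support]


def l1_objective(weights: np.ndarray, intercept: float, X, y, C: float) -> float:
    """Value of the L1-logistic objective ‖ω‖₁ + C·Σ log(1+exp(−s(ωᵀx+b))).

    Labels y in {0,1} are mapped to s in {−1,+1}. Used to verify solver
    optimality independently of the fitting path.
    """
    arr, _ = _as_matrix(X)
    s = 2 * np.asarray(y) - 1
    margins = s * (arr @ weights + intercept)
    return float(np.abs(weights).sum() + C * np.logaddexp(0, -margins).sum())
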