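"""Gradient-tree-boosting binary classifier.

Stagewise additive model F_m = F_{m−1} + γ_m h_m, where each regression tree
h_m is fitted to the negative gradient of the binomial deviance (log-loss)
at the current scores and γ_m realizes the per-leaf line search by the
standard one-step Newton update. Backed by scikit-learn's
``GradientBoostingClassifier``; the single-iteration behaviour is pinned by
an independent literal implementation in the test suite.

Defaults follow the pipeline configuration: M = 1000 boosting iterations,
deviance loss; learning rate 0.1 and tree depth 3 are the conventional
companion defaults and are config-exposed. No early stopping, no
subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier


@dataclass
class GTBModel:
    """A trained gradient-tree-boosting model plus its training metadata."""

    estimator: GradientBoostingClassifier
    M: int
    learning_rate: float
    max_depth: int
    seed: int
    feature_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    return np.asarray(X, dtype=float), None


def train_gtb(
    X,
    y,
    M: int = 1000,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    seed: int = 0,
) -> GTBModel:
    """Train the boosted-tree classifier on a finite feature matrix.

    Deterministic given identical inputs and seed. Raises when only one
    class is present or M < 1.
    """
    arr, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if M < 1:
        raise ValueError("M must be >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; need both 0 and 1")
    est = GradientBoostingClassifier(
        loss="log_loss",
        n_estimators=M,
        learning_rate=learning_rate,
        max_depth=max_depth,
        random_state=seed,
        subsample=1.0,
    )
    est.fit(arr, y)
    if names is None:
        names = tuple(f"f{j}" for j in range(arr.shape[1]))
    return GTBModel(est, M, learning_rate, max_depth, seed, names)


def _check_columns(model: GTBModel, X) -> np.ndarray:
    arr, names = _as_matrix(X)
    if arr.shape[1] != model.n_features:
        raise ValueError(
            f"column-count mismatch: matrix has {arr.shape[1]}, model expects {model.n_features}"
        )
    if names is not None and names != model.feature_names:
        raise ValueError("feature-name mismatch between matrix and model")
    return arr


def decision_scores(model: GTBModel, X) -> np.ndarray:
    """Raw additive scores F_M(x) before the logistic link."""
    return model.estimator.decision_function(_check_columns(model, X))


def predict_proba(model: GTBModel, X) -> np.ndarray:
    """Interaction probability: logistic transform of F_M(x), in (0, 1)."""
    return model.estimator.predict_proba(_check_columns(model, X))[:, 1]


def predict_label(model: GTBModel, X, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff the predicted probability is >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (predict_proba(model, X) >= threshold).astype(int)


def staged_deviance(model: GTBModel, X, y) -> np.ndarray:
    """Mean binomial deviance after each boosting stage.

    deviance_m = (2/n) Σ log(1 + exp(−s_i F_m(x_i))) with s in {−1, +1};
    non-increasing in m on the training set.
    """
    arr = _check_columns(model, X)
    s = 2 * np.asarray(y) - 1
    out = np.empty(model.M)
    for m, scores in enumerate(model.estimator.staged_decision_function(arr)):
        out[m] = 2.0 * np.logaddexp(0, -s * scores.ravel()).mean()
    return out
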