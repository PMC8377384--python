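"""Binary-classification evaluation: confusion metrics, ROC/PR curves and
stratified k-fold cross-validation of the select-then-boost pipeline.

Metric conventions: recall = TP/(TP+FN), precision = TP/(TP+FP),
ACC = (TP+TN)/n, and the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Any zero-denominator ratio is reported as 0 with a warning flag rather than
NaN, so reports are always serializable. The ROC curve uses a
score-descending threshold sweep with tie-grouping and trapezoidal area;
the PR curve uses step (right-continuous) interpolation for its area, which
avoids the optimistic bias of trapezoids on PR axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .encoders import EncoderConfig, build_pair_features
from .gtb import predict_label, predict_proba, train_gtb
from .selection import apply_selection, fit_l1rlr

METRIC_KEYS = ("recall", "precision", "acc", "mcc", "auroc", "auprc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred have different lengths")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class EvalReport:
    """Evaluation results; curve and fold sections are filled when computed."""

    counts: ConfusionCounts | None = None
    recall: float | None = None
    precision: float | None = None
    acc: float | None = None
    mcc: float | None = None
    warnings: list[str] = field(default_factory=list)
    roc_points: list[tuple[float, float]] | None = None
    pr_points: list[tuple[float, float]] | None = None
    auroc: float | None = None
    auprc: float | None = None
    per_fold: list["EvalReport"] | None = None
    mean: dict[str, float] | None = None
    std: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out: dict = {"warnings": list(self.warnings)}
        if self.counts is not None:
            out["counts"] = {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            }
        for key in ("recall", "precision", "acc", "mcc", "auroc", "auprc"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.roc_points is not None:
            out["roc_points"] = [list(p) for p in self.roc_points]
        if self.pr_points is not None:
            out["pr_points"] = [list(p) for p in self.pr_points]
        if self.per_fold is not None:
            out["per_fold"] = [r.to_dict() for r in self.per_fold]
        if self.mean is not None:
            out["mean"] = self.mean
            out["std"] = self.std
        return out


def _safe_ratio(num: float, den: float, name: str, warnings: list[str]) -> float:
    if den == 0:
        warnings.append(f"zero denominator in {name}; reported as 0")
        return 0.0
    return num / den


def binary_metrics(y_true, y_pred) -> EvalReport:
    """Confusion counts plus recall, precision, ACC and MCC from hard labels."""
    c = ConfusionCounts.from_labels(y_true, y_pred)
    if c.n < 1:
        raise ValueError("need at least one sample")
    warnings: list[str] = []
    recall = _safe_ratio(c.tp, c.tp + c.fn, "recall", warnings)
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision", warnings)
    acc = (c.tp + c.tn) / c.n
    mcc_den = np.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_ratio(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc", warnings)
    return EvalReport(
        counts=c, recall=recall, precision=precision, acc=acc, mcc=float(mcc),
        warnings=warnings,
    )


def curves_and_auc(y_true, scores) -> EvalReport:
    """ROC and PR curves with their areas from continuous scores."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores have different lengths")
    if len(np.unique(y_true)) < 2:
        raise ValueError("curves need both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    auroc = float(np.trapezoid(tpr, fpr))
    prec, rec, _ = precision_recall_curve(y_true, scores)
    auprc = float(average_precision_score(y_true, scores))  # step-wise rule
    return EvalReport(
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        pr_points=list(zip(rec.tolist(), prec.tolist())),
        auroc=auroc,
        auprc=auprc,
    )


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> EvalReport:
    """Full report: threshold metrics plus curves from one score vector."""
    metrics = binary_metrics(y_true, (np.asarray(scores) >= threshold).astype(int))
    curves = curves_and_auc(y_true, scores)
    metrics.roc_points = curves.roc_points
    metrics.pr_points = curves.pr_points
    metrics.auroc = curves.auroc
    metrics.auprc = curves.auprc
    return metrics


def stratified_folds(y, k: int, seed: int) -> list[np.ndarray]:
    """Index arrays of the k stratified test folds (sizes differ by <= 1)."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    minority = min(np.sum(y == 0), np.sum(y == 1))
    if minority < k:
        raise ValueError(f"minority class has {minority} samples, fewer than k={k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def cross_validate(
    proteins,
    pssms,
    pairs,
    encoder_config: EncoderConfig = EncoderConfig(),
    *,
    C: float = 1.0,
    M: int = 1000,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full select-then-boost pipeline.

    Pairs (not proteins) are split; per-protein encodings are fixed,
    unsupervised transforms, so they are computed once, while the L1
    selector and the boosted trees are fitted on each training fold only.
    The report carries one sub-report per fold plus the mean and standard
    deviation of every metric; top-level counts and curves pool the held-out
    predictions of all folds.
    """
    X, y = build_pair_features(proteins, pssms, pairs, encoder_config)
    return cross_validate_features(
        X, y, C=C, M=M, learning_rate=learning_rate, max_depth=max_depth,
        k=k, seed=seed, threshold=threshold,
    )


def cross_validate_features(
    X,
    y,
    *,
    C: float = 1.0,
    M: int = 1000,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Cross-validate selection + boosting on a precomputed feature matrix."""
    import pandas as pd

    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k, seed)
    all_idx = np.concatenate(folds)
    if len(np.unique(all_idx)) != len(y):
        raise AssertionError("folds do not partition the samples")
    rng = np.random.SeedSequence(seed)
    fold_seeds = [int(s) % (2**31 - 1) for s in rng.generate_state(k)]

    per_fold: list[EvalReport] = []
    pooled_scores = np.empty(len(y))
    supports: list[tuple[str, ...]] = []
    for fold_no, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        X_train = X.iloc[train_mask.nonzero()[0]] if isinstance(X, pd.DataFrame) else X[train_mask]
        X_test = X.iloc[test_idx] if isinstance(X, pd.DataFrame) else X[test_idx]
        sel = fit_l1rlr(X_train, y[train_mask], C=C, seed=fold_seeds[fold_no])
        model = train_gtb(
            apply_selection(X_train, sel),
            y[train_mask],
            M=M,
            learning_rate=learning_rate,
            max_depth=max_depth,
            seed=fold_seeds[fold_no],
        )
        scores = predict_proba(model, apply_selection(X_test, sel))
        pooled_scores[test_idx] = scores
        per_fold.append(evaluate_predictions(y[test_idx], scores, threshold))
        supports.append(sel.support_names)

    report = evaluate_predictions(y, pooled_scores, threshold)
    report.per_fold = per_fold
    report.mean = {
        key: float(np.mean([getattr(r, key) for r in per_fold])) for key in METRIC_KEYS
    }
    report.std = {
        key: float(np.std([getattr(r, key) for r in per_fold])) for key in METRIC_KEYS
    }
    for r in per_fold:
        report.warnings.extend(w for w in r.warnings if w not in report.warnings)
    report.fold_supports = supports  # leakage sentinel: supports vary across folds
    return report
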