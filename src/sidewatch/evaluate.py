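"""Cross-validation harness, confusion-matrix metrics and component reports.

The headline numbers are pooled out-of-fold metrics: stratified K-fold
assignment is fixed by a seed, every data-dependent fitting step (text
vocabulary, PCA, learner calibration) happens inside the training fold
only, and the out-of-fold predictions are pooled into one confusion matrix
from which per-class and support-weighted precision/recall/F are derived.
Per-fold metrics and their mean are also reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .corpus import CLASS_LABELS, ClassLabel, Post


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        labels: Optional[Sequence[str]] = None,
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = [l.code for l in CLASS_LABELS]
        pos = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[pos[str(t)], pos[str(p)]] += 1
        return cls(counts, tuple(labels))

    def to_csv(self, path) -> None:
        import csv as _csv
        from pathlib import Path

        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["class", *self.labels])
            for lbl, row in zip(self.labels, self.counts):
                writer.writerow([lbl, *row.tolist()])


@dataclass
class MetricsReport:
    """Per-class and support-weighted precision/recall/F plus micro accuracy."""

    per_class: Dict[str, Tuple[float, float, float, int]]
    weighted: Tuple[float, float, float]
    micro_accuracy: float

    def rounded(self, ndigits: int = 3) -> "MetricsReport":
        """Report-display rounding (half-up) to ``ndigits`` decimals."""
        from decimal import ROUND_HALF_UP, Decimal

        def r(x: float) -> float:
            return float(
                Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP)
            )

        return MetricsReport(
            per_class={k: (r(p), r(rc), r(f), s) for k, (p, rc, f, s) in self.per_class.items()},
            weighted=tuple(r(v) for v in self.weighted),
            micro_accuracy=r(self.micro_accuracy),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_class": {
                    k: {"precision": p, "recall": r, "f1": f, "support": s}
                    for k, (p, r, f, s) in self.per_class.items()
                },
                "weighted": dict(zip(("precision", "recall", "f1"), self.weighted)),
                "micro_accuracy": self.micro_accuracy,
            },
            indent=2,
        )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall/F and support-weighted averages.

    Precision is the diagonal over the column sum (0 with a warning when a
    class is never predicted), recall the diagonal over the row sum, F their
    harmonic mean; weighted averages use the true-class supports, so the
    weighted recall equals the overall (micro) accuracy exactly.
    """
    counts = cm.counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    per_class: Dict[str, Tuple[float, float, float, int]] = {}
    for k, label in enumerate(cm.labels):
        if col[k] == 0:
            warnings.warn(f"class {label}: never predicted; precision defined as 0")
            precision = 0.0
        else:
            precision = diag[k] / col[k]
        recall = diag[k] / row[k] if row[k] > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class[label] = (precision, recall, f1, int(row[k]))
    support = row / row.sum()
    weighted = tuple(
        float(np.sum(support * np.array([per_class[l][i] for l in cm.labels])))
        for i in range(3)
    )
    micro = float(diag.sum() / counts.sum())
    return MetricsReport(per_class, weighted, micro)


class PipelineProtocol(Protocol):
    """What cross_validate expects: a fresh, fittable classifier pipeline."""

    def fit(self, posts: Sequence[Post], labels: Sequence[str]) -> "PipelineProtocol": ...

    def predict(self, posts: Sequence[Post]) -> Sequence[str]: ...


@dataclass
class CrossValidationResult:
    pooled_metrics: MetricsReport
    pooled_confusion: ConfusionMatrix
    fold_metrics: List[MetricsReport]

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean([m.micro_accuracy for m in self.fold_metrics]))


def cross_validate(
    posts: Sequence[Post],
    labels: Sequence[str],
    pipeline_factory,
    folds: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified K-fold cross-validation of a classifier pipeline.

    ``pipeline_factory()`` must return a fresh unfitted pipeline for each
    fold; all feature fitting therefore happens inside the training fold
    only.  Fold assignment is deterministic given ``seed``.  Returns pooled
    out-of-fold metrics (the headline numbers) plus per-fold metrics.
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    labels = [str(l) for l in labels]
    if len(posts) != len(labels):
        raise ValueError("posts and labels differ in length")
    label_names = sorted(set(labels), key=lambda c: (len(c), c))
    smallest = min(labels.count(c) for c in label_names)
    if smallest < folds:
        warnings.warn(
            f"smallest class has {smallest} members < {folds} folds; "
            "stratification degrades"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = np.array(labels)
    idx = np.arange(len(posts))
    pooled_true: List[str] = []
    pooled_pred: List[str] = []
    fold_metrics: List[MetricsReport] = []
    for train_idx, test_idx in skf.split(idx.reshape(-1, 1), y):
        pipeline = pipeline_factory()
        pipeline.fit([posts[i] for i in train_idx], y[train_idx].tolist())
        pred = [str(p) for p in pipeline.predict([posts[i] for i in test_idx])]
        true = y[test_idx].tolist()
        pooled_true.extend(true)
        pooled_pred.extend(pred)
        fold_metrics.append(
            metrics_from_confusion(
                ConfusionMatrix.from_predictions(true, pred, labels=label_names)
            )
        )
    pooled_cm = ConfusionMatrix.from_predictions(pooled_true, pooled_pred, labels=label_names)
    return CrossValidationResult(metrics_from_confusion(pooled_cm), pooled_cm, fold_metrics)


def component_report(
    components: np.ndarray,
    feature_names: Sequence[str],
    model,
    class_label: "ClassLabel | str",
    top_n: int = 5,
) -> List[Tuple[int, float, List[Tuple[str, float]]]]:
    """Rank principal components by their discriminative weight for a class.

    ``model`` must be fitted on the PCA-reduced features and expose either
    per-class linear weights (``coef_``) or Gaussian class means
    (``theta_``); the discriminative weight of a component is the model's
    (signed) weight for the requested class — for Gaussian likelihood
    models, the standardised difference between the class mean and the
    overall mean.  Each reported component is summarised by its ``top_n``
    largest-magnitude feature loadings with their signs, so negatively
    correlated features appear with negative weights.
    """
    components = np.asarray(components, dtype=float)
    if components.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match components")
    code = class_label.code if isinstance(class_label, ClassLabel) else str(class_label)
    classes = [str(c) for c in getattr(model, "classes_", [])]
    if code not in classes:
        raise ValueError(f"model was not trained on class {code!r}")
    k = classes.index(code)
    if hasattr(model, "coef_"):
        coef = np.asarray(model.coef_)
        weights = coef[0] if coef.shape[0] == 1 else coef[k]
    elif hasattr(model, "theta_"):
        theta = np.asarray(model.theta_)
        pooled = np.sqrt(np.asarray(model.var_).mean(axis=0)) + 1e-12
        weights = (theta[k] - theta.mean(axis=0)) / pooled
    else:
        raise TypeError("model exposes neither coef_ nor theta_")
    weights = np.asarray(weights, dtype=float)[: components.shape[0]]
    order = np.argsort(-np.abs(weights))
    report = []
    for comp_idx in order:
        loadings = components[comp_idx]
        top = np.argsort(-np.abs(loadings))[:top_n]
        report.append(
            (
                int(comp_idx),
                float(weights[comp_idx]),
                [(feature_names[j], float(loadings[j])) for j in top],
            )
        )
    return report
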