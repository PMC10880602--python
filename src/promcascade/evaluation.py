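"""Classifier evaluation: metric suite, algorithm comparison, k-fold CV with
ROC curves, and the external-promoter validation protocol.

Metrics follow the usual confusion-matrix definitions — accuracy (TP+TN)/N,
precision TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP), F1 the
harmonic mean of precision and recall, and AUC from ranked scores.  A metric
with a zero denominator is reported as undefined (None), never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cascade_model import CascadeModel, expand_seed
from .dds_encoding import encode_batch
from .errors import ConfigError, DataError

import logging

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricReport:
    """Metric bundle; None marks an undefined (zero-denominator) metric."""

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    f1: float | None = None
    auc: float | None = None
    per_fold: list["MetricReport"] | None = None
    mean_sd: dict[str, tuple[float, float]] | None = None
    roc_curves: list[tuple[np.ndarray, np.ndarray]] | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
        }


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den else None


def compute_metrics(
    c: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricReport:
    """Metrics from confusion counts; AUC additionally needs ranked scores
    with their true labels."""
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true alongside scores")
        y_true = np.asarray(y_true)
        if len(np.unique(y_true)) == 2:
            auc = float(roc_auc_score(y_true, np.asarray(scores)))
    return MetricReport(
        accuracy=_safe_div(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        specificity=_safe_div(c.tn, c.tn + c.fp),
        f1=f1,
        auc=auc,
    )


# the six classifier families screened for both cascade stages
def _algorithm_registry(seed: int) -> dict[str, object]:
    return {
        "Random Forest": RandomForestClassifier(random_state=seed),
        "Support Vector Machines": SVC(random_state=seed),
        "Logistic Regression": LogisticRegression(random_state=seed),
        "Gradient Boosting": GradientBoostingClassifier(random_state=seed),
        "XGBoost": XGBClassifier(random_state=seed, eval_metric="logloss", n_jobs=1),
        "K-Nearest Neighbors": KNeighborsClassifier(),
    }


ALGORITHM_NAMES = tuple(_algorithm_registry(0))


def compare_algorithms(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    algorithms: Sequence[str] | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Screen the candidate families at default parameters on a held-out test.

    Returns one row per algorithm (accuracy, precision, recall, f1) and the
    name of the argmax-accuracy winner.
    """
    registry = _algorithm_registry(int(rng_seed))
    names = list(algorithms) if algorithms is not None else list(registry)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise ConfigError(f"unknown algorithm(s) {unknown}; choose from {list(registry)}")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # default LogisticRegression may hit max_iter
        for name in names:
            clf = registry[name]
            clf.fit(np.asarray(X_train, dtype=np.float64), np.asarray(y_train))
            pred = clf.predict(np.asarray(X_test, dtype=np.float64))
            m = compute_metrics(ConfusionCounts.from_labels(y_test, pred))
            rows.append({"algorithm": name, "accuracy": m.accuracy,
                         "precision": m.precision, "recall": m.recall, "f1": m.f1})
    table = pd.DataFrame(rows)
    best = table.loc[table["accuracy"].idxmax(), "algorithm"]
    return table, str(best)


def cross_validate(
    make_classifier: Callable[[int], object],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    rng_seed: int = 0,
    threshold: float = 0.5,
) -> MetricReport:
    """Stratified k-fold CV with per-fold metrics, mean ± sd, and ROC points.

    ``make_classifier(seed)`` must return an unfitted estimator with
    ``predict_proba``.  The fold union covers the dataset exactly once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    fold_seed, fit_seed = expand_seed(rng_seed, 2)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    per_fold: list[MetricReport] = []
    rocs: list[tuple[np.ndarray, np.ndarray]] = []
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise DataError("a cross-validation fold is single-class")
        clf = make_classifier(fit_seed)
        clf.fit(X[train_idx], y[train_idx])
        proba = clf.predict_proba(X[test_idx])[:, 1]
        pred = (proba >= threshold).astype(int)
        m = compute_metrics(ConfusionCounts.from_labels(y[test_idx], pred),
                            scores=proba, y_true=y[test_idx])
        per_fold.append(m)
        fpr, tpr, _ = roc_curve(y[test_idx], proba)
        rocs.append((fpr, tpr))
    mean_sd = {}
    summary = {}
    for metric in ("accuracy", "precision", "recall", "specificity", "f1", "auc"):
        vals = [getattr(m, metric) for m in per_fold if getattr(m, metric) is not None]
        if vals:
            mean_sd[metric] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
            summary[metric] = float(np.mean(vals))
    return MetricReport(**summary, per_fold=per_fold, mean_sd=mean_sd, roc_curves=rocs)


def make_stage1_factory(params: dict | None = None) -> Callable[[int], XGBClassifier]:
    """Factory producing stage-1-configured boosters for :func:`cross_validate`."""
    from .cascade_model import DEFAULT_STAGE1_PARAMS, _make_xgb

    return lambda seed: _make_xgb(dict(DEFAULT_STAGE1_PARAMS if params is None else params), seed)


@dataclass
class ExternalValidation:
    """Outcome of scoring a set of known promoters with the cascade."""

    n_input: int
    n_encoded: int
    n_skipped: int
    stage1_hits: int
    stage2_rescues: int

    @property
    def total(self) -> int:
        return self.stage1_hits + self.stage2_rescues

    @property
    def fraction(self) -> float | None:
        return self.total / self.n_encoded if self.n_encoded else None


def validate_external(
    model: CascadeModel,
    promoters: Sequence[tuple[str, str]],
    window: int = 60,
) -> ExternalValidation:
    """Score known positives: stage-1 hits plus stage-2 rescues among stage-1
    rejects, and the recovered fraction.

    Sequences longer than ``window`` are trimmed to their final ``window`` nt
    (the anchored-window convention); shorter ones are skipped and counted.
    """
    usable: list[tuple[str, str]] = []
    n_skipped = 0
    for sid, seq in promoters:
        if len(seq) < window:
            n_skipped += 1
            continue
        usable.append((sid, seq[-window:]))
    if n_skipped:
        logger.warning("validate_external: skipped %d sequences shorter than %d nt",
                       n_skipped, window)
    if not usable:
        return ExternalValidation(len(list(promoters)), 0, n_skipped, 0, 0)
    X, ids = encode_batch(usable, model.table)
    recs = model.predict(X, ids)
    stage1_hits = sum(r.stage1_label == 1 for r in recs)
    stage2_rescues = sum(r.stage1_label == 0 and r.final_label == 1 for r in recs)
    return ExternalValidation(
        n_input=len(usable) + n_skipped,
        n_encoded=len(usable),
        n_skipped=n_skipped,
        stage1_hits=stage1_hits,
        stage2_rescues=stage2_rescues,
    )
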