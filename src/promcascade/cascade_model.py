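"""Two-stage boosted-tree cascade with an error-trained rescue classifier.

Stage 1 is a gradient-boosted tree ensemble (XGBoost) trained on the full
balanced dataset.  Its misclassifications are collected out-of-fold
(stratified 10-fold, so no record is judged by a model that saw it), and
stage 2 is trained to separate the false negatives (true promoters stage 1
rejected, label 1) from the false positives (background stage 1 accepted,
label 0), after downsampling the larger error set to a 1:1 ratio.  At
prediction time stage 2 is consulted only for stage-1 negatives, and the
final label is the union: a sequence is called a promoter if either stage
says so.  The union rule can only raise recall and lower specificity
relative to stage 1 — it rescues weak promoters at the cost of extra false
positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .dds_encoding import DDSTable, default_table
from .errors import DataError, ShapeError, VersionError

logger = logging.getLogger(__name__)

#: Stage-1 configuration selected by grid search in the original study.
DEFAULT_STAGE1_PARAMS = {"n_estimators": 200, "learning_rate": 0.2, "max_depth": 7}

#: The hyperparameter grid screened for stage 1.
DEFAULT_GRID = {
    "n_estimators": [50, 100, 200],
    "learning_rate": [0.01, 0.1, 0.2],
    "max_depth": [3, 5, 7],
}

DEFAULT_THRESHOLD = 0.5
MODEL_FORMAT = "promcascade-model"
MODEL_FORMAT_VERSION = 1


def expand_seed(rng_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2**31) from one top-level seed."""
    ss = np.random.SeedSequence(int(rng_seed))
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def _make_xgb(params: dict | None, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **(params or {}),
        random_state=int(seed),
        eval_metric="logloss",
        n_jobs=1,
    )


@dataclass
class PredictionRecord:
    """Per-sequence cascade outcome; stage-2 fields are None when stage 1
    already accepted the sequence (or the cascade has no stage 2)."""

    id: str
    stage1_score: float
    stage1_label: int
    stage2_score: float | None
    stage2_label: int | None
    final_label: int


@dataclass
class ErrorSets:
    """Out-of-fold stage-1 misclassifications over a labeled dataset."""

    fp_indices: np.ndarray  # label 0, predicted 1
    fn_indices: np.ndarray  # label 1, predicted 0
    oof_labels: np.ndarray  # out-of-fold predicted label per record

    @property
    def n_fp(self) -> int:
        return len(self.fp_indices)

    @property
    def n_fn(self) -> int:
        return len(self.fn_indices)


def train_stage1(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    rng_seed: int = 0,
) -> XGBClassifier:
    """Fit the stage-1 booster (defaults to the tuned 200 / 0.2 / 7 config)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("stage-1 training data contains a single class")
    clf = _make_xgb(dict(DEFAULT_STAGE1_PARAMS if hyperparams is None else hyperparams), rng_seed)
    clf.fit(np.asarray(X, dtype=np.float64), y)
    return clf


def grid_search_stage1(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    rng_seed: int = 0,
    cv: int = 5,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search scored by stratified ``cv``-fold CV accuracy.

    Returns the winning configuration and the full score table.  Ties are
    broken toward the simplest model: fewer estimators, then lower depth,
    then lower learning rate.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise DataError("hyperparameter grid is empty")
    from sklearn.model_selection import cross_val_score

    fold_seed, fit_seed = expand_seed(rng_seed, 2)
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=fold_seed)
    keys = sorted(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = cross_val_score(_make_xgb(params, fit_seed), np.asarray(X, dtype=np.float64),
                                 np.asarray(y), cv=splitter, scoring="accuracy")
        rows.append({**params, "mean_cv_accuracy": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    ranked = sorted(
        rows,
        key=lambda r: (
            -r["mean_cv_accuracy"],
            r.get("n_estimators", 0),
            r.get("max_depth", 0),
            r.get("learning_rate", 0.0),
        ),
    )
    best = {k: ranked[0][k] for k in keys}
    return best, table


def collect_errors(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    rng_seed: int = 0,
    n_folds: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
) -> ErrorSets:
    """Stage-1 false positives / false negatives from out-of-fold prediction.

    Each record is predicted exactly once, by a model trained on the other
    ``n_folds − 1`` folds (stratified), so the error sets carry no training
    leakage into stage 2.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    fold_seed, fit_seed = expand_seed(rng_seed, 2)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    oof = np.full(len(y), -1, dtype=np.int64)
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise DataError("a cross-validation fold is single-class")
        clf = _make_xgb(dict(DEFAULT_STAGE1_PARAMS if hyperparams is None else hyperparams),
                        fit_seed)
        clf.fit(X[train_idx], y[train_idx])
        proba = clf.predict_proba(X[test_idx])[:, 1]
        oof[test_idx] = (proba >= threshold).astype(np.int64)
    assert (oof >= 0).all(), "out-of-fold partition must cover every record"
    fp = np.flatnonzero((y == 0) & (oof == 1))
    fn = np.flatnonzero((y == 1) & (oof == 0))
    return ErrorSets(fp_indices=fp, fn_indices=fn, oof_labels=oof)


def balance_error_sets(
    X_fp: np.ndarray, X_fn: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """1:1 stage-2 training set: the larger error set uniformly downsampled
    (without replacement) to the smaller one's size; FP → label 0, FN → 1."""
    n = min(len(X_fp), len(X_fn))
    if len(X_fp) > n:
        X_fp = X_fp[np.sort(rng.choice(len(X_fp), size=n, replace=False))]
    if len(X_fn) > n:
        X_fn = X_fn[np.sort(rng.choice(len(X_fn), size=n, replace=False))]
    X2 = np.vstack([X_fp, X_fn])
    y2 = np.concatenate([np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)])
    return X2, y2


def train_stage2(
    X_fp: np.ndarray,
    X_fn: np.ndarray,
    rng_seed: int = 0,
    hyperparams: dict | None = None,
) -> XGBClassifier | None:
    """Fit the rescue classifier on stage-1 errors (FN → 1, FP → 0).

    The larger error set is uniformly downsampled (seeded) to the smaller
    one's size, giving the 1:1 error dataset.  Booster hyperparameters stay
    at library defaults — tuning did not improve this stage.  Returns None
    when either error set is empty; the cascade then degenerates to stage 1.
    """
    X_fp = np.asarray(X_fp, dtype=np.float64)
    X_fn = np.asarray(X_fn, dtype=np.float64)
    if len(X_fp) == 0 or len(X_fn) == 0:
        logger.info("empty error set (|FP|=%d, |FN|=%d); cascade will use stage 1 only",
                    len(X_fp), len(X_fn))
        return None
    sample_seed, fit_seed = expand_seed(rng_seed, 2)
    X2, y2 = balance_error_sets(X_fp, X_fn, np.random.default_rng(sample_seed))
    clf = _make_xgb(dict(hyperparams or {}), fit_seed)
    clf.fit(X2, y2)
    return clf


@dataclass
class CascadeModel:
    """Trained two-stage cascade plus everything needed to reproduce it."""

    stage1: XGBClassifier
    stage2: XGBClassifier | None
    table: DDSTable
    threshold: float = DEFAULT_THRESHOLD
    combination_rule: str = "rescue_union"
    manifest: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.stage1.n_features_in_)

    def predict(self, X: np.ndarray, ids: Sequence[str] | None = None) -> list[PredictionRecord]:
        """Cascade prediction: stage 2 is consulted only for stage-1 negatives;
        final label = stage1 OR stage2 (the rescue-union rule)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ShapeError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match the trained width {self.n_features}"
            )
        if ids is None:
            ids = [str(i) for i in range(len(X))]
        s1 = self.stage1.predict_proba(X)[:, 1]
        l1 = (s1 >= self.threshold).astype(int)
        s2_all = np.full(len(X), np.nan)
        neg = np.flatnonzero(l1 == 0)
        if self.stage2 is not None and len(neg):
            s2_all[neg] = self.stage2.predict_proba(X[neg])[:, 1]
        out: list[PredictionRecord] = []
        for i, rid in enumerate(ids):
            if l1[i] == 1:
                out.append(PredictionRecord(rid, float(s1[i]), 1, None, None, 1))
            elif self.stage2 is None:
                out.append(PredictionRecord(rid, float(s1[i]), 0, None, None, 0))
            else:
                l2 = int(s2_all[i] >= self.threshold)
                out.append(PredictionRecord(rid, float(s1[i]), 0, float(s2_all[i]), l2, l2))
        return out

    def predict_frame(self, X: np.ndarray, ids: Sequence[str] | None = None) -> pd.DataFrame:
        recs = self.predict(X, ids)
        return pd.DataFrame(
            {
                "id": [r.id for r in recs],
                "stage1_score": [r.stage1_score for r in recs],
                "stage1_label": [r.stage1_label for r in recs],
                "stage2_score": [r.stage2_score for r in recs],
                "stage2_label": [r.stage2_label for r in recs],
                "final_label": [r.final_label for r in recs],
            }
        )


def fit_cascade(
    X: np.ndarray,
    y: np.ndarray,
    rng_seed: int,
    stage1_params: dict | None = None,
    table: DDSTable | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    n_folds: int = 10,
) -> tuple[CascadeModel, ErrorSets]:
    """End-to-end training: out-of-fold error collection, stage 1 on the full
    set, stage 2 on the balanced error set.  All randomness flows from
    ``rng_seed`` through named sub-seeds."""
    table = table or default_table()
    errors_seed, stage1_seed, stage2_seed = expand_seed(rng_seed, 3)
    params = dict(DEFAULT_STAGE1_PARAMS if stage1_params is None else stage1_params)
    errors = collect_errors(X, y, params, errors_seed, n_folds=n_folds, threshold=threshold)
    stage1 = train_stage1(X, y, params, stage1_seed)
    stage2 = train_stage2(
        np.asarray(X)[errors.fp_indices], np.asarray(X)[errors.fn_indices], stage2_seed
    )
    y = np.asarray(y)
    manifest = {
        "rng_seed": int(rng_seed),
        "sub_seeds": {"errors": errors_seed, "stage1": stage1_seed, "stage2": stage2_seed},
        "stage1_params": params,
        "error_fold_scheme": {"n_folds": n_folds, "stratified": True},
        "threshold": float(threshold),
        "class_counts": {int(c): int((y == c).sum()) for c in np.unique(y)},
        "n_fp": errors.n_fp,
        "n_fn": errors.n_fn,
        "table_name": table.name,
        "table_checksum": table.checksum(),
    }
    model = CascadeModel(stage1=stage1, stage2=stage2, table=table,
                         threshold=threshold, manifest=manifest)
    return model, errors


def save_model(model: CascadeModel, path) -> None:
    """Serialize the cascade (stages, manifest, DDS table + checksum) to one file."""
    payload = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "manifest": model.manifest,
        "threshold": model.threshold,
        "combination_rule": model.combination_rule,
        "table": model.table.to_dict(),
        "table_checksum": model.table.checksum(),
        "stage1": model.stage1,
        "stage2": model.stage2,
    }
    joblib.dump(payload, path)


def load_model(path) -> CascadeModel:
    """Load a model archive, verifying format version and DDS-table checksum."""
    try:
        payload = joblib.load(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"model archive not found: {path}") from None
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise VersionError(f"{path}: not a promcascade model archive")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise VersionError(
            f"{path}: archive version {payload.get('format_version')} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    table = DDSTable.from_dict(payload["table"])
    if table.checksum() != payload.get("table_checksum"):
        raise VersionError(f"{path}: DDS table checksum mismatch (archive corrupted?)")
    return CascadeModel(
        stage1=payload["stage1"],
        stage2=payload["stage2"],
        table=table,
        threshold=float(payload["threshold"]),
        combination_rule=payload.get("combination_rule", "rescue_union"),
        manifest=payload.get("manifest", {}),
    )
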