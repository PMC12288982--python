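"""Ensemble random-forest biomarker ranking and logistic-regression evaluation.

The ranking procedure fits one random forest per leave-out block: the sample
set is split into k (default 20) disjoint held-out blocks, each forest trains
on the ~95% complement, and Gini importances plus out-of-bag errors are
recorded per iteration and aggregated as mean ± sd per feature.  Selected
top features are then evaluated with a stratified 70:30 ridge-penalized
logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateLabelError, SchemaError, StratificationError, ValidationError


@dataclass
class LeaveOutPartition:
    """k disjoint held-out index blocks covering all n samples."""

    blocks: list[np.ndarray]
    n: int
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.blocks)
        if len(all_idx) != self.n or len(np.unique(all_idx)) != self.n:
            raise ValidationError("blocks must be disjoint and cover all samples")
        sizes = {len(b) for b in self.blocks}
        if max(sizes) - min(sizes) > 1:
            raise ValidationError("block sizes must differ by at most 1")


def make_partition(n: int, k: int = 20, seed: int = 0) -> LeaveOutPartition:
    """Randomly split n samples into k near-equal held-out blocks."""
    if k > n:
        raise ValidationError(f"cannot make {k} blocks from {n} samples")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    blocks = [np.sort(b) for b in np.array_split(perm, k)]
    return LeaveOutPartition(blocks=blocks, n=n, seed=seed)


@dataclass
class ImportanceSummary:
    importance: pd.DataFrame  # feature x (mean, sd)
    oob_errors: list[float]
    n_iterations: int


def ensemble_importance(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    partition: LeaveOutPartition,
    n_trees: int = 1000,
    seed: int = 0,
    mtry: str = "sqrt_features",
) -> ImportanceSummary:
    """Per-iteration random forests on leave-out training sets.

    Each iteration fits a Gini-impurity forest (``n_trees`` trees,
    features-per-split = floor(sqrt(p)) by default, or floor(sqrt(n)) with
    ``mtry="sqrt_samples"``) on the complement of one held-out block, and
    records out-of-bag error and mean-decrease-in-Gini importances.
    """
    if X.isna().to_numpy().any():
        raise ValidationError("feature table must be complete")
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise DegenerateLabelError("labels must have exactly two classes")
    if mtry == "sqrt_features":
        max_features = max(1, int(np.sqrt(X.shape[1])))
    elif mtry == "sqrt_samples":
        max_features = min(X.shape[1], max(1, int(np.sqrt(X.shape[0]))))
    else:
        raise ValidationError(f"unknown mtry rule {mtry!r}")

    rng = np.random.default_rng(seed)
    importances, oob_errors = [], []
    for block in partition.blocks:
        train = np.setdiff1d(np.arange(partition.n), block)
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise DegenerateLabelError("a training set contains a single class")
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            criterion="gini",
            oob_score=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X.iloc[train], y_tr)
        importances.append(forest.feature_importances_)
        oob_errors.append(1.0 - float(forest.oob_score_))
    imp = np.asarray(importances)
    summary = pd.DataFrame(
        {"mean": imp.mean(axis=0), "sd": imp.std(axis=0, ddof=1)}, index=X.columns
    )
    return ImportanceSummary(
        importance=summary, oob_errors=oob_errors, n_iterations=len(partition.blocks)
    )


def select_top_features(summary: ImportanceSummary, k: int = 9) -> list[str]:
    """Top-k features by mean importance; ties break lexicographically."""
    imp = summary.importance
    if k > len(imp):
        raise ValidationError(f"k={k} exceeds feature count {len(imp)}")
    order = sorted(imp.index, key=lambda f: (-imp.at[f, "mean"], f))
    return order[:k]


@dataclass
class EvalResult:
    train_accuracy: float
    test_accuracy: float
    train_index: np.ndarray
    test_index: np.ndarray
    features: list[str]


def train_test_logistic(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    features: list[str],
    test_fraction: float = 0.3,
    seed: int = 0,
    ridge_penalty: float = 1.0,
) -> EvalResult:
    """Stratified 70:30 split, ridge-penalized logistic regression, accuracy on
    both splits at a 0.5 probability cut-off.

    ``ridge_penalty`` is the L2 strength (sklearn C = 1/penalty); a small
    penalty keeps the fit convergent under perfect separation.
    """
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise SchemaError(f"features absent from table: {missing}")
    y = np.asarray(y)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    for part, name in ((train_idx, "training"), (test_idx, "test")):
        if len(np.unique(y[part])) < 2:
            raise StratificationError(f"{name} split lacks both classes")
    scaler = StandardScaler().fit(X.iloc[train_idx][features])
    clf = LogisticRegression(C=1.0 / ridge_penalty, max_iter=5000)
    clf.fit(scaler.transform(X.iloc[train_idx][features]), y[train_idx])

    def _acc(part: np.ndarray) -> float:
        prob = clf.predict_proba(scaler.transform(X.iloc[part][features]))[:, 1]
        pred = np.where(prob >= 0.5, clf.classes_[1], clf.classes_[0])
        return float((pred == y[part]).mean())

    return EvalResult(
        train_accuracy=_acc(train_idx),
        test_accuracy=_acc(test_idx),
        train_index=np.sort(train_idx),
        test_index=np.sort(test_idx),
        features=list(features),
    )
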