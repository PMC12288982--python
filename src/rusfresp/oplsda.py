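"""LASSO-regularized OPLS-DA with signed VIP scores, repeated cross-validation,
permutation-null testing, and cross-cohort transfer.

Orthogonal projections to latent structures discriminant analysis (OPLS-DA)
splits the predictor variation into a single class-predictive latent variable
(LV1) and ``n_ortho`` class-orthogonal components (LV2+).  The class vector is
encoded ±1 and centered; per orthogonal component the algorithm computes the
predictive weight w ∝ Xᵀy, extracts the loading direction orthogonal to w,
and deflates X by the orthogonal component before the final predictive fit.

LASSO (L1-penalized least squares on the encoded class) is used purely for
feature selection upstream of the OPLS-DA fit; λ is chosen by cross-validated
squared error over a log-spaced grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateLabelError,
    SchemaError,
    TransferError,
    ValidationError,
)

_TOL = 1e-12


import contextlib
import warnings as _warnings

from sklearn.exceptions import ConvergenceWarning


@contextlib.contextmanager
def _silence_convergence():
    # coordinate descent at the small-λ end of the path may hit max_iter;
    # the selected support is stable well before full convergence
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        yield


# ---------------------------------------------------------------------------
# LASSO feature selection


def lasso_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 30,
) -> list[str]:
    """Features with nonzero LASSO coefficients at the CV-optimal penalty.

    The ±1-encoded class vector is centered and regressed on column-
    standardized X; λ minimizing mean cross-validated squared error wins.
    If the winning λ selects nothing, the largest λ selecting at least one
    feature is used instead.
    """
    ynum = _encode_labels(np.asarray(y))[0]
    Xs, _, _ = _standardize(X.to_numpy(float), unit_variance=True)
    yc = ynum - ynum.mean()
    n = len(yc)
    if lambda_grid is None:
        lam_max = np.abs(Xs.T @ yc).max() / n
        lambda_grid = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.zeros((cv_folds, len(lambda_grid)))
    with np.errstate(all="ignore"), _silence_convergence():
        for i, (tr, va) in enumerate(splitter.split(Xs, ynum)):
            _, coefs, _ = lasso_path(Xs[tr], yc[tr], alphas=lambda_grid, max_iter=5000)
            resid = yc[va][:, None] - Xs[va] @ coefs
            mse[i] = (resid**2).mean(axis=0)
        best = int(np.argmin(mse.mean(axis=0)))

        _, coefs_full, _ = lasso_path(Xs, yc, alphas=lambda_grid, max_iter=5000)
    nonzero = np.abs(coefs_full) > _TOL
    chosen = nonzero[:, best]
    if not chosen.any():
        with_any = np.flatnonzero(nonzero.any(axis=0))
        if len(with_any) == 0:
            # degenerate data: fall back to the single best-correlated feature
            chosen = np.zeros(Xs.shape[1], bool)
            chosen[int(np.argmax(np.abs(Xs.T @ yc)))] = True
        else:
            chosen = nonzero[:, with_any[0]]
    return [f for f, c in zip(X.columns, chosen) if c]


# ---------------------------------------------------------------------------
# OPLS-DA model


@dataclass
class OplsdaModel:
    features: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    w: np.ndarray  # predictive weights, unit norm
    t: np.ndarray  # training predictive scores
    p: np.ndarray  # predictive loadings
    c: float  # y-loading
    orthogonal: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (w_o, t_o, p_o)
    encoding: dict[str, int]  # label -> ±1
    unit_variance: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def n_ortho(self) -> int:
        return len(self.orthogonal)

    def decode(self, signs: np.ndarray) -> np.ndarray:
        inv = {v: k for k, v in self.encoding.items()}
        return np.asarray([inv[int(s)] for s in signs])

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "features": self.features,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "c": self.c,
            "orthogonal": [
                {"w_o": w.tolist(), "p_o": p.tolist()} for w, _, p in self.orthogonal
            ],
            "encoding": self.encoding,
            "unit_variance": self.unit_variance,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OplsdaModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            features=doc["features"],
            mean_=np.asarray(doc["mean"]),
            scale_=np.asarray(doc["scale"]),
            w=np.asarray(doc["w"]),
            t=np.empty(0),
            p=np.asarray(doc["p"]),
            c=float(doc["c"]),
            orthogonal=[
                (np.asarray(o["w_o"]), np.empty(0), np.asarray(o["p_o"]))
                for o in doc["orthogonal"]
            ],
            encoding={k: int(v) for k, v in doc["encoding"].items()},
            unit_variance=bool(doc["unit_variance"]),
        )


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, dict[str, int]]:
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise DegenerateLabelError(f"need exactly two classes, got {classes}")
    encoding = {str(classes[0]): -1, str(classes[1]): 1}
    return np.where(y == classes[0], -1.0, 1.0), encoding


def _standardize(
    X: np.ndarray, unit_variance: bool, mean: np.ndarray | None = None, scale: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if mean is None:
        mean = X.mean(axis=0)
    if scale is None:
        if unit_variance:
            scale = X.std(axis=0, ddof=1)
            scale = np.where(scale > 0, scale, 1.0)
        else:
            scale = np.ones(X.shape[1])
    return (X - mean) / scale, mean, scale


def fit_oplsda(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_ortho: int = 1,
    unit_variance: bool = True,
) -> OplsdaModel:
    """Fit OPLS-DA on the given (already feature-selected) table.

    ``unit_variance=True`` auto-scales columns (biomarker convention);
    ``False`` centers only (composition convention, since proportions share
    a scale).
    """
    ynum, encoding = _encode_labels(np.asarray(y))
    if min((ynum == -1).sum(), (ynum == 1).sum()) < 2:
        raise ValidationError("need >= 2 samples per class")
    if X.shape[1] < 1:
        raise ValidationError("need >= 1 selected feature")
    Xs, mean, scale = _standardize(X.to_numpy(float), unit_variance)
    yc = ynum - ynum.mean()

    notes: list[str] = []
    Xd = Xs.copy()
    orthogonal: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for _ in range(n_ortho):
        w = Xd.T @ yc
        w = w / np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo <= 1e-10 * max(np.linalg.norm(p), 1.0):
            notes.append(
                "orthogonal weight numerically zero; model stored with "
                f"{len(orthogonal)} orthogonal component(s)"
            )
            break
        w_o = w_o / norm_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        orthogonal.append((w_o, t_o, p_o))
        Xd = Xd - np.outer(t_o, p_o)

    w = Xd.T @ yc
    w = w / np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    return OplsdaModel(
        features=list(X.columns),
        mean_=mean,
        scale_=scale,
        w=w,
        t=t,
        p=p,
        c=c,
        orthogonal=orthogonal,
        encoding=encoding,
        unit_variance=unit_variance,
        warnings=notes,
    )


def predict(model: OplsdaModel, X_new: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and decision scores for new samples.

    New data is scaled with the training parameters, each stored orthogonal
    component is removed sequentially, and the decision score is c·(Xw); the
    label is the sign of the score mapped back through the class encoding
    (an exact zero goes to the class encoded +1).
    """
    missing = [f for f in model.features if f not in X_new.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    X = X_new[model.features].to_numpy(float)
    Xs = (X - model.mean_) / model.scale_
    for w_o, _, p_o in model.orthogonal:
        t_o_new = Xs @ w_o
        Xs = Xs - np.outer(t_o_new, p_o)
    scores = model.c * (Xs @ model.w)
    signs = np.where(scores >= 0, 1, -1)
    return model.decode(signs), scores


def vip_scores(model: OplsdaModel) -> pd.DataFrame:
    """Signed variable-importance-in-projection scores for the predictive LV.

    magnitudeⱼ = √m·|wⱼ|/‖w‖ over the m selected features, so the mean squared
    magnitude is exactly 1; the sign is the sign of the predictive loading,
    orienting each feature toward the class it associates with.  Sorted by
    magnitude descending.
    """
    m = len(model.features)
    mags = np.sqrt(m) * np.abs(model.w) / np.linalg.norm(model.w)
    signs = np.where(model.p >= 0, 1, -1)
    out = pd.DataFrame(
        {
            "feature": model.features,
            "vip": mags,
            "sign": signs,
            "signed_vip": mags * signs,
        }
    )
    return out.sort_values("vip", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Repeated cross-validation and permutation testing


@dataclass
class CvResult:
    accuracies: list[float]
    mean_accuracy: float
    folds: int
    repetitions: int
    seed: int


def _cv_accuracy_once(
    X: pd.DataFrame,
    ynum: np.ndarray,
    labels: np.ndarray,
    folds: int,
    rep_seed: int,
    nested_selection: bool,
    preselected: list[str] | None,
    n_ortho: int,
    unit_variance: bool,
    lasso_folds: int,
) -> float:
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
    correct = 0
    for fold_i, (tr, te) in enumerate(splitter.split(X, ynum)):
        X_tr, y_tr = X.iloc[tr], labels[tr]
        if nested_selection:
            feats = lasso_select(X_tr, y_tr, cv_folds=lasso_folds, seed=rep_seed + fold_i)
        else:
            feats = preselected
        model = fit_oplsda(X_tr[feats], y_tr, n_ortho=n_ortho, unit_variance=unit_variance)
        pred, _ = predict(model, X.iloc[te])
        correct += int((pred == labels[te]).sum())
    return correct / len(labels)


def repeated_cv(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    folds: int = 5,
    repetitions: int = 1000,
    seed: int = 0,
    nested_selection: bool = True,
    n_ortho: int = 1,
    unit_variance: bool = True,
    lasso_folds: int = 5,
) -> CvResult:
    """Stratified k-fold CV of the selection+OPLS-DA pipeline, repeated.

    With ``nested_selection`` the LASSO step reruns inside every training
    fold (no selection leakage); otherwise features are selected once on the
    full data before the folds are cut, mirroring a non-nested pipeline.
    """
    labels = np.asarray(y)
    ynum, _ = _encode_labels(labels)
    counts = [int((ynum == v).sum()) for v in (-1, 1)]
    if min(counts) < folds:
        raise ValidationError(f"each class needs >= {folds} samples, got {counts}")
    preselected = None
    if not nested_selection:
        preselected = lasso_select(X, labels, cv_folds=lasso_folds, seed=seed)
    rng = np.random.default_rng(seed)
    accs = [
        _cv_accuracy_once(
            X,
            ynum,
            labels,
            folds,
            int(rng.integers(2**31 - 1)),
            nested_selection,
            preselected,
            n_ortho,
            unit_variance,
            lasso_folds,
        )
        for _ in range(repetitions)
    ]
    return CvResult(
        accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        folds=folds,
        repetitions=repetitions,
        seed=seed,
    )


@dataclass
class PermutationResult:
    observed_accuracy: float
    permuted_accuracies: list[float]
    p_value: float
    n_permutations: int


def permutation_test(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    folds: int = 5,
    inner_repetitions: int = 10,
    nested_selection: bool = False,
    n_ortho: int = 1,
    unit_variance: bool = True,
) -> PermutationResult:
    """Label-permutation null for the full selection+fit+CV pipeline.

    Each permutation shuffles the class labels (sizes preserved), reruns the
    complete pipeline at ``inner_repetitions`` CV repetitions, and records the
    mean CV accuracy.  The observed accuracy uses the same inner settings so
    observed and null values are exchangeable under the null hypothesis.
    p = (1 + #{permuted ≥ observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = np.asarray(y)
    rng = np.random.default_rng(seed)

    def _run(lab: np.ndarray, run_seed: int) -> float:
        return repeated_cv(
            X,
            lab,
            folds=folds,
            repetitions=inner_repetitions,
            seed=run_seed,
            nested_selection=nested_selection,
            n_ortho=n_ortho,
            unit_variance=unit_variance,
        ).mean_accuracy

    observed = _run(labels, int(rng.integers(2**31 - 1)))
    permuted = [
        _run(rng.permutation(labels), int(rng.integers(2**31 - 1))) for _ in range(n_perm)
    ]
    count = int(sum(a >= observed for a in permuted))
    return PermutationResult(
        observed_accuracy=observed,
        permuted_accuracies=permuted,
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# Cross-cohort transfer


@dataclass
class TransferResult:
    labels: np.ndarray
    scores: np.ndarray
    accuracy: float | None
    feature_overlap: float


def transfer_predict(
    model: OplsdaModel,
    X_other: pd.DataFrame,
    y_true: pd.Series | np.ndarray | None = None,
) -> TransferResult:
    """Apply a trained model to a second cohort's composition matrix.

    Model features absent from the new cohort are imputed at the training
    mean (zero after scaling); extra cohort features are ignored.  Reports
    the fraction of model features present in the new cohort, and accuracy
    when true labels are supplied.
    """
    present = [f for f in model.features if f in X_other.columns]
    if not present:
        raise TransferError("no shared features between model and new cohort")
    filled = pd.DataFrame(
        np.tile(model.mean_, (len(X_other), 1)),
        index=X_other.index,
        columns=model.features,
    )
    filled[present] = X_other[present].to_numpy(float)
    labels, scores = predict(model, filled)
    accuracy = None
    if y_true is not None:
        accuracy = float((labels == np.asarray(y_true)).mean())
    return TransferResult(
        labels=labels,
        scores=scores,
        accuracy=accuracy,
        feature_overlap=len(present) / len(model.features),
    )
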