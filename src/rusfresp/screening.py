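"""Univariate biomarker screening, PCA, and inflamed-outlier flagging.

Group contrasts use two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg
correction across the screened features; categorical contrasts use Pearson's
χ² without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import BiomarkerTable, GroupLabel
from .errors import (
    ConfigurationError,
    DegenerateTableError,
    InsufficientDataError,
    ValidationError,
)

#: Markers of systemic inflammation used for outlier flagging (config-exposed).
DEFAULT_INFLAMMATION_MARKERS = ("CRP", "AGP", "IL-6", "TNF-a", "IFN-g", "IL-1b")

EXACT_WILCOXON_MAX_N = 10


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or len(p) == 0 or ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must be a non-empty 1-D array in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_bh(
    table: pd.DataFrame, labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-feature two-sided rank-sum test with BH correction.

    Uses the exact null distribution when both groups have ≤ 10 observations
    and no ties, and the tie-corrected normal approximation otherwise.
    Returns a DataFrame (feature, statistic, p, q, direction) where direction
    names the group with the larger rank sum.
    """
    labels = pd.Series(np.asarray(labels), index=table.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly two groups, got {groups}")
    a_mask = (labels == groups[0]).to_numpy()
    b_mask = (labels == groups[1]).to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise InsufficientDataError("each group needs >= 2 observations")

    rows = []
    for feature in table.columns:
        x = table[feature].to_numpy(float)[a_mask]
        y = table[feature].to_numpy(float)[b_mask]
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if len(x) <= EXACT_WILCOXON_MAX_N and len(y) <= EXACT_WILCOXON_MAX_N and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
            stat, p = float(len(x) * len(y) / 2), 1.0  # all values identical
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        direction = str(groups[0]) if np.median(x) > np.median(y) else str(groups[1])
        rows.append((feature, stat, p, direction))

    out = pd.DataFrame(rows, columns=["feature", "statistic", "p", "direction"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["feature", "statistic", "p", "q", "direction"]]


def chisq_categorical(counts: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Pearson χ² (no continuity correction) on an r x c contingency table."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    if arr.sum() <= 0 or (arr < 0).any():
        raise ValidationError("contingency counts must be non-negative with positive total")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise DegenerateTableError("a zero marginal gives zero expected cells")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    dropped_features: list[str]


def pca_features(table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Centered (optionally unit-variance scaled) PCA via SVD.

    Sign convention: within each component the largest-magnitude loading is
    positive, so results are deterministic.  Zero-variance features are
    dropped with a warning when standardizing.
    """
    if table.isna().to_numpy().any():
        raise ValidationError("PCA requires a complete table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 features")
    X = table.to_numpy(float)
    cols = list(table.columns)
    dropped: list[str] = []
    sd = X.std(axis=0, ddof=1)
    if standardize and (sd == 0).any():
        dropped = [c for c, s in zip(cols, sd) if s == 0]
        warnings.warn(f"dropping zero-variance features before scaling: {dropped}")
        keep = sd > 0
        X, cols, sd = X[:, keep], [c for c, k in zip(cols, keep) if k], sd[keep]
    X = X - X.mean(axis=0)
    if standardize:
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: flip each component so its largest |loading| is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = X @ vt.T
    var = s**2 / (X.shape[0] - 1)
    evr = var / X.var(axis=0, ddof=1).sum()
    names = [f"PC{i + 1}" for i in range(vt.shape[0])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=names),
        loadings=pd.DataFrame(vt.T, index=cols, columns=names),
        explained_variance_ratio=evr,
        dropped_features=dropped,
    )


@dataclass
class OutlierFlags:
    """Per-sample inflamed-outlier call with its two score components."""

    flags: pd.Series  # boolean, indexed like the table
    composite_score: pd.Series
    distance_score: pd.Series
    composite_cutoff: float
    distance_cutoff: float


def flag_inflamed_outliers(
    biomarkers: BiomarkerTable,
    labels: pd.Series,
    inflammation_markers: tuple[str, ...] = DEFAULT_INFLAMMATION_MARKERS,
    percentile: float = 95.0,
) -> OutlierFlags:
    """Flag systemically inflamed nonresponders.

    A nonresponder is flagged when BOTH (a) its composite inflammation score
    (mean z-score over the inflammation marker panel, standardized against the
    control group) and (b) its Euclidean distance from the control centroid in
    the first two PCA components exceed the given percentile of the control
    distribution.  Controls and responders are never flagged.
    """
    df = biomarkers.data
    labels = pd.Series(np.asarray(labels), index=df.index)
    missing = [m for m in inflammation_markers if m not in df.columns]
    if missing:
        raise ConfigurationError(f"inflammation markers absent from table: {missing}")
    control = labels == "control"
    if not control.any():
        raise ValidationError("control group is empty")

    panel = df[list(inflammation_markers)]
    mu = panel[control].mean(axis=0)
    sd = panel[control].std(axis=0, ddof=1).replace(0.0, 1.0)
    composite = ((panel - mu) / sd).mean(axis=1)

    pca = pca_features(df, standardize=True)
    pc12 = pca.scores.iloc[:, :2]
    centroid = pc12[control.to_numpy()].mean(axis=0)
    distance = np.sqrt(((pc12 - centroid) ** 2).sum(axis=1))

    comp_cut = float(np.percentile(composite[control.to_numpy()], percentile))
    dist_cut = float(np.percentile(distance[control.to_numpy()], percentile))
    flags = (
        (labels == "nonresponder")
        & (composite > comp_cut)
        & (distance > dist_cut)
    )
    return OutlierFlags(
        flags=flags,
        composite_score=composite,
        distance_score=distance,
        composite_cutoff=comp_cut,
        distance_cutoff=dist_cut,
    )


def write_screen_result(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)
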