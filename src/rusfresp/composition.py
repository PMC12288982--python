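"""Compositional microbiome analysis: relative abundance, taxon aggregation,
alpha/beta diversity, NMDS ordination, PERMANOVA, multi-level composition
matrices, and correlation-edge extraction.

Diversity conventions: richness is the count of taxa with nonzero counts;
Simpson diversity is the Gini-Simpson index 1 − Σpᵢ² (the probability two
randomly drawn reads belong to different taxa).  Beta diversity is
Bray-Curtis on raw counts; no rarefaction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .data_io import UNASSIGNED, AsvCountTable, TaxonomyMap
from .errors import EmptySampleError, ValidationError


def _check_no_empty_rows(counts: AsvCountTable) -> None:
    totals = counts.total_reads
    empty = totals[totals == 0]
    if len(empty):
        raise EmptySampleError(f"samples with zero total reads: {list(empty.index)}")


def relative_abundance(counts: AsvCountTable, percent: bool = False) -> pd.DataFrame:
    """Counts divided by row totals (x100 when ``percent``)."""
    _check_no_empty_rows(counts)
    comp = counts.data.div(counts.total_reads, axis=0)
    return comp * 100.0 if percent else comp


def aggregate_taxa(
    counts: AsvCountTable, taxonomy: TaxonomyMap, rank: str
) -> AsvCountTable:
    """Sum ASV counts sharing a rank label; unmapped ASVs pool under "unassigned".

    Column order is deterministic: descending grand total, then name.
    """
    labels = taxonomy.rank_labels(counts.features, rank)
    agg = counts.data.T.groupby(labels.to_numpy()).sum().T
    order = sorted(agg.columns, key=lambda c: (-agg[c].sum(), c))
    return AsvCountTable(agg[order])


def alpha_diversity(counts: AsvCountTable) -> pd.DataFrame:
    """Per-sample observed richness S and Gini-Simpson diversity D = 1 − Σpᵢ²."""
    _check_no_empty_rows(counts)
    p = relative_abundance(counts)
    return pd.DataFrame(
        {
            "richness": (counts.data > 0).sum(axis=1).astype(int),
            "simpson": 1.0 - (p**2).sum(axis=1),
        }
    )


def bray_curtis(counts: AsvCountTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = 1 − 2Σmin(x,y)/(Σx+Σy)."""
    if isinstance(counts, AsvCountTable):
        _check_no_empty_rows(counts)
        df = counts.data
    else:
        df = counts
        if (df.sum(axis=1) == 0).any():
            raise EmptySampleError("samples with zero totals")
    if len(df) < 2:
        raise ValidationError("Bray-Curtis needs >= 2 samples")
    d = squareform(pdist(df.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _validate_dissimilarity(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValidationError("dissimilarity matrix must have a zero diagonal")
    return arr


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centered
    stress: float  # final Kruskal stress-1
    n_iter: int
    stress_path: list[float]


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals)


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Initialized from classical metric scaling, then alternates isotonic
    regression of configuration distances on dissimilarity ranks with a
    Guttman-transform update.  Iteration stops when stress fails to improve
    by ``tol`` (recorded stress values are non-increasing by construction)
    or at ``max_iter``.  The seed only perturbs degenerate (duplicate-point)
    initializations, so results are deterministic.
    """
    arr = _validate_dissimilarity(d)
    n = arr.shape[0]
    if n < 4:
        raise ValidationError("NMDS needs >= 4 samples")
    iu = np.triu_indices(n, 1)
    delta = arr[iu]
    order = np.argsort(delta, kind="stable")

    x = _classical_mds(arr, k)
    if np.allclose(x, 0):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=1e-6, size=(n, k))

    iso = IsotonicRegression(increasing=True)

    def _dists(conf: np.ndarray) -> np.ndarray:
        return pdist(conf)

    def _stress(dist: np.ndarray, dhat: np.ndarray) -> float:
        denom = float((dist**2).sum())
        if denom == 0:
            return 0.0
        return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))

    dist = _dists(x)
    dhat = iso.fit_transform(np.arange(len(delta)), dist[order])[np.argsort(order, kind="stable")]
    stress = _stress(dist, dhat)
    path = [stress]
    it = 0
    for it in range(1, max_iter + 1):
        # Guttman transform with current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        bmat = squareform(-ratio)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x_new = bmat @ x / n
        dist_new = _dists(x_new)
        dhat_new = iso.fit_transform(np.arange(len(delta)), dist_new[order])[
            np.argsort(order, kind="stable")
        ]
        stress_new = _stress(dist_new, dhat_new)
        if stress_new > stress - tol:
            if stress_new < stress:  # keep a final marginal improvement
                x, stress = x_new, stress_new
                path.append(stress_new)
            break
        x, dist, dhat, stress = x_new, dist_new, dhat_new, stress_new
        path.append(stress)

    x = x - x.mean(axis=0)
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    coords = pd.DataFrame(x, index=index, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=coords, stress=stress, n_iter=it, stress_path=path)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Permutational MANOVA pseudo-F with a label-permutation p-value.

    p = (1 + #{permuted F ≥ observed F}) / (1 + n_perm), so p is never zero.
    """
    arr = _validate_dissimilarity(d)
    labels = np.asarray(labels)
    if len(labels) != arr.shape[0]:
        raise ValidationError("labels must match the distance matrix")
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    if (np.bincount(codes) < 2).any():
        raise ValidationError("every group needs >= 2 samples")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    d2 = arr**2
    observed = _pseudo_f(d2, codes, len(groups))
    rng = np.random.default_rng(seed)
    count = 0
    # tie tolerance: permutations recreating the observed grouping must count
    # as >= despite summation-order rounding
    cut = observed - 1e-9 * max(1.0, abs(observed))
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(groups)) >= cut:
            count += 1
    return PermanovaResult(
        pseudo_f=float(observed),
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
    )


def multilevel_composition(
    counts: AsvCountTable, taxonomy: TaxonomyMap, ranks: tuple[str, ...] = ("phylum", "class", "family")
) -> pd.DataFrame:
    """Percent composition at several ranks, concatenated column-wise.

    Column names are rank-prefixed ("class:Negativicutes"); each rank block
    row-sums to 100.  This is the cross-cohort transfer representation.
    """
    blocks = []
    for rank in ranks:
        agg = aggregate_taxa(counts, taxonomy, rank)
        pct = relative_abundance(agg, percent=True)
        pct.columns = [f"{rank}:{c}" for c in pct.columns]
        blocks.append(pct)
    return pd.concat(blocks, axis=1)


def correlation_edges(
    composition: pd.DataFrame,
    anchors: list[str],
    r_threshold: float = 0.7,
    method: str = "pearson",
) -> pd.DataFrame:
    """Features correlated with model-selected anchors beyond |r| > threshold.

    LASSO hides features collinear with a selected driver; this recovers them
    as (anchor, feature, r) edges sorted by |r| descending.
    """
    missing = [a for a in anchors if a not in composition.columns]
    if missing:
        raise ValidationError(f"anchors absent from composition: {missing}")
    corr = composition.corr(method=method)
    rows = []
    for anchor in anchors:
        if composition[anchor].std(ddof=0) == 0:
            warnings.warn(f"anchor {anchor!r} has zero variance; no edges emitted")
            continue
        r = corr[anchor].drop(index=anchor)
        r = r[r.abs() > r_threshold].dropna()
        rows.extend((anchor, feat, float(val)) for feat, val in r.items())
    out = pd.DataFrame(rows, columns=["anchor", "feature", "r"])
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
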