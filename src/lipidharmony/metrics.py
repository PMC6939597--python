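"""Evaluation metrics for cross-method comparability.

Cross-method CoV pools the replicate-level values of a lipid across all
methods (e.g. 5 replicates × 3 methods = one 15-vector) and reports SD/mean.
Fold-from-average expresses each method's mean as a ratio to the unweighted
cross-method mean, so the ratios of a lipid average to 1 by construction.
PCA follows the no-transformation, no-scaling convention (mean centering
only); scores come from an SVD with the sign of each component fixed so its
largest-magnitude loading is positive.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ConcentrationTable, Role

__all__ = [
    "cross_method_cov",
    "fold_from_average",
    "pca_scores",
    "pairwise_correlation",
    "centroid_separation",
]


def _pooled_frame(
    tables: Mapping[str, ConcentrationTable], role: str = Role.STUDY,
    sample: str | None = None,
) -> pd.DataFrame:
    """Concatenate per-method study columns; columns are (method, injection)."""
    pieces = {}
    for method, table in tables.items():
        cols = table.columns_with_role(role)
        if sample is not None:
            meta = table.injections.loc[cols]
            cols = [c for c in cols if meta.loc[c, "sample"] == sample]
        pieces[method] = table.values[cols]
    return pd.concat(pieces, axis=1)


def cross_method_cov(
    tables: Mapping[str, ConcentrationTable],
    role: str = Role.STUDY,
    sample: str | None = None,
) -> pd.Series:
    """Per-lipid CoV over the pooled replicate values of all methods.

    Pairwise-complete: missing values are ignored.  Lipids present in fewer
    than two methods, or with fewer than two values overall, are missing.
    """
    if len(tables) < 2:
        raise ValueError("need at least two methods")
    frame = _pooled_frame(tables, role, sample)
    out = {}
    for lipid, row in frame.iterrows():
        per_method_present = row.groupby(level=0).apply(lambda s: s.notna().any())
        vals = row.dropna().to_numpy(dtype=float)
        if per_method_present.sum() < 2 or vals.size < 2 or vals.mean() <= 0:
            out[lipid] = np.nan
        else:
            out[lipid] = vals.std(ddof=1) / vals.mean()
    return pd.Series(out, name="cross_method_cov")


def fold_from_average(
    tables: Mapping[str, ConcentrationTable],
    role: str = Role.STUDY,
    sample: str | None = None,
) -> pd.DataFrame:
    """Per-lipid ratio of each method's mean to the cross-method mean.

    The cross-method mean is the unweighted mean of the method means, so each
    lipid's row of ratios averages to 1.  Lipids present in fewer than two
    methods, or with zero cross-method mean, are missing.
    """
    frame = _pooled_frame(tables, role, sample)
    method_means = frame.T.groupby(level=0).mean().T  # lipid × method
    n_methods = method_means.notna().sum(axis=1)
    grand = method_means.mean(axis=1)
    ratios = method_means.div(grand, axis=0)
    ratios[(n_methods < 2) | ~(grand > 0)] = np.nan
    return ratios


def pca_scores(
    matrix: pd.DataFrame | np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and explained-variance fractions of a samples × variables matrix.

    The matrix is column-mean-centered (no variance scaling, no
    transformation) and decomposed by SVD; scores are the projections onto
    the right singular vectors.  Each component's sign is chosen so that its
    largest-magnitude loading is positive.  Missing values are not accepted —
    restrict to complete variables first.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input must have no missing values")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        import warnings

        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    # sign convention: largest-|loading| entry of each right singular vector > 0
    for j in range(n_components):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :n_components] * s[:n_components]
    total_var = np.sum(s**2)
    explained = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return scores, explained


def pairwise_correlation(
    x, y, scale: str = "linear"
) -> tuple[float, int]:
    """Pearson correlation of paired values, optionally on log10 scale.

    On log scale, pairs with a non-positive member are dropped.  Returns
    (coefficient, number of pairs used); fewer than three usable pairs →
    (NaN, n).
    """
    if scale not in ("linear", "log10"):
        raise ValueError("scale must be 'linear' or 'log10'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if scale == "log10":
        keep &= (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return float("nan"), int(x.size)
    if scale == "log10":
        x, y = np.log10(x), np.log10(y)
    r, _ = stats.pearsonr(x, y)
    return float(r), int(x.size)


def centroid_separation(
    scores: np.ndarray, labels: Sequence[str]
) -> float:
    """Between-group centroid distance over mean within-group spread.

    Groups are the distinct labels (e.g. methods).  The numerator is the mean
    pairwise distance between group centroids; the denominator the mean
    distance of samples to their own group centroid.  Large values mean the
    grouping dominates the score space.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    centroids = {g: scores[labels == g].mean(axis=0) for g in groups}
    between = [
        np.linalg.norm(centroids[a] - centroids[b])
        for i, a in enumerate(groups)
        for b in groups[i + 1:]
    ]
    within = [
        np.linalg.norm(row - centroids[g])
        for g in groups
        for row in scores[labels == g]
    ]
    denom = np.mean(within)
    if denom == 0:
        return float("inf")
    return float(np.mean(between) / denom)
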