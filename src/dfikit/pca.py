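"""PCA diagnostics of the harmonised CBC matrix.

Variance explained per component, component-score statistics against age
(correlation and the growth of score variance with age, the signature of a
stochastic latent process), and agglomerative clustering of features by
absolute Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.decomposition import PCA

from .harmonize import FeatureMatrix

__all__ = ["PCAResult", "fit_pca", "pc_age_stats", "cluster_features"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # (n_features, k), orthonormal columns
    scores: np.ndarray  # (n_samples, k)
    variance_fraction: np.ndarray  # (k,), non-increasing
    standardized: bool = False

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(np.diff(vf) > 1e-10):
            raise ValueError("variance_fraction must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to <= 1")


def fit_pca(
    matrix: FeatureMatrix | np.ndarray,
    standardize: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Principal components of the (optionally standardised) feature matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making the result deterministic across platforms.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than features (n={n}, p={p})")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Xw = (X - X.mean(axis=0)) / sd
    else:
        Xw = X - X.mean(axis=0)

    rank = np.linalg.matrix_rank(np.cov(Xw, rowvar=False))
    k = n_components if n_components is not None else p
    if rank < k:
        warnings.warn(
            f"rank-deficient input: reducing components from {k} to {rank}",
            RuntimeWarning,
            stacklevel=2,
        )
        k = rank

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xw)
    loadings = pca.components_.T.copy()  # (p, k)
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        standardized=standardize,
    )


def pc_age_stats(
    result: PCAResult,
    ages: np.ndarray,
    age_groups: np.ndarray | None = None,
) -> dict:
    """Per-component age statistics.

    Returns a dict with

    - ``corr``: DataFrame (pc, pearson_r, p) — NaN r where the score is
      constant (correlation undefined, reported as such);
    - ``group_variance``: DataFrame (pc, group_mid_age, variance);
    - ``variance_trend``: DataFrame (pc, spearman_rho, p) of per-group
      variance against group age.
    """
    ages = np.asarray(ages, dtype=float)
    scores = result.scores
    if ages.size != scores.shape[0]:
        raise ValueError("ages must align with score rows")
    if age_groups is None:
        qs = np.quantile(ages, [0.0, 0.25, 0.5, 0.75, 1.0])
        age_groups = np.unique(qs)
    age_groups = np.asarray(age_groups, dtype=float)

    corr_rows, var_rows, trend_rows = [], [], []
    bins = np.clip(np.digitize(ages, age_groups[1:-1]), 0, len(age_groups) - 2)
    for j in range(scores.shape[1]):
        s = scores[:, j]
        if np.std(s) == 0 or np.std(ages) == 0:
            corr_rows.append({"pc": j, "pearson_r": np.nan, "p": np.nan})
        else:
            r, p = pearsonr(s, ages)
            corr_rows.append({"pc": j, "pearson_r": r, "p": p})
        mids, variances = [], []
        for b in range(len(age_groups) - 1):
            mask = bins == b
            if mask.sum() >= 2:
                mids.append(ages[mask].mean())
                variances.append(s[mask].var(ddof=1))
        for m, v in zip(mids, variances):
            var_rows.append({"pc": j, "group_mid_age": m, "variance": v})
        if len(mids) >= 3:
            rho, p = spearmanr(mids, variances)
            trend_rows.append({"pc": j, "spearman_rho": rho, "p": p})
        else:
            trend_rows.append({"pc": j, "spearman_rho": np.nan, "p": np.nan})
    return {
        "corr": pd.DataFrame(corr_rows),
        "group_variance": pd.DataFrame(var_rows),
        "variance_trend": pd.DataFrame(trend_rows),
    }


def cluster_features(
    matrix: FeatureMatrix | pd.DataFrame,
    scores: np.ndarray | None = None,
    score_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering with distance ``1 - |Pearson r|``.

    Optional component scores may be appended as extra columns.  Returns the
    scipy linkage matrix and the column labels in clustering order.
    Zero-variance columns are excluded with a warning.
    """
    if isinstance(matrix, FeatureMatrix):
        data = matrix.values
        labels = list(matrix.columns)
    else:
        data = matrix.to_numpy(dtype=float)
        labels = list(matrix.columns)
    if scores is not None:
        scores = np.atleast_2d(np.asarray(scores, float))
        if scores.shape[0] != data.shape[0]:
            scores = scores.T
        data = np.hstack([data, scores])
        labels = labels + (
            score_names
            if score_names is not None
            else [f"PC{j}" for j in range(scores.shape[1])]
        )
    sd = data.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        warnings.warn(
            f"excluding zero-variance column(s) {dropped}", RuntimeWarning,
            stacklevel=2,
        )
        data = data[:, keep]
        labels = [l for l, k in zip(labels, keep) if k]
    if data.shape[1] < 2:
        raise ValueError("need at least two non-constant columns")
    corr = np.corrcoef(data, rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    merge = linkage(squareform(dist, checks=False), method="average")
    return merge, labels
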