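"""PCA of the standardized neuron x feature matrix.

Columns are z-scored by default so loadings are comparable across features
with different units; components come sorted by decreasing explained
variance, with a deterministic sign convention (the largest-magnitude
loading in each component is positive) so biplots are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "pca_features", "metric_alignment"]


@dataclass
class PCAResult:
    scores: np.ndarray                  # neurons x components
    loadings: np.ndarray                # features x components (orthonormal)
    explained_variance_ratio: np.ndarray
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    row_mask: np.ndarray                # which input rows were kept (no NaN)
    dropped_features: list[str]

    @property
    def n_components_90(self) -> int:
        """Smallest number of components explaining >= 90% of the variance."""
        return int(np.searchsorted(
            np.cumsum(self.explained_variance_ratio), 0.9) + 1)

    def reconstruct(self) -> np.ndarray:
        """scores @ loadings.T — the standardized matrix when all components
        are retained."""
        return self.scores @ self.loadings.T


def pca_features(
    feature_matrix: pd.DataFrame | np.ndarray,
    standardize: bool = True,
    n_components: int | None = None,
    feature_names: list[str] | None = None,
) -> PCAResult:
    """PCA of a neurons x features matrix.

    Rows containing NaN are excluded (recorded in ``row_mask``);
    zero-variance features are dropped with a warning.  With ``standardize``
    each column is z-scored (ddof=1), making the decomposition an
    eigendecomposition of the feature correlation matrix.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        names = list(feature_matrix.columns)
        X = feature_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(feature_matrix, dtype=float)
        names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 neurons and 2 features")
    row_mask = ~np.any(np.isnan(X), axis=1)
    X = X[row_mask]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 complete rows after NaN exclusion")

    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    Z = X - means
    if standardize:
        Z = Z / sds

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    evr = pca.explained_variance_ratio_
    return PCAResult(
        scores=scores, loadings=loadings, explained_variance_ratio=evr,
        feature_names=names, feature_means=means, feature_sds=sds,
        row_mask=row_mask, dropped_features=dropped,
    )


def metric_alignment(
    result: PCAResult,
    feature: str,
    metric_values: np.ndarray,
    n_components: int = 2,
) -> float:
    """Correlation between a tuning metric and a feature's loading direction.

    Projects each neuron's first ``n_components`` PCA scores onto the unit
    loading direction of ``feature`` in that subspace and returns the
    Pearson correlation of the projections with ``metric_values`` (for the
    rows kept by the PCA).  A positive value means the metric increases
    along that feature's loading arrow in the biplot.
    """
    if feature not in result.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    j = result.feature_names.index(feature)
    direction = result.loadings[j, :n_components]
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("feature has a zero loading in the subspace")
    proj = result.scores[:, :n_components] @ (direction / norm)
    metric = np.asarray(metric_values, dtype=float)[result.row_mask]
    return float(np.corrcoef(proj, metric)[0, 1])
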