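"""PCA of treatment × parameter matrices with variance-explained reporting.

Growth traits mix incommensurate units (cm, g, %, SPAD), so the
default is correlation-matrix PCA: columns are centered and scaled to
unit variance before the singular value decomposition.  Component
signs follow a deterministic convention — the largest-magnitude
loading of each component is made positive — so repeated runs and
different LAPACK backends agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

__all__ = ["TraitPCA", "pca", "PcaResult"]


@dataclass
class PcaResult:
    scores: pd.DataFrame        # observations × components
    loadings: pd.DataFrame      # variables × components
    var_explained: np.ndarray   # fraction per component, non-increasing


class TraitPCA(BaseEstimator, TransformerMixin):
    """Correlation- (default) or covariance-matrix PCA.

    Parameters
    ----------
    standardize : bool, default True
        Scale columns to unit variance (correlation-matrix PCA).
        With ``standardize=True`` a zero-variance column is an error.
    n_components : int or None
        Components to retain (None = all).

    Attributes
    ----------
    loadings_ : variables × components array (orthonormal columns).
    var_explained_ : fraction of total variance per component.
    mean_, scale_ : per-column centering and scaling applied.
    """

    def __init__(self, standardize: bool = True, n_components: int | None = None):
        self.standardize = standardize
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        Xd = X if isinstance(X, pd.DataFrame) else None
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need a 2-D matrix with ≥2 observations and ≥2 variables")
        if np.isnan(arr).any():
            raise ValueError("missing values: impute before ordination")
        self.mean_ = arr.mean(axis=0)
        if self.standardize:
            scale = arr.std(axis=0, ddof=1)
            if (scale == 0).any():
                cols = (np.asarray(Xd.columns)[scale == 0].tolist()
                        if Xd is not None else np.flatnonzero(scale == 0).tolist())
                raise ValueError(
                    f"zero-variance column(s) cannot be standardized: {cols}")
            self.scale_ = scale
        else:
            self.scale_ = np.ones(arr.shape[1])
        Z = (arr - self.mean_) / self.scale_

        model = _SkPCA(n_components=self.n_components, svd_solver="full")
        scores = model.fit_transform(Z)
        loadings = model.components_.T
        # deterministic sign: largest-|loading| entry of each component > 0
        for k in range(loadings.shape[1]):
            j = np.argmax(np.abs(loadings[:, k]))
            if loadings[j, k] < 0:
                loadings[:, k] *= -1
                scores[:, k] *= -1
        self.loadings_ = loadings
        self.var_explained_ = model.explained_variance_ratio_
        self.n_features_in_ = arr.shape[1]
        self._columns = list(Xd.columns) if Xd is not None else None
        self._index = list(Xd.index) if Xd is not None else None
        return scores

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "loadings_"):
            raise ValueError("TraitPCA is not fitted")
        arr = np.asarray(X, dtype=float)
        return ((arr - self.mean_) / self.scale_) @ self.loadings_

    def result(self, X) -> PcaResult:
        """Fit on ``X`` and package scores/loadings/variance as DataFrames."""
        scores = self.fit_transform(X)
        comp = [f"PC{k + 1}" for k in range(scores.shape[1])]
        index = self._index if self._index is not None else range(scores.shape[0])
        cols = self._columns if self._columns is not None else range(self.n_features_in_)
        return PcaResult(
            scores=pd.DataFrame(scores, index=index, columns=comp),
            loadings=pd.DataFrame(self.loadings_, index=cols, columns=comp),
            var_explained=self.var_explained_.copy(),
        )


def pca(matrix, standardize: bool = True,
        n_components: int | None = None) -> PcaResult:
    """PCA of an observations × variables matrix; see :class:`TraitPCA`."""
    return TraitPCA(standardize=standardize,
                    n_components=n_components).result(matrix)
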