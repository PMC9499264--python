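"""Rank-based integrative evaluation matrix.

The scoring procedure merges heterogeneous per-treatment measurements
— growth-trait means, rhizosphere Shannon indices, counts of
upregulated genes — into one comparable score per treatment.  Each
parameter is ranked independently across the treatments that were
measured for it: the largest value receives the maximum score (the
number of ranked treatments), the smallest receives 1, and *tied
values all receive the maximum of their tied sort positions* (eight
tied smallest values out of twelve all score 8, not 4.5).  Scores are
summed per treatment and averaged over the number of available
parameters, so treatments tested on unequal parameter sets remain
comparable.  Untested cells ("n.t.") are excluded from both the total
and the mean's denominator.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["rank_scores", "build_score_matrix", "totals_and_means",
           "round_half_up", "TreatmentRanker"]


def rank_scores(values, n_conditions: int | None = None) -> np.ndarray:
    """Score a parameter's values across treatments by rank.

    The greatest value receives the highest score (= number of
    conditions); other values score by ascending sort position down to
    a minimum of 1.  Ties all take the maximum of their tied positions.

    Parameters
    ----------
    values : array-like of float, shape (n,)
        One measured value per treatment; no missing values.
    n_conditions : int, optional
        Expected length, for validation only.

    Returns
    -------
    numpy.ndarray of int, shape (n,)
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if n_conditions is not None and len(arr) != n_conditions:
        raise ValueError(
            f"expected {n_conditions} values, got {len(arr)}")
    if len(arr) < 2:
        raise ValueError("ranking needs at least 2 conditions")
    if np.isnan(arr).any():
        raise ValueError("missing values are handled at matrix level, "
                         "not by rank_scores")
    return rankdata(arr, method="max").astype(int)


def round_half_up(x: int | float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal (79/9 → 8.8)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def _ratio_half_up(num: int, den: int, decimals: int = 1) -> float:
    # exact rational → decimal, so 0.05-boundary ratios round correctly
    q = decimal.Decimal(1).scaleb(-decimals)
    with decimal.localcontext() as ctx:
        ctx.prec = 28
        val = decimal.Decimal(num) / decimal.Decimal(den)
    return float(val.quantize(q, rounding=decimal.ROUND_HALF_UP))


class TreatmentRanker(BaseEstimator, TransformerMixin):
    """Rank treatments per parameter and aggregate into an evaluation matrix.

    Fit on a treatments × parameters DataFrame of real-valued
    measurements (NaN marking untested cells).  The fitted estimator
    exposes the integer score matrix, per-treatment totals and
    (half-up rounded) means, and best/worst flags.

    Parameters
    ----------
    directions : dict, optional
        Per-parameter direction; ``+1`` (default) means greater is
        better, ``-1`` ranks descending.
    precision : int or None, default None
        If given, values are rounded to this many decimals before
        ranking (use the printed precision to reproduce published
        score tables built from rounded means).
    mean_decimals : int, default 1
        Decimals kept in the per-treatment mean (rounded half-up).

    Attributes
    ----------
    scores_ : DataFrame of Int64, treatments × parameters, NA = n.t.
    max_scores_ : Series, per parameter the number of ranked treatments.
    ranking_ : DataFrame with total, n_params, mean, is_highest, is_lowest.
    """

    def __init__(self, directions: dict | None = None,
                 precision: int | None = None, mean_decimals: int = 1):
        self.directions = directions
        self.precision = precision
        self.mean_decimals = mean_decimals

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate(X)
        directions = dict(self.directions or {})
        scores = pd.DataFrame(index=X.index, columns=X.columns, dtype="Int64")
        max_scores = {}
        for col in X.columns:
            vals = X[col]
            avail = vals.notna()
            n_avail = int(avail.sum())
            if n_avail < 2:
                raise ValueError(
                    f"parameter {col!r} has {n_avail} available treatment(s); "
                    "ranking needs at least 2")
            v = vals[avail].to_numpy(dtype=float)
            if self.precision is not None:
                v = np.round(v, self.precision)
            if directions.get(col, 1) < 0:
                v = -v
            scores.loc[avail, col] = rank_scores(v)
            max_scores[col] = n_avail
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.scores_ = scores
        self.max_scores_ = pd.Series(max_scores, name="max_score")
        self.ranking_ = totals_and_means(scores, mean_decimals=self.mean_decimals)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the score matrix for ``X`` (re-ranked with fit params)."""
        if not hasattr(self, "scores_"):
            raise ValueError("TreatmentRanker is not fitted")
        if X is None:
            return self.scores_
        return TreatmentRanker(**self.get_params()).fit(X).scores_

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).scores_

    @staticmethod
    def _validate(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("need at least 2 treatments")
        if X.shape[1] < 1:
            raise ValueError("need at least 1 parameter")
        return X.astype(float)


def build_score_matrix(values: pd.DataFrame, directions: dict | None = None,
                       precision: int | None = None) -> pd.DataFrame:
    """Score matrix (Int64, NA = n.t.) from a treatments × parameters table."""
    return TreatmentRanker(directions=directions,
                           precision=precision).fit(values).scores_


def totals_and_means(scores: pd.DataFrame, mean_decimals: int = 1) -> pd.DataFrame:
    """Per-treatment totals and means of an integer score matrix.

    The total sums available scores; the mean divides by the number of
    available parameters and is rounded half-up to ``mean_decimals``.
    The highest- and lowest-mean treatment(s) are flagged.
    """
    avail = scores.notna()
    total = scores.sum(axis=1, skipna=True).astype(int)
    n_params = avail.sum(axis=1).astype(int)
    if (n_params == 0).any():
        raise ValueError("treatment with no available parameters")
    mean = pd.Series(
        [_ratio_half_up(t, n, mean_decimals) for t, n in zip(total, n_params)],
        index=scores.index, dtype=float)
    out = pd.DataFrame({
        "total": total, "n_params": n_params, "mean": mean,
        "is_highest": mean == mean.max(),
        "is_lowest": mean == mean.min(),
    })
    return out
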