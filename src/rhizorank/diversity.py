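"""Alpha diversity and taxonomic relative abundance from OTU count tables.

Shannon diversity H' = −Σ pᵢ ln pᵢ (natural log by default; log2 by
flag) and the Chao-1 richness estimator, which extrapolates unseen
taxa from singleton (F1) and doubleton (F2) counts.  The
bias-corrected Chao-1 form

    S_chao1 = S_obs + F1·(F1 − 1) / (2·(F2 + 1))

is the default because it stays defined when no doubletons were
observed; the classic form S_obs + F1²/(2·F2) is selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LINEAGE_RANKS, OtuTable

__all__ = ["shannon", "chao1", "alpha_diversity", "relative_abundance",
           "AlphaDiversity"]


def _proportions(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    return arr / total


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity of one sample's counts, in nats by default.

    Zero-count taxa contribute nothing; ``base=2`` gives bits.
    """
    p = _proportions(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao-1 estimated richness of one sample's counts.

    With ``bias_corrected=False`` the classic form is used and F2 must
    be positive.
    """
    arr = np.asarray(counts)
    _proportions(arr)  # validates
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao-1 undefined when F2 = 0; "
                         "use bias_corrected=True")
    return s_obs + f1 * f1 / (2.0 * f2)


class AlphaDiversity(BaseEstimator, TransformerMixin):
    """Per-sample alpha-diversity summary as an sklearn-style transformer.

    ``transform`` maps a samples × taxa count matrix to a DataFrame
    with observed richness (S_obs), singleton/doubleton counts (F1,
    F2), Shannon diversity and Chao-1.  Stateless: ``fit`` only
    validates.

    Parameters
    ----------
    base : float or None, default None
        Logarithm base for Shannon (None = natural log).
    bias_corrected : bool, default True
        Chao-1 form.
    """

    def __init__(self, base: float | None = None, bias_corrected: bool = True):
        self.base = base
        self.bias_corrected = bias_corrected

    def fit(self, X, y=None):
        self.n_features_in_ = self._as_frame(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = self._as_frame(X)
        rows = {}
        for sample, counts in X.iterrows():
            arr = counts.to_numpy(dtype=float)
            rows[sample] = {
                "S_obs": int((arr > 0).sum()),
                "F1": int((arr == 1).sum()),
                "F2": int((arr == 2).sum()),
                "shannon": shannon(arr, base=self.base),
                "chao1": chao1(arr, bias_corrected=self.bias_corrected),
            }
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "sample_id"
        return out

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, OtuTable):
            return X.counts.T
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))


def alpha_diversity(table: OtuTable | pd.DataFrame, base: float | None = None,
                    bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample S_obs, F1, F2, Shannon and Chao-1 (samples × taxa input,
    or an :class:`OtuTable`)."""
    return AlphaDiversity(base=base, bias_corrected=bias_corrected).fit_transform(table)


def relative_abundance(table: OtuTable, rank: str = "phylum",
                       floor: float = 0.0) -> pd.DataFrame:
    """Relative abundance aggregated at a taxonomic rank, per sample.

    Counts are summed over all OTUs sharing the taxon name at ``rank``
    and divided by the sample's library size.  Taxa whose abundance
    stays below ``floor`` in every sample are pooled into ``"Other"``,
    mirroring the display floor of stacked-bar figures.  Unassigned
    OTUs keep their own ``"unassigned"`` bucket.

    Returns a taxa × samples DataFrame whose columns each sum to 1.
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {LINEAGE_RANKS}")
    grouped = table.counts.groupby(table.lineages[rank]).sum()
    props = grouped / grouped.sum(axis=0)
    if floor > 0:
        minor = (props.max(axis=1) < floor) & (props.index != "unassigned")
        if minor.any():
            other = props.loc[minor].sum(axis=0)
            props = props.loc[~minor]
            props.loc["Other"] = other
    props.index.name = rank
    return props


def rarefy(table: OtuTable, depth: int | None = None,
           seed: int | None = None) -> OtuTable:
    """Subsample every sample to equal depth without replacement.

    Off by default in the pipeline; provided for sensitivity checks.
    """
    rng = np.random.default_rng(seed)
    depth = depth or int(table.counts.sum(axis=0).min())
    new = {}
    for sample in table.counts.columns:
        col = table.counts[sample].to_numpy()
        if col.sum() < depth:
            raise ValueError(f"sample {sample!r} has fewer than {depth} reads")
        pool = np.repeat(np.arange(len(col)), col)
        keep = rng.choice(pool, size=depth, replace=False)
        new[sample] = np.bincount(keep, minlength=len(col))
    counts = pd.DataFrame(new, index=table.counts.index)
    return OtuTable(counts=counts, lineages=table.lineages.copy(),
                    sample_meta=table.sample_meta)
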