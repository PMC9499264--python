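"""Relative quantification of RT-qPCR data by the 2^−ΔΔCt method.

Per gene and sample, ΔCt = Ct_target − Ct_housekeeping; per treatment,
ΔΔCt = ΔCt_treatment − ΔCt_calibrator, and the fold change relative to
the calibrator is FC = 2^−ΔΔCt.  Technical replicates are collapsed by
arithmetic mean of their determined Ct values; biological replicates
are averaged on the ΔΔCt (log) scale by default, so the reported FC is
the geometric mean across replicates (arithmetic averaging on the FC
scale is selectable).  A gene is called *up* when FC ≥ 2 and *down*
when FC ≤ 0.5 — both thresholds inclusive — and *undetermined* when a
required Ct (target or housekeeping, in the sample or the calibrator)
is missing, i.e. was above the detection ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["collapse_tech_reps", "classify_fc", "count_upregulated",
           "DeltaDeltaCt", "fold_changes"]

UP_THRESHOLD = 2.0
DOWN_THRESHOLD = 0.5

_KEY = ["gene", "treatment", "timepoint", "bio_rep"]


def collapse_tech_reps(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over determined technical replicates, per biological replicate.

    Returns one row per (gene, treatment, timepoint, bio_rep) with the
    collapsed ``ct`` (NaN when every technical replicate was
    undetermined), the number of determined replicates ``n_tech`` and a
    ``partial`` flag marking cells where some but not all technical
    replicates were determined.
    """
    g = records.groupby(_KEY, sort=False)["ct"]
    out = g.agg(ct="mean", n_tech="count", n_total="size").reset_index()
    out["partial"] = (out["n_tech"] > 0) & (out["n_tech"] < out["n_total"])
    return out.drop(columns="n_total")


def classify_fc(fc: float) -> str:
    """up / down / unchanged / undetermined, thresholds inclusive."""
    if fc is None or np.isnan(fc):
        return "undetermined"
    if fc >= UP_THRESHOLD:
        return "up"
    if fc <= DOWN_THRESHOLD:
        return "down"
    return "unchanged"


class DeltaDeltaCt(BaseEstimator):
    """2^−ΔΔCt relative quantification as an sklearn-style estimator.

    Fit on a tidy Ct table (columns gene, treatment, timepoint,
    bio_rep, tech_rep, ct with NaN = undetermined, as produced by
    :func:`rhizorank.io.read_ct_table`).

    Parameters
    ----------
    housekeeping : str, default "18S"
        Reference gene used for ΔCt normalization.
    calibrator : str, default "Control"
        Treatment whose ΔCt anchors ΔΔCt; its own FC is exactly 1.
    fc_averaging : {"geometric", "arithmetic"}, default "geometric"
        How biological replicates are combined into one FC.

    Attributes
    ----------
    results_ : DataFrame with one row per (gene, treatment, timepoint):
        mean_dct, ddct, fc, status and n_bio_reps.
    calibrator_dct_ : DataFrame of calibrator ΔCt per (gene, timepoint).
    """

    def __init__(self, housekeeping: str = "18S", calibrator: str = "Control",
                 fc_averaging: str = "geometric"):
        self.housekeeping = housekeeping
        self.calibrator = calibrator
        self.fc_averaging = fc_averaging

    def fit(self, X: pd.DataFrame, y=None):
        if self.fc_averaging not in ("geometric", "arithmetic"):
            raise ValueError("fc_averaging must be 'geometric' or 'arithmetic'")
        if self.calibrator not in set(X["treatment"]):
            raise ValueError(f"calibrator {self.calibrator!r} absent from data")
        if self.housekeeping not in set(X["gene"]):
            raise ValueError(f"housekeeping gene {self.housekeeping!r} absent")

        cells = collapse_tech_reps(X)
        hk = (cells[cells["gene"] == self.housekeeping]
              .rename(columns={"ct": "hk_ct"})
              [["treatment", "timepoint", "bio_rep", "hk_ct"]])
        tgt = cells[cells["gene"] != self.housekeeping].copy()
        merged = tgt.merge(hk, on=["treatment", "timepoint", "bio_rep"],
                           how="left")
        # ΔCt per biological replicate; undetermined target or housekeeping
        # Ct leaves the replicate undetermined
        merged["dct"] = merged["ct"] - merged["hk_ct"]

        per_cell = (merged.groupby(["gene", "treatment", "timepoint"],
                                   sort=False)["dct"]
                    .agg(mean_dct="mean", n_bio_reps="count").reset_index())

        calib = (per_cell[per_cell["treatment"] == self.calibrator]
                 .rename(columns={"mean_dct": "calib_dct"})
                 [["gene", "timepoint", "calib_dct", "n_bio_reps"]]
                 .rename(columns={"n_bio_reps": "n_calib_reps"}))
        res = per_cell.merge(calib, on=["gene", "timepoint"], how="left")
        res.loc[res["n_bio_reps"] == 0, "mean_dct"] = np.nan
        res.loc[res.get("n_calib_reps", 0) == 0, "calib_dct"] = np.nan
        res["ddct"] = res["mean_dct"] - res["calib_dct"]

        if self.fc_averaging == "geometric":
            res["fc"] = 2.0 ** (-res["ddct"])
        else:
            rep = merged.merge(calib[["gene", "timepoint", "calib_dct"]],
                               on=["gene", "timepoint"], how="left")
            rep["fc_rep"] = 2.0 ** (-(rep["dct"] - rep["calib_dct"]))
            fc = (rep.groupby(["gene", "treatment", "timepoint"], sort=False)
                  ["fc_rep"].mean().rename("fc").reset_index())
            res = res.drop(columns=[c for c in res.columns if c == "fc"])
            res = res.merge(fc, on=["gene", "treatment", "timepoint"],
                            how="left")
        # under log-scale averaging the calibrator's own fold change is 1
        # by construction; pin it exactly so floating-point noise never
        # shifts its status
        own = res["treatment"] == self.calibrator
        res.loc[own & res["ddct"].notna(), "ddct"] = 0.0
        if self.fc_averaging == "geometric":
            res.loc[own & res["fc"].notna(), "fc"] = 1.0
        res["status"] = res["fc"].map(classify_fc)
        res = res.drop(columns=["n_calib_reps"])

        self.results_ = res
        self.calibrator_dct_ = calib.rename(
            columns={"calib_dct": "dct"}).set_index(["gene", "timepoint"])
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).results_

    def delta_ct_matrix(self) -> pd.DataFrame:
        """Genes × (treatment, timepoint) matrix of mean ΔCt values
        (heatmap export)."""
        self._check_fitted()
        return self.results_.pivot_table(
            index="gene", columns=["treatment", "timepoint"],
            values="mean_dct", aggfunc="first")

    def log2_fc_matrix(self) -> pd.DataFrame:
        """Genes × (treatment, timepoint) matrix of log2 fold changes."""
        self._check_fitted()
        res = self.results_.copy()
        res["log2_fc"] = np.log2(res["fc"])
        return res.pivot_table(index="gene",
                               columns=["treatment", "timepoint"],
                               values="log2_fc", aggfunc="first")

    def _check_fitted(self):
        if not hasattr(self, "results_"):
            raise ValueError("DeltaDeltaCt is not fitted")


def fold_changes(records: pd.DataFrame, housekeeping: str = "18S",
                 calibrator: str = "Control",
                 fc_averaging: str = "geometric") -> pd.DataFrame:
    """One-shot 2^−ΔΔCt: tidy Ct records → per-(gene, treatment,
    timepoint) fold-change table."""
    return DeltaDeltaCt(housekeeping=housekeeping, calibrator=calibrator,
                        fc_averaging=fc_averaging).fit_predict(records)


def count_upregulated(results: pd.DataFrame, treatment: str | None = None,
                      timepoint: str | None = None):
    """Number of genes with status ``up`` (FC ≥ 2); undetermined genes
    are excluded from the count.

    With ``treatment`` and ``timepoint`` given, returns one integer;
    otherwise a treatments × timepoints DataFrame of counts.
    """
    res = results
    if treatment is not None:
        res = res[res["treatment"] == treatment]
    if timepoint is not None:
        res = res[res["timepoint"] == timepoint]
    if treatment is not None and timepoint is not None:
        return int((res["status"] == "up").sum())
    up = res.assign(is_up=res["status"] == "up")
    return (up.pivot_table(index="treatment", columns="timepoint",
                           values="is_up", aggfunc="sum", fill_value=0)
            .astype(int))
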