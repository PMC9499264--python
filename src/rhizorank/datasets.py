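"""Packaged reference study: a greenhouse biofertilizer trial.

Treatment-level summaries of a published greenhouse trial in which
durum wheat (12 treatments) and maize (8 treatments) were supplemented
with combinations of biochar, two five-strain microbial consortia
(MC-B, MC-C) and arbuscular mycorrhizal fungi.  The tables carry, per
treatment, the printed means (and SDs) of nine growth traits measured
at harvest, plus the published integrative score matrix: per-parameter
ranks over the nine traits, two rhizosphere Shannon-index columns (16S
bacteria, ITS fungi) and two counts of upregulated leaf genes (21 and
60 days after sowing), with row totals and means.

Replicate-level raw data were not published; trait tables expand the
means to single pseudo-replicates, and the :mod:`rhizorank.simulate`
module generates full replicate sets with the same structure.

One published score cell is internally inconsistent: the wheat
MC-C_AMF shoot-length score is printed as 5, but re-ranking the printed
shoot-length means gives 4 (propagating to that row's total, 81 printed
versus 80 recomputed).  See :data:`KNOWN_DISCREPANT_CELLS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TRAITS
from .treatments import MAIZE_LABELS, WHEAT_LABELS, study_labels

#: Non-physiological score-matrix columns, taken as published inputs:
#: the per-treatment Shannon indices behind them live in the study's
#: appendix and the fold-change values behind the up-gene counts were
#: published only as a heatmap, so these columns cannot be recomputed.
AUX_PARAMETERS: tuple[str, ...] = (
    "shannon_bacteria", "shannon_fungi", "up_genes_21das", "up_genes_60das",
)

#: All 13 score-matrix parameters, in published column order.
PARAMETERS: tuple[str, ...] = TRAITS + AUX_PARAMETERS

#: Score cells whose published value disagrees with recomputation from
#: the published trait means (crop, treatment, parameter).
KNOWN_DISCREPANT_CELLS: tuple[tuple[str, str, str], ...] = (
    ("wheat", "MC-C_AMF", "shoot_length_cm"),
)

# Trait columns: root_length_cm, shoot_length_cm, root_fw_g, shoot_fw_g,
# root_dw_g, shoot_dw_g, root_dry_biomass_pct, shoot_dry_biomass_pct, spad.
_WHEAT_MEANS = {
    "Control":        (61.2, 33.3, 0.7, 0.4, 0.1, 0.12, 11.4, 28.1, 25.8),
    "Char":           (26.2, 32.0, 0.7, 0.6, 0.1, 0.16, 15.5, 28.1, 27.2),
    "AMF":            (64.6, 31.8, 0.7, 0.5, 0.1, 0.15, 15.7, 26.7, 27.7),
    "Char_AMF":       (44.4, 30.0, 0.5, 0.4, 0.1, 0.31, 14.6, 37.9, 24.1),
    "MC-B":           (53.6, 35.4, 0.7, 0.5, 0.1, 0.15, 12.5, 27.2, 23.6),
    "MC-C":           (35.6, 27.8, 0.6, 0.4, 0.1, 0.14, 11.4, 30.8, 24.2),
    "MC-B_AMF":       (52.6, 28.4, 0.4, 0.4, 0.1, 0.15, 18.5, 31.4, 22.2),
    "MC-C_AMF":       (39.4, 31.6, 1.5, 0.6, 0.1, 0.16,  9.9, 27.2, 26.2),
    "Char_MC-B":      (49.2, 45.0, 1.6, 1.9, 0.2, 0.47, 15.2, 24.1, 29.0),
    "Char_MC-C":      (48.6, 45.6, 2.0, 1.4, 0.3, 0.42, 14.7, 30.6, 33.3),
    "Char_MC-B_AMF":  (54.8, 45.4, 1.6, 1.7, 0.3, 0.44, 17.3, 28.4, 29.5),
    "Char_MC-C_AMF":  (74.8, 48.2, 0.6, 1.5, 0.2, 0.22, 26.4, 16.0, 27.8),
}

_WHEAT_SDS = {
    "Control":        ( 6.7, 2.6, 0.1, 0.1, 0.1, 0.02,  3.4,  2.7, 2.2),
    "Char":           ( 2.3, 5.1, 0.3, 0.1, 0.0, 0.03,  6.1,  6.2, 2.3),
    "AMF":            ( 9.0, 4.3, 0.1, 0.1, 0.0, 0.04,  3.2, 13.3, 1.6),
    "Char_AMF":       ( 3.4, 3.7, 0.1, 0.1, 0.0, 0.03,  3.2, 10.8, 3.5),
    "MC-B":           (24.8, 4.7, 0.2, 0.1, 0.0, 0.01,  1.0,  4.3, 1.6),
    "MC-C":           (17.2, 1.3, 0.1, 0.1, 0.0, 0.01,  5.1,  7.6, 2.1),
    "MC-B_AMF":       ( 8.1, 5.7, 0.2, 0.1, 0.0, 0.01,  6.8,  4.6, 5.2),
    "MC-C_AMF":       ( 3.3, 5.3, 0.5, 0.1, 0.1, 0.04, 10.6,  8.2, 3.3),
    "Char_MC-B":      ( 9.4, 7.3, 0.5, 0.1, 0.1, 0.07,  7.8,  2.2, 4.1),
    "Char_MC-C":      (10.0, 3.3, 0.7, 0.4, 0.1, 0.02,  3.7,  8.4, 8.7),
    "Char_MC-B_AMF":  ( 3.3, 11.5, 0.3, 0.1, 0.1, 0.02, 3.0,  3.0, 1.5),
    "Char_MC-C_AMF":  ( 7.0, 3.3, 0.1, 0.3, 0.0, 0.06,  6.7,  6.1, 3.0),
}

_MAIZE_MEANS = {
    "Control":        (51.7, 56.0, 3.1,  4.3, 0.3, 0.6, 10.3, 14.5,  9.4),
    "Char":           (59.2, 68.0, 2.6,  5.0, 0.3, 0.6,  9.0, 12.0, 13.0),
    "AMF":            (70.8, 62.8, 3.1,  6.6, 0.2, 1.1,  8.7, 15.4, 12.2),
    "Char_AMF":       (61.2, 68.3, 3.2,  5.3, 0.2, 0.7,  8.4, 13.0, 13.4),
    "Char_MC-B":      (61.7, 64.5, 2.6,  4.8, 0.2, 0.6,  9.2, 14.3, 12.5),
    "Char_MC-B_AMF":  (88.2, 62.2, 3.0, 12.5, 0.2, 2.7,  8.1, 22.3, 17.5),
    "Char_MC-C":      (65.2, 65.2, 3.0,  4.7, 0.3, 0.7,  9.1, 14.6, 15.0),
    "Char_MC-C_AMF":  (81.0, 59.7, 2.7,  8.9, 0.3, 1.5,  9.5, 16.1, 14.5),
}

_MAIZE_SDS = {
    "Control":        (10.3,  8.0, 0.7, 1.7, 0.1, 0.2, 1.2, 1.4, 2.4),
    "Char":           (16.6, 10.9, 0.5, 3.3, 0.6, 0.3, 1.0, 0.9, 2.6),
    "AMF":            ( 9.3, 13.8, 1.1, 2.9, 0.1, 0.7, 3.0, 2.7, 1.8),
    "Char_AMF":       (10.5, 20.0, 1.7, 2.4, 0.1, 0.3, 1.9, 1.3, 3.4),
    "Char_MC-B":      (13.0, 14.5, 0.4, 2.0, 0.1, 0.3, 0.7, 0.1, 2.3),
    "Char_MC-B_AMF":  (21.5,  9.6, 0.9, 6.4, 0.1, 0.1, 1.2, 8.7, 3.8),
    "Char_MC-C":      ( 7.0,  9.1, 0.4, 1.8, 0.1, 0.3, 1.3, 2.2, 3.7),
    "Char_MC-C_AMF":  (10.3, 11.8, 1.0, 3.1, 0.1, 0.6, 1.1, 1.9, 3.4),
}

# Published score matrix: 9 trait ranks, 2 Shannon ranks, 2 up-gene
# ranks (None = n.t.), then the published Total and Mean.
_WHEAT_SCORES = {
    "Control":        (10, 7,  8,  4,  8,  1,  3,  7,  5,    2,    4,    1,    1,   61,  4.7),
    "Char":           ( 1, 6,  8,  8,  8,  7,  8,  7,  7,    1,    1,    7,    7,   76,  5.8),
    "AMF":            (11, 5,  8,  6,  8,  5,  9,  3,  8,    6,    4,    3,    2,   78,  6.0),
    "Char_AMF":       ( 4, 3,  2,  4,  8,  9,  5, 12,  3,    6,    2,    5,    4,   67,  5.2),
    "MC-B":           ( 8, 8,  8,  6,  8,  5,  4,  5,  2, None, None, None, None,   54,  6.0),
    "MC-C":           ( 2, 1,  4,  4,  8,  2,  3, 10,  4,    6,    7,    7,    5,   63,  4.8),
    "MC-B_AMF":       ( 7, 2,  1,  4,  8,  5, 11, 11,  1, None, None, None, None,   50,  5.6),
    "MC-C_AMF":       ( 3, 5,  9,  8,  8,  7,  1,  5,  6,    6,    7,    8,    8,   81,  6.2),
    "Char_MC-B":      ( 6, 9, 11, 12, 10, 12,  7,  2, 10, None, None, None, None,   79,  8.8),
    "Char_MC-C":      ( 5, 11, 12,  9, 12, 10,  6,  9, 12,   8,    5,    5,    7,  111,  8.5),
    "Char_MC-B_AMF":  ( 9, 10, 11, 11, 12, 11, 10,  8, 11, None, None, None, None,  93, 10.3),
    "Char_MC-C_AMF":  (12, 12,  4, 10, 10,  8, 12,  1,  9,    7,    8,    3,    4, 100,  7.7),
}

_MAIZE_SCORES = {
    "Control":        (1, 1, 7, 1, 8, 3, 8, 4, 1, 5, 8, 1, 2, 50, 3.8),
    "Char":           (2, 7, 2, 4, 8, 3, 4, 1, 4, 2, 7, 7, 8, 59, 4.5),
    "AMF":            (6, 4, 7, 6, 4, 6, 3, 6, 2, 7, 5, 6, 7, 69, 5.3),
    "Char_AMF":       (3, 8, 8, 5, 4, 5, 2, 2, 5, 2, 6, 6, 2, 58, 4.5),
    "Char_MC-B":      (4, 5, 2, 3, 4, 3, 6, 3, 3, 6, 4, 6, 5, 54, 4.2),
    "Char_MC-B_AMF":  (8, 3, 5, 8, 4, 8, 1, 8, 8, 5, 3, 2, 4, 67, 5.2),
    "Char_MC-C":      (5, 6, 5, 2, 8, 5, 5, 5, 7, 8, 2, 8, 4, 70, 5.4),
    "Char_MC-C_AMF":  (7, 2, 3, 7, 8, 7, 7, 7, 6, 5, 1, 6, 7, 73, 5.6),
}


def _frame(data: dict, columns) -> pd.DataFrame:
    return pd.DataFrame.from_dict(data, orient="index", columns=list(columns),
                                  dtype=float).rename_axis("treatment")


def trait_means(crop: str) -> pd.DataFrame:
    """Published treatment × trait mean matrix for ``crop``."""
    data = _WHEAT_MEANS if crop == "wheat" else _MAIZE_MEANS
    return _frame(data, TRAITS)


def trait_sds(crop: str) -> pd.DataFrame:
    """Published treatment × trait standard-deviation matrix."""
    data = _WHEAT_SDS if crop == "wheat" else _MAIZE_SDS
    return _frame(data, TRAITS)


def reference_scores(crop: str) -> pd.DataFrame:
    """Published treatment × parameter score matrix (NaN = n.t.)."""
    data = _WHEAT_SCORES if crop == "wheat" else _MAIZE_SCORES
    return _frame({k: v[:13] for k, v in data.items()}, PARAMETERS)


def reference_totals(crop: str) -> pd.DataFrame:
    """Published per-treatment Total and Mean columns."""
    data = _WHEAT_SCORES if crop == "wheat" else _MAIZE_SCORES
    return _frame({k: v[13:] for k, v in data.items()}, ("total", "mean"))


def aux_scores(crop: str) -> pd.DataFrame:
    """The published metagenomic / gene-expression score columns.

    These four columns are inputs to the integrative matrix, not
    recomputable from packaged data (see module docstring).
    """
    return reference_scores(crop)[list(AUX_PARAMETERS)]


def load_trait_table(crop: str) -> pd.DataFrame:
    """Tidy trait table with the published means as single pseudo-replicates."""
    means = trait_means(crop)
    rows = [
        {"treatment": t, "replicate": 1, "trait": trait, "value": means.at[t, trait]}
        for t in study_labels(crop) for trait in TRAITS
    ]
    return pd.DataFrame(rows, columns=["treatment", "replicate", "trait", "value"])
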