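"""Readers and writers for the three tabular formats the pipeline touches.

All files are UTF-8 TSV/CSV with a header row, ``.`` decimal separator
and ``NA`` as the missing-value sentinel.  Trait and Ct tables are tidy
(one measurement per row); OTU tables follow the common
taxa-by-sample dialect with one lineage column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine growth traits measured per plant.
TRAITS: tuple[str, ...] = (
    "root_length_cm", "shoot_length_cm",
    "root_fw_g", "shoot_fw_g",
    "root_dw_g", "shoot_dw_g",
    "root_dry_biomass_pct", "shoot_dry_biomass_pct",
    "spad",
)

#: Cycle-threshold detection ceiling: raw Ct strictly above this is
#: treated as undetermined (36.0 itself is a valid measurement).
CT_CEILING = 36.0

#: Named taxonomic ranks carried by OTU lineages, most to least inclusive.
LINEAGE_RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus",
)

#: Timepoints of the expression assay, in days after sowing.
TIMEPOINTS: tuple[str, ...] = ("21DAS", "60DAS")


class ParseError(ValueError):
    """A malformed row or value in an input file."""


def _sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# trait tables

def read_trait_table(path) -> pd.DataFrame:
    """Read a tidy trait table: columns treatment, replicate, trait, value.

    Returns a validated DataFrame in long layout.  Unknown trait names
    and negative values are rejected with the offending line number.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    required = ["treatment", "replicate", "trait", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    out = df[required].copy()
    for i, row in enumerate(out.itertuples(index=False), start=2):
        if row.trait not in TRAITS:
            raise ParseError(
                f"{path}:{i}: unknown trait {row.trait!r}; allowed: {', '.join(TRAITS)}"
            )
        try:
            v = float(row.value)
        except ValueError:
            raise ParseError(f"{path}:{i}: non-numeric value {row.value!r}") from None
        if v < 0:
            raise ParseError(f"{path}:{i}: negative trait value {v}")
    out["replicate"] = out["replicate"].astype(int)
    out["value"] = out["value"].astype(float)
    _check_dw_le_fw(out, path)
    return out


def _check_dw_le_fw(df: pd.DataFrame, path) -> None:
    wide = df.pivot_table(index=["treatment", "replicate"], columns="trait",
                          values="value", aggfunc="first")
    for organ in ("root", "shoot"):
        dw, fw = f"{organ}_dw_g", f"{organ}_fw_g"
        if dw in wide.columns and fw in wide.columns:
            bad = wide[wide[dw] > wide[fw]].dropna(subset=[dw, fw])
            if len(bad):
                key = bad.index[0]
                raise ParseError(
                    f"{path}: {organ} dry weight exceeds fresh weight for "
                    f"treatment {key[0]!r} replicate {key[1]}"
                )


def write_trait_table(df: pd.DataFrame, path) -> None:
    df[["treatment", "replicate", "trait", "value"]].to_csv(
        path, sep="\t", index=False, na_rep="NA")


def wide_to_long_traits(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert a treatment × trait (or (treatment, replicate) × trait) wide
    table to the tidy long layout used everywhere else."""
    w = wide.copy()
    if "treatment" not in w.columns:
        w = w.reset_index()
    if "treatment" not in w.columns:
        raise ParseError("wide trait table needs a 'treatment' index or column")
    if "replicate" not in w.columns:
        w["replicate"] = 1
    long = w.melt(id_vars=["treatment", "replicate"], var_name="trait",
                  value_name="value")
    unknown = set(long["trait"]) - set(TRAITS)
    if unknown:
        raise ParseError(f"unknown trait(s) {sorted(unknown)}")
    return long.dropna(subset=["value"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# OTU tables

@dataclass
class OtuTable:
    """Taxa × samples count table with parsed lineages.

    counts
        integer DataFrame, index otu_id, one column per sample.
    lineages
        DataFrame indexed like ``counts``, one column per rank in
        :data:`LINEAGE_RANKS`; unparseable ranks hold ``"unassigned"``.
    sample_meta
        optional DataFrame indexed by sample id with ``treatment`` and
        ``replicate`` columns.
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ParseError(f"duplicate otu_id(s): {list(dupes)}")
        if (self.counts.to_numpy() < 0).any():
            raise ParseError("negative counts in OTU table")
        sums = self.counts.sum(axis=0)
        empty = sums.index[sums == 0].tolist()
        if empty:
            raise ParseError(f"empty sample column(s): {empty}")
        if not self.lineages.index.equals(self.counts.index):
            raise ParseError("lineage index does not match counts index")

    def __eq__(self, other):
        return (isinstance(other, OtuTable)
                and self.counts.equals(other.counts)
                and self.lineages.equals(other.lineages))

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def parse_lineage(text: str) -> dict[str, str]:
    """Parse a ``;``-separated lineage, tolerating ``k__`` style prefixes.

    Missing or empty ranks become ``"unassigned"``.
    """
    parts = [p.strip() for p in str(text).split(";")]
    out = {}
    for rank, part in zip(LINEAGE_RANKS, parts + [""] * len(LINEAGE_RANKS)):
        if len(part) > 2 and part[1:3] == "__":
            part = part[3:]
        out[rank] = part if part else "unassigned"
    return out


def format_lineage(ranks: dict[str, str]) -> str:
    return ";".join(ranks.get(r, "unassigned") for r in LINEAGE_RANKS)


def read_otu_table(path) -> OtuTable:
    """Read a taxa-by-sample TSV: otu_id, lineage, then one column per sample."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need otu_id, lineage and ≥1 sample column")
    otu_col, lin_col = df.columns[:2]
    sample_cols = list(df.columns[2:])
    counts = pd.DataFrame(index=pd.Index(df[otu_col], name="otu_id"))
    for col in sample_cols:
        try:
            vals = df[col].astype(np.int64)
        except ValueError:
            bad = df.loc[~df[col].str.fullmatch(r"-?\d+"), col].iloc[0]
            raise ParseError(f"{path}: non-integer count {bad!r} in sample {col!r}") from None
        counts[col] = vals.to_numpy()
    lineages = pd.DataFrame(
        [parse_lineage(t) for t in df[lin_col]],
        index=counts.index, columns=list(LINEAGE_RANKS))
    return OtuTable(counts=counts, lineages=lineages)


def write_otu_table(table: OtuTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "lineage", [format_lineage(dict(r))
                              for _, r in table.lineages.iterrows()])
    out.to_csv(path, sep="\t", index=True, index_label="otu_id")


# ---------------------------------------------------------------------------
# Ct tables

CT_COLUMNS = ["gene", "treatment", "timepoint", "bio_rep", "tech_rep", "ct"]


def apply_ct_ceiling(df: pd.DataFrame, ceiling: float = CT_CEILING) -> pd.DataFrame:
    """Mark raw Ct strictly above the ceiling as undetermined (NaN).

    The reader applies this automatically; use it for in-memory tables
    that never passed through a file.
    """
    out = df.copy()
    out.loc[out["ct"] > ceiling, "ct"] = np.nan
    return out


def read_ct_table(path, housekeeping: str | None = "18S") -> pd.DataFrame:
    """Read tidy qPCR cycle-threshold records.

    Raw Ct strictly greater than :data:`CT_CEILING` (and ``NA``) is
    mapped to NaN — the undetermined sentinel — at read time, so no
    downstream stage ever sees an out-of-range Ct.  Missing
    housekeeping rows for a (treatment, timepoint) are logged as a
    warning and left for downstream stages to flag.
    """
    df = pd.read_csv(path, sep=_sep(path), na_values=["NA"])
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = df[CT_COLUMNS].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="raise").astype(float)
    if (df["ct"].dropna() <= 0).any():
        raise ParseError(f"{path}: non-positive Ct value")
    df.loc[df["ct"] > CT_CEILING, "ct"] = np.nan
    if housekeeping is not None:
        cells = df.groupby(["treatment", "timepoint"], sort=False)["gene"]
        for key, genes in cells:
            if housekeeping not in set(genes):
                logger.warning(
                    "no housekeeping (%s) rows for treatment=%s timepoint=%s",
                    housekeeping, *key)
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df[CT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
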