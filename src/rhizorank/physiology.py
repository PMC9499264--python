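"""Growth-trait summaries and nonparametric group comparisons.

Treatments are compared per trait with a Kruskal–Wallis omnibus test
followed by Dunn's pairwise z-tests on pooled midranks (the workflow
of the Past statistics package), with classical one-way ANOVA reported
alongside for transparency.  Group memberships are summarized as a
compact letter display: treatments sharing a letter are not
significantly different at the chosen alpha.

Dunn's statistic for groups i, j compares mean pooled ranks:

    z = (R̄ᵢ − R̄ⱼ) / sqrt( (N(N+1)/12 − T) (1/nᵢ + 1/nⱼ) )

with the tie correction T = Σ(t³ − t) / (12 (N − 1)) over tie groups
of size t.  Pairwise p-values are two-sided normal; unadjusted by
default (Past's default), Holm or Bonferroni selectable.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TRAITS

__all__ = ["dry_biomass_pct", "summarize_traits", "group_test",
           "kruskal_dunn", "compact_letter_display", "GroupTestResult"]


def dry_biomass_pct(dw: float, fw: float) -> float:
    """Dry biomass as a percentage of fresh weight, 100·DW/FW.

    Scale-invariant in (DW, FW); requires 0 ≤ DW ≤ FW and FW > 0.
    """
    dw = np.asarray(dw, dtype=float)
    fw = np.asarray(fw, dtype=float)
    if np.any(fw <= 0):
        raise ValueError("fresh weight must be positive")
    if np.any(dw < 0) or np.any(dw > fw):
        raise ValueError("dry weight must lie in [0, fresh weight]")
    out = 100.0 * dw / fw
    return float(out) if out.ndim == 0 else out


def summarize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Per treatment × trait mean, sample SD (n−1 denominator) and n.

    Single-replicate cells get sd = 0 and are identifiable by n = 1.
    """
    def _sd(x):
        return 0.0 if len(x) < 2 else float(np.std(x, ddof=1))

    out = (table.groupby(["treatment", "trait"], sort=False)["value"]
           .agg(mean="mean", sd=_sd, n="count").reset_index())
    return out


def summary_matrix(summaries: pd.DataFrame, order=None) -> pd.DataFrame:
    """Pivot tidy summaries into a treatments × traits matrix of means."""
    wide = summaries.pivot(index="treatment", columns="trait", values="mean")
    cols = [t for t in TRAITS if t in wide.columns]
    wide = wide[cols]
    if order is not None:
        wide = wide.reindex([t for t in order if t in wide.index])
    return wide


@dataclass
class GroupTestResult:
    """Omnibus + pairwise comparison of one trait across treatments."""

    trait: str
    omnibus_statistic: float   # Kruskal–Wallis H (tie-corrected)
    omnibus_p: float
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame     # symmetric matrix of Dunn p-values
    letters: dict[str, str]    # compact letter display per treatment
    alpha: float = 0.05


def _dunn_pairwise(groups: dict[str, np.ndarray], adjust: str = "none") -> pd.DataFrame:
    labels = list(groups)
    sizes = {k: len(v) for k, v in groups.items()}
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for k in labels:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(labels, 2))
    pvals = []
    for a, b in pairs:
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:  # fully tied data
            pvals.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pvals.append(2.0 * stats.norm.sf(abs(z)))
    pvals = _adjust(np.asarray(pvals), adjust)

    mat = pd.DataFrame(np.ones((len(labels), len(labels))),
                       index=labels, columns=labels)
    for (a, b), p in zip(pairs, pvals):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    m = len(pvals)
    if method == "none" or m == 0:
        return np.minimum(pvals, 1.0)
    if method == "bonferroni":
        return np.minimum(pvals * m, 1.0)
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * pvals[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def compact_letter_display(labels, pairwise: pd.DataFrame,
                           alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one set containing every treatment; each significant
    pair splits the sets containing both members; subset sets are then
    absorbed.  Treatments share a letter iff no significant pairwise
    difference separates them within that set.
    """
    labels = list(labels)
    sets: list[set] = [set(labels)]
    sig_pairs = [(a, b) for a, b in itertools.combinations(labels, 2)
                 if pairwise.loc[a, b] < alpha]
    for a, b in sig_pairs:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [s for s in new_sets
                if s and not any(s < t for t in new_sets)]
        # deduplicate preserving order
        seen, uniq = [], []
        for s in sets:
            if s not in seen:
                seen.append(s)
                uniq.append(s)
        sets = uniq
    # stable letter order: by earliest member in input order
    sets.sort(key=lambda s: min(labels.index(m) for m in s))
    alphabet = string.ascii_lowercase
    letters = {lab: "" for lab in labels}
    for i, s in enumerate(sets):
        letter = alphabet[i % 26] * (1 + i // 26)
        for member in s:
            letters[member] += letter
    return letters


def kruskal_dunn(groups: dict[str, np.ndarray], trait: str = "",
                 alpha: float = 0.05, adjust: str = "none") -> GroupTestResult:
    """Kruskal–Wallis omnibus, Dunn pairwise z-tests and letter display.

    ``groups`` maps treatment label → replicate values (≥2 groups of
    ≥2 values each).  All-identical data give omnibus p = 1 and a
    single shared letter.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 treatments")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 replicates per treatment")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all values identical: no evidence of differences
        h, p_kw, f, p_f = 0.0, 1.0, 0.0, 1.0
    else:
        h, p_kw = stats.kruskal(*arrays)
        f, p_f = stats.f_oneway(*arrays)
    pairwise = _dunn_pairwise(groups, adjust=adjust)
    letters = compact_letter_display(list(groups), pairwise, alpha=alpha)
    return GroupTestResult(trait=trait, omnibus_statistic=float(h),
                           omnibus_p=float(p_kw), anova_f=float(f),
                           anova_p=float(p_f), pairwise=pairwise,
                           letters=letters, alpha=alpha)


def group_test(table: pd.DataFrame, trait: str, alpha: float = 0.05,
               adjust: str = "none") -> GroupTestResult:
    """Run :func:`kruskal_dunn` on one trait of a tidy trait table."""
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present")
    groups = {t: g["value"].to_numpy()
              for t, g in sub.groupby("treatment", sort=False)}
    return kruskal_dunn(groups, trait=trait, alpha=alpha, adjust=adjust)
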