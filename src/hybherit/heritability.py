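"""Additivity/dominance classification and parental-effect categories.

For each differentially expressed gene and each reciprocal hybrid the scheme
reduces inheritance to two numbers computed from group-mean normalized
intensities:

    alpha (additivity) = (W - D) / 2
    delta (dominance)  = (W + D) / 2 - hybrid

A hybrid at mid-parent expression has delta/alpha = 0 (pure additivity);
expression equal to the wild parent gives delta/alpha = -1, equal to the
domesticated parent +1, and values beyond +-1.5 indicate over-dominance
(hybrid outside the parental range).  Interval memberships:

    additive               -0.5 < ratio < 0.5
    wild dominant          -1.5 < ratio <= -0.5
    domesticated dominant   0.5 <= ratio < 1.5
    over-dominant           ratio <= -1.5 or ratio >= 1.5

Boundary points (measure-zero) go to the dominant class at +-0.5 and to
over-dominance at +-1.5 so every defined ratio has exactly one class.
Parental-effect categories are derived from which post-hoc contrasts between
the four cross types are significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

MODES = ("additive", "wild_dominant", "domesticated_dominant", "over_dominant", "undefined")

#: ordered table classes, over-dominance split by the sign of delta/alpha
TABLE_CLASSES = (
    "wild_over_dominant",
    "wild_dominant",
    "additive",
    "domesticated_dominant",
    "domesticated_over_dominant",
)

_PAIR_WW_DD = frozenset(("WW", "DD"))
#: contrasts that differ in the maternal line while sharing the paternal line
_MATERNAL_PAIRS = (frozenset(("WW", "DW")), frozenset(("WD", "DD")))
#: contrasts that share the mother and differ in the father
_PATERNAL_PAIRS = (frozenset(("WW", "WD")), frozenset(("DW", "DD")))
_HYBRID_PAIR = frozenset(("WD", "DW"))

#: the study's literal category lists (any hybrid-vs-WW or DD contrast counts),
#: selectable for strict reproduction
_LITERAL_MATERNAL = (
    frozenset(("WW", "DW")), frozenset(("WW", "DD")), frozenset(("WW", "WD")),
)
_LITERAL_PATERNAL = (
    frozenset(("WW", "WD")), frozenset(("WW", "DD")), frozenset(("WW", "DW")),
)


def additivity_dominance(w_ni: float, d_ni: float, hybrid_ni: float):
    """Return (alpha, delta, ratio) for one gene in one hybrid.

    Inputs are gene-level group means on the normalized-intensity (log2
    ratio) scale.  ``ratio`` is NaN when alpha == 0 (mid-parent undefined
    direction); such genes are reported, never dropped.
    """
    alpha = (w_ni - d_ni) / 2.0
    delta = (w_ni + d_ni) / 2.0 - hybrid_ni
    if alpha == 0:
        if delta != 0:
            log.warning("alpha = 0 with delta = %g: ratio undefined", delta)
        return alpha, delta, float("nan")
    return alpha, delta, delta / alpha


def classify_mode(ratio: float) -> str:
    """Map delta/alpha to its inheritance-mode class."""
    if ratio is None or np.isnan(ratio):
        return "undefined"
    if -0.5 < ratio < 0.5:
        return "additive"
    if -1.5 < ratio <= -0.5:
        return "wild_dominant"
    if 0.5 <= ratio < 1.5:
        return "domesticated_dominant"
    return "over_dominant"


def table_class(ratio: float) -> str:
    """Five-class label with over-dominance split by side (wild = negative)."""
    mode = classify_mode(ratio)
    if mode == "over_dominant":
        return "wild_over_dominant" if ratio < 0 else "domesticated_over_dominant"
    if mode == "undefined":
        return "undefined"
    return mode


def exclude_pure_only(posthoc: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split genes whose only significant contrast is pure-vs-pure.

    A transcript that differs between WW and DD but shows no contrast
    involving a hybrid carries no inheritance information and is excluded
    from effect categorization.  Returns (kept, excluded).
    """
    only_pure = posthoc["significant_pairs"].map(
        lambda pairs: len(pairs) > 0 and set(pairs) == {_PAIR_WW_DD}
    )
    return posthoc[~only_pure], posthoc[only_pure]


def categorize_parental_effect(significant_pairs, scheme: str = "line_sharing") -> str:
    """Assign maternal / paternal / parental / hybrid_only from contrasts.

    Default ``line_sharing`` scheme: a contrast supports a maternal effect
    when the two crosses share the paternal line but differ in the maternal
    line ({WW,DW} or {WD,DD}); a paternal effect when they share the mother
    and differ in the father ({WW,WD} or {DW,DD}); both kinds present →
    parental; only the hybrid-vs-hybrid contrast → hybrid_only.  The
    ``literal`` scheme reproduces the study's published category lists, under
    which any contrast of a pure cross against the other three crosses counts
    for both parent categories except the cross sharing that parent.
    """
    pairs = set(significant_pairs)
    if not pairs:
        return "uncategorized"
    if scheme == "line_sharing":
        maternal = any(p in pairs for p in _MATERNAL_PAIRS)
        paternal = any(p in pairs for p in _PATERNAL_PAIRS)
    elif scheme == "literal":
        maternal = any(p in pairs for p in _LITERAL_MATERNAL)
        paternal = any(p in pairs for p in _LITERAL_PATERNAL)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if maternal and paternal:
        return "parental"
    if maternal:
        return "maternal"
    if paternal:
        return "paternal"
    if pairs == {_HYBRID_PAIR}:
        return "hybrid_only"
    if pairs == {_PAIR_WW_DD}:
        return "excluded_pure_only"
    return "hybrid_only" if _HYBRID_PAIR in pairs else "uncategorized"


@dataclass
class HeritabilityCall:
    gene_id: str
    hybrid: str
    alpha: float
    delta: float
    ratio: float
    mode: str
    effect_category: str


def call_heritability(
    matrix: ExpressionMatrix,
    posthoc: pd.DataFrame,
    scheme: str = "line_sharing",
) -> pd.DataFrame:
    """Per-gene, per-hybrid inheritance calls from group means and contrasts.

    Genes whose only significant contrast is pure-vs-pure are excluded.  For
    each remaining gene and each hybrid whose cross appears in at least one
    significant contrast, alpha, delta and delta/alpha are computed from the
    WW / DD / hybrid group means and classified.
    """
    kept, _excluded = exclude_pure_only(posthoc)
    means = matrix.group_means()
    rows = []
    for gene, pairs in kept["significant_pairs"].items():
        if not pairs:
            continue
        category = categorize_parental_effect(pairs, scheme=scheme)
        w_ni = means.at[gene, "WW"]
        d_ni = means.at[gene, "DD"]
        for hybrid in ("WD", "DW"):
            if not any(hybrid in p for p in pairs):
                continue
            alpha, delta, ratio = additivity_dominance(w_ni, d_ni, means.at[gene, hybrid])
            rows.append(
                {
                    "gene_id": gene,
                    "hybrid": hybrid,
                    "alpha": alpha,
                    "delta": delta,
                    "ratio": ratio,
                    "mode": classify_mode(ratio),
                    "effect_category": category,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "hybrid", "alpha", "delta", "ratio", "mode", "effect_category"],
    )


def heritability_table(calls: pd.DataFrame, include_ratio_above: float = 5) -> pd.DataFrame:
    """Per-hybrid percentages of genes in each of the five classes.

    All classified genes count, including those with |delta/alpha| beyond
    ``include_ratio_above`` (that cap applies to the scatter plot only).
    Genes with undefined ratios are tallied in a separate ``undefined``
    column outside the percentage base.
    """
    if calls.empty:
        log.warning("no heritability calls to summarize")
        return pd.DataFrame(columns=("hybrid", "n_genes", *TABLE_CLASSES, "undefined"))
    rows = []
    for hybrid, sub in calls.groupby("hybrid"):
        sub = sub.drop_duplicates("gene_id")
        defined = sub[sub["mode"] != "undefined"]
        n = len(defined)
        labels = defined["ratio"].map(table_class)
        row = {"hybrid": hybrid, "n_genes": n}
        for cls in TABLE_CLASSES:
            row[cls] = 100.0 * (labels == cls).sum() / n if n else 0.0
        row["undefined"] = int((sub["mode"] == "undefined").sum())
        rows.append(row)
    return pd.DataFrame(rows)
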