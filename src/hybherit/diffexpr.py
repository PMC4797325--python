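"""Differential expression between stocks and among the four cross types.

Two branches mirror the study design:

* stock contrast — per-gene Welch t-test (unpaired, unequal variance) between
  the pure domesticated (DD) and pure wild (WW) groups, Benjamini–Hochberg
  correction at 0.05 plus a two-sided linear fold-change filter of 1.25;
* four-group analysis — Welch's heteroscedastic one-way ANOVA across
  WW/WD/DW/DD with BH FDR at 10 %, followed by a Student–Newman–Keuls
  stepwise post-hoc on the group means for the genes that pass.

The t, ANOVA, BH and SNK cores are vectorized/looped numpy implementations so
they run across tens of thousands of probes in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CROSS_TYPES, ExpressionMatrix

__all__ = [
    "welch_t",
    "welch_t_matrix",
    "bh_adjust",
    "welch_anova",
    "welch_anova_matrix",
    "snk_posthoc",
    "de_between_stocks",
    "anova_posthoc_scan",
    "DEResult",
    "PosthocResult",
]


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def welch_t_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test between two replicate blocks.

    ``a`` and ``b`` are (genes x replicates) arrays.  Returns (t, two-sided p)
    per row, with Welch–Satterthwaite degrees of freedom.  Rows where both
    groups are constant and equal get t = 0, p = 1 by convention.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicates")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(degenerate & (diff == 0), 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    return t, p


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch t statistic and two-sided p for two 1-d samples."""
    t, p = welch_t_matrix(np.asarray(group_a)[None, :], np.asarray(group_b)[None, :])
    return float(t[0]), float(p[0])


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1).

    ``p_adj[i] = min over rank >= rank(i) of p * m / rank``, returned in the
    input order; invariant to input permutation after rank restoration.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Welch one-way ANOVA
# ---------------------------------------------------------------------------

def welch_anova_matrix(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch heteroscedastic one-way ANOVA.

    ``groups`` is a list of (genes x replicates) blocks, one per group.
    Returns (F*, p) per row.  Rows where every observation is identical get
    F = 0, p = 1 by convention.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    ns = np.array([g.shape[1] for g in groups])
    if (ns < 2).any():
        raise ValueError("each group needs at least 2 replicates")
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)   # genes x k
    vars_ = np.stack([g.var(axis=1, ddof=1) for g in groups], axis=1)
    degenerate = (vars_ == 0).all(axis=1) & (np.ptp(means, axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = ns / vars_                                            # genes x k
        sw = w.sum(axis=1)
        grand = (w * means).sum(axis=1) / sw
        a = (w * (means - grand[:, None]) ** 2).sum(axis=1) / (k - 1)
        frac = ((1 - w / sw[:, None]) ** 2 / (ns - 1)).sum(axis=1)
        b = 1 + 2 * (k - 2) / (k**2 - 1) * frac
        f = a / b
        df2 = (k**2 - 1) / (3 * frac)
    p = stats.f.sf(f, k - 1, df2)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    if not degenerate.all() and not np.isfinite(p[~degenerate]).all():
        # a single zero-variance group with distinct mean -> overwhelming evidence
        bad = ~np.isfinite(p) & ~degenerate
        p[bad] = 0.0
        f[bad] = np.inf
    return f, p


def welch_anova(groups) -> float:
    """Welch ANOVA p-value for a list of 1-d samples."""
    blocks = [np.asarray(g, dtype=float)[None, :] for g in groups]
    _, p = welch_anova_matrix(blocks)
    return float(p[0])


# ---------------------------------------------------------------------------
# Student–Newman–Keuls
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1024)
def _q_crit(alpha: float, r: int, df: float) -> float:
    # studentized-range quantiles are expensive; identical across genes with
    # equal design, so cache them
    return float(stats.studentized_range.ppf(1 - alpha, r, df))


def snk_posthoc(groups: dict[str, np.ndarray], alpha_snk: float = 0.05) -> set[frozenset]:
    """Stepwise SNK procedure on ordered group means.

    Classical SNK: pooled within-group mean square with N - k degrees of
    freedom; the extreme pair is tested at range r = k against the
    studentized-range quantile q(alpha, r, df), and sub-ranges are tested only
    inside ranges already declared significant.  Returns the set of
    significant unordered label pairs.  Group sizes may differ; the harmonic
    mean of the two compared group sizes is used in the standard error.
    """
    labels = list(groups)
    data = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    ns = {lab: d.size for lab, d in data.items()}
    if min(ns.values()) < 2:
        raise ValueError("each group needs at least 2 replicates")
    n_total = sum(ns.values())
    k = len(labels)
    df_err = n_total - k
    ms_err = sum((ns[lab] - 1) * data[lab].var(ddof=1) for lab in labels) / df_err
    means = sorted(((data[lab].mean(), lab) for lab in labels))
    significant: set[frozenset] = set()
    if ms_err == 0:
        # all replicates identical within groups: any mean difference is real
        for (mi, li), (mj, lj) in combinations(means, 2):
            if mi != mj:
                significant.add(frozenset((li, lj)))
        return significant

    # top-down over ranges: a span is tested only when every enclosing span
    # rejected (a single accepting range blocks everything inside it)
    rejected: dict[tuple[int, int], bool] = {}
    for r in range(k, 1, -1):
        for lo in range(0, k - r + 1):
            hi = lo + r - 1
            left_ok = rejected.get((lo - 1, hi), lo == 0)
            right_ok = rejected.get((lo, hi + 1), hi == k - 1)
            if not (left_ok and right_ok):
                rejected[(lo, hi)] = False
                continue
            m_lo, lab_lo = means[lo]
            m_hi, lab_hi = means[hi]
            n_h = 2 / (1 / ns[lab_lo] + 1 / ns[lab_hi])
            q = (m_hi - m_lo) / np.sqrt(ms_err / n_h)
            rejected[(lo, hi)] = bool(q > _q_crit(alpha_snk, r, float(df_err)))
            if rejected[(lo, hi)]:
                significant.add(frozenset((lab_lo, lab_hi)))
    return significant


# ---------------------------------------------------------------------------
# Gene-level result tables
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene stock-contrast result (domesticated vs wild)."""

    gene_id: str
    statistic: float
    p_raw: float
    p_adj: float
    log2_fc: float
    significant: bool


@dataclass
class PosthocResult:
    """Per-gene four-group ANOVA + SNK result."""

    gene_id: str
    anova_p_raw: float
    anova_p_adj: float
    significant_pairs: set[frozenset] = field(default_factory=set)


def de_between_stocks(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.25,
) -> pd.DataFrame:
    """Welch t + BH + fold-change filter between DD and WW.

    ``log2_fc`` is the domesticated-minus-wild difference of mean log ratios;
    a gene is significant iff BH-adjusted p <= ``alpha`` and the linear fold
    change in either direction, max(FC, 1/FC) with FC = 2**log2_fc, is at
    least ``fc_threshold``.
    """
    ww = matrix.group_values("WW")
    dd = matrix.group_values("DD")
    if ww.shape[1] < 2 or dd.shape[1] < 2:
        raise ValueError("each pure stock needs at least 2 replicates")
    t, p = welch_t_matrix(dd, ww)
    log2_fc = dd.mean(axis=1) - ww.mean(axis=1)
    p_adj = bh_adjust(p)
    passes_fc = np.abs(log2_fc) >= np.log2(fc_threshold)
    out = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "log2_fc": log2_fc,
            "significant": (p_adj <= alpha) & passes_fc,
        }
    ).set_index("gene_id", drop=False)
    out.index.name = None
    return out


def anova_posthoc_scan(
    matrix: ExpressionMatrix,
    anova_fdr: float = 0.10,
    alpha_snk: float = 0.05,
) -> pd.DataFrame:
    """Welch ANOVA across the four cross types with BH gating, then SNK.

    SNK runs only for genes whose BH-adjusted ANOVA p is <= ``anova_fdr``;
    other genes carry an empty pair set.  Returns a table with columns
    anova_p_raw, anova_p_adj, significant_pairs (set of frozensets).
    """
    blocks = {ct: matrix.group_values(ct) for ct in CROSS_TYPES}
    _, p = welch_anova_matrix([blocks[ct] for ct in CROSS_TYPES])
    p_adj = bh_adjust(p)
    pairs: list[set] = []
    gene_ids = list(matrix.values.index)
    for i, gene in enumerate(gene_ids):
        if p_adj[i] <= anova_fdr:
            groups = {ct: blocks[ct][i] for ct in CROSS_TYPES}
            pairs.append(snk_posthoc(groups, alpha_snk=alpha_snk))
        else:
            pairs.append(set())
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "anova_p_raw": p,
            "anova_p_adj": p_adj,
            "significant_pairs": pairs,
        }
    ).set_index("gene_id", drop=False)
    out.index.name = None
    return out


def format_pairs(pairs: set[frozenset]) -> str:
    """Render a pair set as a deterministic semicolon-joined string."""
    return ";".join("-".join(sorted(p)) for p in sorted(pairs, key=lambda q: sorted(q)))
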