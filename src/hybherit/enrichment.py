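"""Gene-set perturbation testing between the pure stocks.

The design follows the generally-applicable gene-set analysis idea: each
domesticated replicate is compared one-on-group against the mean of all wild
replicates, giving one per-gene fold-change profile per test replicate.  For
every gene set and direction a two-sample unequal-variance t-test contrasts
the set members' fold changes against all genes' fold changes: one-sided
upper for coordinated up-regulation, one-sided lower for down-regulation, and
the same upper test on |fold change| for "two-way perturbed" sets whose
members move coordinately in magnitude but in mixed directions.  Per-replicate
p-values are combined by Stouffer's method; because all test replicates share
the same control-group mean, the pipeline-level combination uses a
dependence-adjusted denominator (see :func:`run_enrichment`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .diffexpr import bh_adjust, welch_t_matrix

log = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "two_way")


@dataclass
class GeneSet:
    """A named gene set (e.g. a KEGG pathway) with its top-level group."""

    set_id: str
    member_genes: frozenset
    functional_group: str = ""

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"gene set {self.set_id} is empty")


@dataclass
class EnrichmentResult:
    set_id: str
    direction: str
    p_raw: float
    p_adj: float
    mean_stat: float
    essential_genes: list[str] = field(default_factory=list)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file.

    Column 2 (the description field) carries the functional group.
    """
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g), parts[1]))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.functional_group, *sorted(gs.member_genes)]) + "\n")


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------

def one_on_group_foldchanges(
    matrix: ExpressionMatrix,
    test_group: str = "DD",
    control_group: str = "WW",
) -> pd.DataFrame:
    """Genes x test-replicates matrix of one-on-group fold changes.

    Entry (g, j) is gene g's log ratio in test replicate j minus its mean
    over all control replicates.
    """
    control = matrix.group_values(control_group)
    if control.shape[1] < 2:
        raise ValueError("control group needs at least 2 replicates")
    test_arrays = matrix.arrays_for(test_group)
    fc = matrix.values[test_arrays].to_numpy(dtype=float) - control.mean(axis=1, keepdims=True)
    return pd.DataFrame(fc, index=matrix.values.index, columns=test_arrays)


def gage_set_test(fc_column: pd.Series, gene_set: GeneSet, direction: str) -> float:
    """One comparison's set-perturbation p-value.

    Unequal-variance two-sample t of the set members' fold changes against all
    genes' fold changes; ``up`` tests for a higher set mean, ``down`` for a
    lower one, ``two_way`` applies the upper test to absolute fold changes.
    Degenerate (zero-variance) input returns p = 1.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    values = fc_column.to_numpy(dtype=float)
    members = [g for g in gene_set.member_genes if g in fc_column.index]
    if not members:
        raise ValueError(f"gene set {gene_set.set_id} has no members in the matrix")
    sel = fc_column.loc[members].to_numpy(dtype=float)
    if direction == "two_way":
        sel, values = np.abs(sel), np.abs(values)
    if np.ptp(values) == 0 and np.ptp(sel) == 0:
        return 1.0
    t, _ = welch_t_matrix(sel[None, :], values[None, :])
    na, nb = sel.size, values.size
    va, vb = sel.var(ddof=1), values.var(ddof=1)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / max(na - 1, 1) + (vb / nb) ** 2 / (nb - 1)
    )
    if direction == "down":
        return float(stats.t.cdf(t[0], df))
    return float(stats.t.sf(t[0], df))


def combine_comparisons(p_list) -> float:
    """Equal-weight Stouffer combination of independent one-sided p-values."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    p = np.clip(p, 1e-300, 1 - 1e-16)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))


def _combine_dependent(p_list, rho: float) -> float:
    """Stouffer combination with exchangeable inter-comparison correlation."""
    p = np.clip(np.asarray(list(p_list), dtype=float), 1e-300, 1 - 1e-16)
    z = stats.norm.isf(p)
    k = p.size
    denom = np.sqrt(k + k * (k - 1) * rho)
    return float(stats.norm.sf(z.sum() / denom))


def estimate_column_correlation(fc: pd.DataFrame) -> float:
    """Mean off-diagonal correlation between fold-change columns.

    One-on-group fold changes share the control-group mean, which induces a
    positive correlation of roughly 1/(n_control + 1) between comparisons;
    estimating it from the data keeps the combined p-values calibrated.
    Clipped to [0, 0.95].
    """
    corr = np.corrcoef(fc.to_numpy(dtype=float), rowvar=False)
    k = corr.shape[0]
    off = corr[~np.eye(k, dtype=bool)]
    return float(np.clip(np.nanmean(off), 0.0, 0.95))


# ---------------------------------------------------------------------------
# Pipeline-level driver
# ---------------------------------------------------------------------------

def essential_genes(matrix: ExpressionMatrix, gene_set: GeneSet) -> list[str]:
    """Key genes of a perturbed set.

    Members whose domesticated-minus-wild mean difference deviates from the
    all-gene mean difference by more than one SD of all genes' differences
    AND whose per-gene Welch t p-value (unadjusted) is <= 0.05.
    """
    ww = matrix.group_values("WW")
    dd = matrix.group_values("DD")
    diff = dd.mean(axis=1) - ww.mean(axis=1)
    center, spread = diff.mean(), diff.std(ddof=1)
    _, p = welch_t_matrix(dd, ww)
    diff = pd.Series(diff, index=matrix.values.index)
    p = pd.Series(p, index=matrix.values.index)
    members = sorted(g for g in gene_set.member_genes if g in diff.index)
    return [
        g for g in members
        if abs(diff[g] - center) > spread and p[g] <= 0.05
    ]


def run_enrichment(
    matrix: ExpressionMatrix,
    gene_sets,
    q_threshold: float = 0.1,
    p_2d_focus: float = 0.02,
    exclude_groups: set | None = frozenset({"Human Diseases"}),
    min_size: int = 10,
    max_size: int = 500,
    test_group: str = "DD",
    control_group: str = "WW",
) -> pd.DataFrame:
    """Full set-perturbation scan between the pure stocks.

    For every retained gene set and every direction, each test replicate's
    one-on-group comparison is tested and the per-replicate p-values are
    combined by a dependence-adjusted Stouffer (correlation estimated from
    the fold-change columns).  BH adjustment runs across sets within each
    direction.  Output columns: set_id, functional_group, direction, n_members,
    p_raw, p_adj, mean_stat, significant, focus_2d, essential_genes.
    """
    exclude_groups = set(exclude_groups or ())
    fc = one_on_group_foldchanges(matrix, test_group, control_group)
    present = set(matrix.values.index)
    usable = []
    for gs in gene_sets:
        if gs.functional_group in exclude_groups:
            continue
        n_in = len(gs.member_genes & present)
        if min_size <= n_in <= max_size:
            usable.append(gs)
    if not usable:
        log.warning("no gene sets pass the size filter")
        return pd.DataFrame(
            columns=[
                "set_id", "functional_group", "direction", "n_members",
                "p_raw", "p_adj", "mean_stat", "significant", "focus_2d",
                "essential_genes",
            ]
        )
    rho = estimate_column_correlation(fc)
    rho_abs = estimate_column_correlation(fc.abs())
    rows = []
    for direction in DIRECTIONS:
        r = rho_abs if direction == "two_way" else rho
        for gs in usable:
            members = sorted(gs.member_genes & present)
            p_reps = [gage_set_test(fc[col], gs, direction) for col in fc.columns]
            p_comb = _combine_dependent(p_reps, r)
            sel = fc.loc[members].to_numpy()
            mean_stat = float(np.abs(sel).mean() if direction == "two_way" else sel.mean())
            rows.append(
                {
                    "set_id": gs.set_id,
                    "functional_group": gs.functional_group,
                    "direction": direction,
                    "n_members": len(members),
                    "p_raw": p_comb,
                    "mean_stat": mean_stat,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.concatenate(
        [bh_adjust(out.loc[out["direction"] == d, "p_raw"]) for d in DIRECTIONS]
    ) if len(out) else []
    # restore: bh within direction, rows are grouped by direction in order
    out["significant"] = out["p_adj"] <= q_threshold
    out["focus_2d"] = (out["direction"] == "two_way") & (out["p_raw"] <= p_2d_focus)
    by_id = {gs.set_id: gs for gs in usable}
    out["essential_genes"] = [
        ";".join(essential_genes(matrix, by_id[row.set_id])) if row.significant else ""
        for row in out.itertuples()
    ]
    return out.sort_values(["direction", "p_raw"], kind="mergesort").reset_index(drop=True)


def assign_primary_function(gene_id: str, candidate_sets, analysed_genes) -> str:
    """Pick one function for a gene that belongs to several sets.

    The winning set is the candidate with the most members among the full
    analysed gene list; ties break on the lexicographically smaller set_id.
    """
    candidates = [gs for gs in candidate_sets if gene_id in gs.member_genes]
    if not candidates:
        raise ValueError(f"gene {gene_id} belongs to no candidate set")
    analysed = set(analysed_genes)
    return min(
        candidates, key=lambda gs: (-len(gs.member_genes & analysed), gs.set_id)
    ).set_id
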