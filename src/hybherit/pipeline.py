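"""End-to-end orchestration: QC → collapse → DE → heritability → enrichment.

A single :class:`RunConfig` drives the whole analysis, either from files on
disk (feature tables + sample sheet + annotation + GMT) or from a simulation
block.  The run report records probe/gene counts at every filtering stage so
each attrition step is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import array_io, collapse, diffexpr, enrichment as enr, heritability as herit
from .containers import CROSS_TYPES, ExpressionMatrix
from .simulate import SimulationConfig, simulate_experiment, truth_vs_calls

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured configuration for one pipeline run."""

    # exactly one of (input paths, simulate) must be given
    feature_paths: dict | None = None      # array_id -> file
    sample_sheet: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    simulate: SimulationConfig | None = None

    outdir: str = "hybherit_out"
    seed: int = 11

    # thresholds (study defaults)
    alpha_de: float = 0.05
    fc: float = 1.25
    anova_fdr: float = 0.10
    alpha_snk: float = 0.05
    q_set: float = 0.1
    p_2d: float = 0.02
    ratio_plot_cap: float = 5.0
    lowess_span: float = 0.3
    qc_frac: float = 0.75
    qc_min_groups: int = 2

    # scheme switches
    parental_scheme: str = "line_sharing"   # or "literal"
    exclude_groups: tuple = ("Human Diseases",)
    make_figures: bool = True
    skip_enrichment: bool = False

    def __post_init__(self) -> None:
        has_files = self.sample_sheet is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError("exactly one of input paths / simulate block required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        return cls(**raw)


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    accuracy: dict | None = None


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = simulate_experiment(config.simulate, seed=config.seed)
        return sim.features, sim.samples, sim.annotation, sim.gene_sets, sim
    features, samples = array_io.read_feature_tables(
        config.feature_paths, config.sample_sheet
    )
    annotation = collapse.read_annotation(config.annotation)
    gene_sets = enr.read_gmt(config.gene_sets) if config.gene_sets else []
    return features, samples, annotation, gene_sets, None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write all result tables under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    counts = report.counts

    features, samples, annotation, gene_sets, sim = _load_inputs(config)
    counts["probes_read"] = len(next(iter(features.values())))

    features = array_io.floor_intensities(features)
    matrix = array_io.lowess_normalize(features, samples, span=config.lowess_span)
    retained = array_io.qc_filter(
        features, samples, frac_threshold=config.qc_frac, min_groups=config.qc_min_groups
    )
    counts["probes_post_qc"] = len(retained)
    matrix = matrix.subset_rows(retained)

    annotated = collapse.drop_unannotated(matrix, annotation)
    counts["probes_annotated"] = annotated.n_rows

    # stock-contrast branch: collapse on the per-probe Welch t p-value
    t_p = pd.Series(
        diffexpr.welch_t_matrix(annotated.group_values("DD"), annotated.group_values("WW"))[1],
        index=annotated.values.index,
    )
    gene_matrix_t, chosen_t = collapse.collapse_to_genes(annotated, annotation, t_p)
    counts["genes_collapsed"] = gene_matrix_t.n_rows

    de = diffexpr.de_between_stocks(gene_matrix_t, alpha=config.alpha_de, fc_threshold=config.fc)
    counts["genes_de"] = int(de["significant"].sum())
    report.tables["de"] = de

    # four-group branch: collapse on the per-probe Welch ANOVA p-value
    a_p = pd.Series(
        diffexpr.welch_anova_matrix(
            [annotated.group_values(ct) for ct in CROSS_TYPES]
        )[1],
        index=annotated.values.index,
    )
    gene_matrix_a, chosen_a = collapse.collapse_to_genes(annotated, annotation, a_p)
    posthoc = diffexpr.anova_posthoc_scan(
        gene_matrix_a, anova_fdr=config.anova_fdr, alpha_snk=config.alpha_snk
    )
    counts["genes_anova_significant"] = int(
        (posthoc["anova_p_adj"] <= config.anova_fdr).sum()
    )
    report.tables["posthoc"] = posthoc

    calls = herit.call_heritability(gene_matrix_a, posthoc, scheme=config.parental_scheme)
    counts["genes_categorized"] = int(calls["gene_id"].nunique())
    report.tables["calls"] = calls
    summary = herit.heritability_table(calls, include_ratio_above=config.ratio_plot_cap)
    report.tables["herit_summary"] = summary

    enrich = enr.run_enrichment(
        gene_matrix_t,
        gene_sets,
        q_threshold=config.q_set,
        p_2d_focus=config.p_2d,
        exclude_groups=set(config.exclude_groups),
    ) if gene_sets and not config.skip_enrichment else pd.DataFrame()
    report.tables["enrichment"] = enrich

    # -- write outputs --------------------------------------------------------
    gene_matrix_t.to_tsv(outdir / "gene_matrix.tsv")
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    ph_out = posthoc.copy()
    ph_out["significant_pairs"] = ph_out["significant_pairs"].map(diffexpr.format_pairs)
    ph_out.to_csv(outdir / "posthoc_table.tsv", sep="\t", index=False)
    calls.to_csv(outdir / "heritability_calls.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "heritability_summary.tsv", sep="\t", index=False)
    if len(enrich):
        enrich.to_csv(outdir / "enrichment_table.tsv", sep="\t", index=False)

    if config.make_figures:
        de_genes = de.index[de["significant"]]
        if len(de_genes) >= 2:
            leaf_orders = cluster_heatmap(
                gene_matrix_t.subset_rows(de_genes),
                direction_split=True,
                de_table=de,
                outdir=outdir,
            )
            report.outputs["leaf_orders"] = leaf_orders
        n_plotted = ratio_scatter(calls, cap=config.ratio_plot_cap,
                                  path=outdir / "ratio_scatter.svg")
        report.outputs["scatter_points"] = n_plotted

    if sim is not None:
        report.accuracy = truth_vs_calls(sim.truth_genes, calls, sim.annotation)

    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump({"counts": counts}, fh, sort_keys=False)
    log.info("stage counts: %s", counts)
    return report


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def correlation_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows sit at distance 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(values, metric="correlation")
    if np.isnan(d).any():
        log.warning("constant-expression rows: correlation undefined, distance set to 1")
        d = np.nan_to_num(d, nan=1.0)
    return d


def cluster_rows(values: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Average-linkage clustering on 1 - Pearson; returns (linkage, leaf order)."""
    link = hierarchy.linkage(correlation_distance(values), method="average")
    return link, list(hierarchy.leaves_list(link))


def cluster_heatmap(
    matrix: ExpressionMatrix,
    direction_split: bool = True,
    de_table: pd.DataFrame | None = None,
    outdir: Path | str = ".",
) -> dict[str, list[str]]:
    """Clustered heatmap(s) of DE-gene expression; returns leaf orderings.

    With ``direction_split`` the genes are split into up- and
    down-in-domesticated panels (sign of log2_fc from ``de_table``), matching
    how the study displayed its expression profiles.  Each panel's leaf order
    is written alongside the figure.
    """
    if matrix.n_rows < 2:
        raise ValueError("need at least 2 genes to cluster")
    outdir = Path(outdir)
    panels: dict[str, pd.DataFrame] = {}
    if direction_split and de_table is not None:
        fc = de_table.loc[matrix.values.index, "log2_fc"]
        up, down = matrix.values[fc > 0], matrix.values[fc <= 0]
        if len(up) >= 2:
            panels["up"] = up
        if len(down) >= 2:
            panels["down"] = down
        if not panels:
            panels["all"] = matrix.values
    else:
        panels["all"] = matrix.values
    leaf_orders: dict[str, list[str]] = {}
    for name, block in panels.items():
        link, order = cluster_rows(block.to_numpy(dtype=float))
        ordered = block.iloc[order]
        leaf_orders[name] = list(ordered.index)
        fig, ax = plt.subplots(
            figsize=(6, max(2.0, 0.12 * len(ordered))), constrained_layout=True
        )
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(ordered.columns)))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
        ax.set_yticks([])
        ax.set_title(f"{name}-regulated transcripts (D vs W)")
        fig.colorbar(im, ax=ax, label="log2 ratio")
        fig.savefig(outdir / f"heatmap_{name}.png", dpi=120)
        plt.close(fig)
        with open(outdir / f"leaf_order_{name}.txt", "w") as fh:
            fh.write("\n".join(leaf_orders[name]) + "\n")
    return leaf_orders


def ratio_scatter(calls: pd.DataFrame, cap: float = 5.0, path="ratio_scatter.svg") -> int:
    """Scatter of additivity (alpha) vs delta/alpha, coloured by hybrid.

    Points with |delta/alpha| beyond ``cap`` are omitted from the figure only
    (the summary table always keeps them).  Returns the number of points
    plotted.
    """
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    n_plotted = 0
    if calls.empty:
        log.warning("no heritability calls; empty scatter written")
    else:
        shown = calls[calls["ratio"].abs() <= cap]
        n_plotted = int(shown.shape[0])
        for hybrid, colour in (("WD", "tab:blue"), ("DW", "tab:orange")):
            sub = shown[shown["hybrid"] == hybrid]
            ax.scatter(sub["alpha"], sub["ratio"], s=12, alpha=0.7,
                       color=colour, label=hybrid)
        ax.legend(title="hybrid")
    ax.axhline(0, lw=0.5, color="grey")
    ax.set_xlabel(r"additivity $\alpha$")
    ax.set_ylabel(r"$\delta/\alpha$")
    fig.savefig(path)
    plt.close(fig)
    return n_plotted
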