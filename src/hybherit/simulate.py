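"""Synthetic two-colour microarray experiments with planted inheritance modes.

The generator emulates the study design end-to-end: four cross types
(pure wild WW, reciprocal hybrids WD / DW, pure domesticated DD) x R
replicate arrays, dual-channel probes hybridised against a common reference
pool, multiple probes per gene, technical controls, saturated / low-signal /
outlier probes, an annotation table covering a configurable fraction of
genes, and GMT gene sets with planted coordinated perturbations.  Every
planted quantity is recorded in a machine-readable truth record so each
pipeline stage can be validated without any external data.

Inheritance planting: a DE gene receives a wild/domesticated mean difference
of ``effect_size`` log2 units (random sign).  Its hybrid means follow the
planted mode — mid-parent (additive), one parental mean (dominant), beyond
the parental range by half an alpha past the +-1.5 delta/alpha boundary
(over-dominant) — or, for maternal genes, each hybrid copies its mother's
mean so the two reciprocal hybrids disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CROSS_TYPES
from .enrichment import GeneSet, write_gmt

MODE_NAMES = (
    "wild_over_dominant",
    "wild_dominant",
    "additive",
    "domesticated_dominant",
    "domesticated_over_dominant",
)

#: planted delta/alpha per mode; over-dominant targets sit half an alpha
#: beyond the +-1.5 class boundary so the true class survives default noise
_MODE_RATIO = {
    "wild_over_dominant": -2.0,
    "wild_dominant": -1.0,
    "additive": 0.0,
    "domesticated_dominant": 1.0,
    "domesticated_over_dominant": 2.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults mirror the study design."""

    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)      # uniform inclusive range
    n_controls: int = 100
    annotated_fraction: float = 0.62
    replicates_per_cross: int = 6
    noise_sd: float = 0.25                         # biological, log2 scale
    probe_noise_sd: float = 0.05                   # technical, per probe
    de_fraction: float = 0.25                      # genes with planted W/D effect
    mode_proportions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.2, 0.1)
    effect_size: float = 1.0                       # |log2| W - D difference
    maternal_gene_fraction: float = 0.15           # of DE genes, maternal instead
    n_gene_sets: int = 50
    null_set_size: int = 30
    planted_set_spec: tuple = (("up", 1.0, 50), ("two_way", 1.0, 50))
    dye_bias_amplitude: float = 0.3                # log2 units, sinusoidal in A
    saturated_fraction: float = 0.005
    outlier_fraction: float = 0.002
    low_signal_fraction: float = 0.05
    seed: int = 11

    def validate(self) -> None:
        props = np.asarray(self.mode_proportions, dtype=float)
        if props.size != 5 or (props < 0).any() or abs(props.sum() - 1) > 1e-9:
            raise ValueError("mode_proportions must be 5 non-negative values summing to 1")
        for name in ("annotated_fraction", "de_fraction", "maternal_gene_fraction",
                     "saturated_fraction", "outlier_fraction", "low_signal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.replicates_per_cross < 2:
            raise ValueError("need at least 2 replicates per cross")


@dataclass
class SimulatedExperiment:
    """In-memory synthetic experiment plus its planted truth."""

    config: SimulationConfig
    features: dict[str, pd.DataFrame]
    samples: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: list[GeneSet]
    truth_genes: pd.DataFrame      # per gene: modes, categories, planted means
    truth_probes: pd.DataFrame     # per probe: gene, qc_fate
    truth_sets: pd.DataFrame       # per set: direction, shift
    truth_log_ratios: pd.DataFrame = field(repr=False)  # probes x arrays, pre-bias

    def write(self, outdir) -> dict[str, Path]:
        """Write every file dialect the pipeline reads; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        sheet = self.samples.reset_index()
        for array_id in self.samples.index:
            p = outdir / f"{array_id}.tsv"
            tab = self.features[array_id].reset_index()
            for col in ("is_control", "flag_saturated", "flag_outlier", "flag_above_background"):
                tab[col] = tab[col].astype(int)
            tab.to_csv(p, sep="\t", index=False)
            paths[array_id] = p
        # relative names keep the directory relocatable (and reruns comparable)
        sheet["file"] = [paths[a].name for a in sheet["array_id"]]
        sheet_path = outdir / "sample_sheet.tsv"
        sheet[["array_id", "file", "cross_type", "replicate", "slide_id"]].to_csv(
            sheet_path, sep="\t", index=False
        )
        ann_path = outdir / "annotation.tsv"
        self.annotation.reset_index().to_csv(ann_path, sep="\t", index=False)
        gmt_path = outdir / "gene_sets.gmt"
        write_gmt(self.gene_sets, gmt_path)
        self.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
        self.truth_probes.to_csv(outdir / "truth_probes.tsv", sep="\t")
        self.truth_sets.to_csv(outdir / "truth_sets.tsv", sep="\t")
        paths.update(
            sample_sheet=sheet_path, annotation=ann_path, gene_sets=gmt_path,
        )
        return paths


def _plant_gene_means(config: SimulationConfig, rng: np.random.Generator):
    """Per-gene planted means for WW/WD/DW/DD plus truth labels."""
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    baseline = rng.normal(0.0, 0.5, size=n)

    n_de = round(n * config.de_fraction)
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    sign = rng.choice([-1.0, 1.0], size=n)

    w_mean = baseline.copy()
    d_mean = baseline.copy()
    half = config.effect_size / 2.0
    w_mean[is_de] += sign[is_de] * half
    d_mean[is_de] -= sign[is_de] * half

    n_maternal = round(n_de * config.maternal_gene_fraction)
    maternal_idx = rng.choice(de_idx, size=n_maternal, replace=False)
    is_maternal = np.zeros(n, dtype=bool)
    is_maternal[maternal_idx] = True

    mode = np.array(["none"] * n, dtype=object)
    mode_planted = np.setdiff1d(de_idx, maternal_idx)
    draw = rng.choice(len(MODE_NAMES), size=mode_planted.size,
                      p=np.asarray(config.mode_proportions))
    mode[mode_planted] = np.asarray(MODE_NAMES, dtype=object)[draw]
    mode[maternal_idx] = "maternal"

    mid = (w_mean + d_mean) / 2.0
    alpha = (w_mean - d_mean) / 2.0
    wd_mean = mid.copy()   # W mother x D father
    dw_mean = mid.copy()
    for name, ratio in _MODE_RATIO.items():
        sel = mode == name
        hyb = mid[sel] - ratio * alpha[sel]
        wd_mean[sel] = hyb
        dw_mean[sel] = hyb
    wd_mean[is_maternal] = w_mean[is_maternal]
    dw_mean[is_maternal] = d_mean[is_maternal]

    # per-hybrid true mode: maternal genes track their mother
    def _mode_for(hybrid_mean):
        out = mode.copy()
        sel = is_maternal
        out[sel] = np.where(
            hybrid_mean[sel] == w_mean[sel], "wild_dominant", "domesticated_dominant"
        )
        return out

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": is_de,
            "planted_mode": mode,
            "true_mode_WD": _mode_for(wd_mean),
            "true_mode_DW": _mode_for(dw_mean),
            "true_effect_category": np.where(
                is_maternal, "maternal", np.where(is_de, "parental", "none")
            ),
            "true_W_mean": w_mean,
            "true_D_mean": d_mean,
            "true_WD_mean": wd_mean,
            "true_DW_mean": dw_mean,
        }
    ).set_index("gene_id")
    truth.loc[~pd.Series(is_de, index=truth.index), ["true_mode_WD", "true_mode_DW"]] = "none"
    return truth


def simulate_experiment(config: SimulationConfig | None = None, **overrides) -> SimulatedExperiment:
    """Generate a complete deterministic synthetic experiment.

    All randomness flows from ``config.seed``; identical configs give
    byte-identical written files.
    """
    config = replace(config or SimulationConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    truth = _plant_gene_means(config, rng)
    gene_ids = list(truth.index)
    n = len(gene_ids)

    # annotation: a fraction of genes carry a BLAST symbol and/or a KO number
    annotated = rng.random(n) < config.annotated_fraction
    kind = rng.choice(3, size=n)   # 0 both, 1 symbol only, 2 KO only
    symbols = np.array([f"GENE{i}" for i in range(n)], dtype=object)
    kos = np.array([f"K{i:05d}" for i in range(n)], dtype=object)
    gene_symbol = np.where(annotated & (kind != 2), symbols, "")
    gene_ko = np.where(annotated & (kind != 1), kos, "")

    # planted gene sets among annotated, non-DE genes; shifts move the D mean
    ann_gene = pd.DataFrame({"gene_id": gene_symbol, "ko_id": gene_ko}, index=gene_ids)
    usable_mask = (np.asarray(gene_symbol) != "") & ~truth["is_de"].to_numpy()
    pool = list(np.array(gene_ids)[usable_mask])
    rng.shuffle(pool)
    n_needed = sum(size for _, _, size in config.planted_set_spec)
    if len(pool) < max(n_needed, 1 if config.n_gene_sets else 0):
        raise ValueError(
            f"only {len(pool)} annotated non-DE genes available for gene sets; "
            f"planted sets need {n_needed} — increase n_genes or shrink the sets"
        )
    gene_sets, set_rows, cursor = [], [], 0
    for i, (direction, shift, size) in enumerate(config.planted_set_spec):
        members = pool[cursor:cursor + size]
        cursor += size
        d_shift = np.full(len(members), float(shift))
        if direction == "down":
            d_shift = -d_shift
        elif direction == "two_way":
            d_shift[1::2] *= -1.0
        for g, s in zip(members, d_shift):
            truth.at[g, "true_D_mean"] += s
            # hybrids stay additive for planted-set genes
            mid = (truth.at[g, "true_W_mean"] + truth.at[g, "true_D_mean"]) / 2
            truth.at[g, "true_WD_mean"] = mid
            truth.at[g, "true_DW_mean"] = mid
        sid = f"planted_{direction}_{i}"
        member_syms = frozenset(ann_gene.at[g, "gene_id"] for g in members)
        gene_sets.append(GeneSet(sid, member_syms, "Planted"))
        set_rows.append({"set_id": sid, "direction": direction, "shift": float(shift),
                         "members": ";".join(sorted(member_syms))})
    for i in range(config.n_gene_sets):
        take = [pool[(cursor + i * 7 + j) % len(pool)] for j in range(config.null_set_size)]
        sid = f"null_{i:03d}"
        groups = ("Metabolism", "Organismal Systems", "Cellular Processes", "Human Diseases")
        member_syms = frozenset(ann_gene.at[g, "gene_id"] for g in take)
        gene_sets.append(GeneSet(sid, member_syms, groups[i % len(groups)]))
        set_rows.append({"set_id": sid, "direction": "null", "shift": 0.0,
                         "members": ";".join(sorted(member_syms))})
    truth_sets = pd.DataFrame(
        set_rows, columns=["set_id", "direction", "shift", "members"]
    ).set_index("set_id")

    # probes: 1..k per gene plus technical controls
    lo, hi = config.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=n)
    probe_gene_idx = np.repeat(np.arange(n), n_probes_per_gene)
    probe_ids = [
        f"{gene_ids[g]}_p{j+1}"
        for g, cnt in zip(range(n), n_probes_per_gene)
        for j in range(cnt)
    ]
    control_ids = [f"ctrl_{i:04d}" for i in range(config.n_controls)]
    all_probe_ids = probe_ids + control_ids
    n_reg = len(probe_ids)
    n_all = len(all_probe_ids)

    annotation = pd.DataFrame(
        {
            "probe_id": all_probe_ids,
            "gene_id": [gene_symbol[g] for g in probe_gene_idx] + [""] * config.n_controls,
            "ko_id": [gene_ko[g] for g in probe_gene_idx] + [""] * config.n_controls,
        }
    ).set_index("probe_id")

    # QC fates for regular probes
    fate = np.array(["pass"] * n_reg, dtype=object)
    n_sat = round(n_reg * config.saturated_fraction)
    n_out = round(n_reg * config.outlier_fraction)
    n_low = round(n_reg * config.low_signal_fraction)
    special = rng.choice(n_reg, size=n_sat + n_out + n_low, replace=False)
    sat_idx = special[:n_sat]
    out_idx = special[n_sat:n_sat + n_out]
    low_idx = special[n_sat + n_out:]
    fate[sat_idx], fate[out_idx], fate[low_idx] = "saturated", "outlier", "low_signal"

    # sample sheet: one replicate of each cross per slide
    R = config.replicates_per_cross
    rows = []
    for r in range(1, R + 1):
        for ct in CROSS_TYPES:
            rows.append(
                {"array_id": f"{ct}_r{r}", "file": "", "cross_type": ct,
                 "replicate": r, "slide_id": f"slide{r}"}
            )
    samples = pd.DataFrame(rows).set_index("array_id")

    # channel model: per-probe reference abundance, planted log ratios + noise
    abundance = rng.normal(10.0, 1.5, size=n_reg)
    cross_mean = {
        "WW": truth["true_W_mean"].to_numpy(),
        "DD": truth["true_D_mean"].to_numpy(),
        "WD": truth["true_WD_mean"].to_numpy(),
        "DW": truth["true_DW_mean"].to_numpy(),
    }
    features: dict[str, pd.DataFrame] = {}
    truth_m: dict[str, np.ndarray] = {}
    for array_id in samples.index:
        ct = samples.at[array_id, "cross_type"]
        bio = rng.normal(0.0, config.noise_sd, size=n)            # per gene
        m = cross_mean[ct][probe_gene_idx] + bio[probe_gene_idx]
        m = m + rng.normal(0.0, config.probe_noise_sd, size=n_reg)  # per probe
        truth_m[array_id] = m
        # symmetric split of the log ratio across channels keeps the spot's
        # average log intensity A independent of expression
        mid = abundance + rng.normal(0.0, 0.05, size=n_reg)
        cy5 = 2.0 ** (mid - m / 2)
        cy3 = 2.0 ** (mid + m / 2)
        a = 0.5 * np.log2(cy3 * cy5)
        if config.dye_bias_amplitude:
            cy3 = cy3 * 2.0 ** (config.dye_bias_amplitude * np.sin(a))
        above = np.ones(n_reg, dtype=bool)
        sat = np.zeros(n_reg, dtype=bool)
        outl = np.zeros(n_reg, dtype=bool)
        # low-signal probes: dim and above background on too few arrays
        rep = samples.at[array_id, "replicate"]
        above[low_idx] = (low_idx + rep) % (R + 2) == 0   # deterministic sparse pattern
        cy3[low_idx] *= 2.0**-6
        cy5[low_idx] *= 2.0**-6
        # saturated/outlier probes flagged on a subset of arrays
        sat[sat_idx] = (sat_idx + rep) % 3 == 0
        outl[out_idx] = (out_idx + rep) % 4 == 0
        cy3_ctrl = 2.0 ** rng.normal(8.0, 1.0, size=config.n_controls)
        feats = pd.DataFrame(
            {
                "cy3": np.concatenate([cy3, cy3_ctrl]),
                "cy5": np.concatenate([cy5, cy3_ctrl * 2.0 ** rng.normal(0, 0.1, config.n_controls)]),
                "is_control": np.concatenate([np.zeros(n_reg, bool), np.ones(config.n_controls, bool)]),
                "flag_saturated": np.concatenate([sat, np.zeros(config.n_controls, bool)]),
                "flag_outlier": np.concatenate([outl, np.zeros(config.n_controls, bool)]),
                "flag_above_background": np.concatenate([above, np.ones(config.n_controls, bool)]),
            },
            index=pd.Index(all_probe_ids, name="probe_id"),
        )
        features[array_id] = feats

    # every saturated/outlier probe must be flagged on >= 1 array; the modular
    # patterns above can miss some, so force a flag on the first array
    first = samples.index[0]
    features[first].iloc[sat_idx, features[first].columns.get_loc("flag_saturated")] = True
    features[first].iloc[out_idx, features[first].columns.get_loc("flag_outlier")] = True

    truth_probes = pd.DataFrame(
        {
            "probe_id": all_probe_ids,
            "gene_id": [gene_ids[g] for g in probe_gene_idx] + [""] * config.n_controls,
            "qc_fate": list(fate) + ["control"] * config.n_controls,
        }
    ).set_index("probe_id")
    truth_log_ratios = pd.DataFrame(
        {a: truth_m[a] for a in samples.index}, index=pd.Index(probe_ids, name="probe_id")
    )

    return SimulatedExperiment(
        config=config,
        features=features,
        samples=samples,
        annotation=annotation,
        gene_sets=gene_sets,
        truth_genes=truth,
        truth_probes=truth_probes,
        truth_sets=truth_sets,
        truth_log_ratios=truth_log_ratios,
    )


# ---------------------------------------------------------------------------
# Truth vs calls
# ---------------------------------------------------------------------------

def truth_vs_calls(truth_genes: pd.DataFrame, calls: pd.DataFrame,
                   annotation: pd.DataFrame | None = None) -> dict:
    """Score inheritance-mode calls against the planted truth.

    ``calls`` is the heritability call table (gene_id = annotation symbol or
    KO when no symbol exists; hybrid; mode; ratio).  Returns a dict with the
    per-(gene, hybrid) confusion table, overall accuracy and per-class recall.
    Calls whose gene cannot be matched to a truth entry raise.
    """
    if annotation is not None:
        sym2gene = {}
        for probe, row in annotation.iterrows():
            key = row["gene_id"] or row["ko_id"]
            if key:
                sym2gene[key] = probe.rsplit("_p", 1)[0]
    else:
        sym2gene = {g: g for g in truth_genes.index}

    records = []
    for row in calls.itertuples():
        gene = sym2gene.get(row.gene_id)
        if gene is None or gene not in truth_genes.index:
            raise ValueError(f"call for unknown gene {row.gene_id}")
        true_mode = truth_genes.at[gene, f"true_mode_{row.hybrid}"]
        called = _coarse(row.mode, row.ratio)
        records.append({"gene_id": gene, "hybrid": row.hybrid,
                        "true": true_mode, "called": called})
    scored = pd.DataFrame(records)
    scored = scored[scored["true"] != "none"]
    if scored.empty:
        return {"confusion": pd.DataFrame(), "accuracy": float("nan"), "n": 0}
    confusion = pd.crosstab(scored["true"], scored["called"])
    accuracy = float((scored["true"] == scored["called"]).mean())
    recall = {
        cls: float((sub["called"] == cls).mean())
        for cls, sub in scored.groupby("true")
    }
    return {"confusion": confusion, "accuracy": accuracy, "recall": recall,
            "n": int(len(scored))}


def _coarse(mode: str, ratio: float) -> str:
    if mode == "over_dominant":
        return "wild_over_dominant" if ratio < 0 else "domesticated_over_dominant"
    return mode


def detection_table(truth_sets: pd.DataFrame, enrichment: pd.DataFrame) -> pd.DataFrame:
    """Planted-set detection summary: was each planted set called, and how."""
    rows = []
    for sid, row in truth_sets[truth_sets["direction"] != "null"].iterrows():
        sub = enrichment[enrichment["set_id"] == sid]
        hit = sub[sub["significant"]]
        rows.append(
            {
                "set_id": sid,
                "planted_direction": row["direction"],
                "detected": bool(len(hit)),
                "detected_directions": ";".join(sorted(hit["direction"].unique())),
                "best_p": float(sub["p_raw"].min()) if len(sub) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
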