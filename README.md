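# hybherit

Inheritance of gene expression in reciprocal hybrid crosses, from two-colour
microarray data.

When a wild (W) and a domesticated (D) fish stock are crossed in both
directions (W♀×D♂ and D♀×W♂) alongside the pure crosses, the expression level
of each differentially expressed gene in the hybrids reveals *how* the
difference is inherited: at mid-parent level (additive), tracking one parent
(dominant), outside the parental range (over-dominant) — or tracking
whichever line supplied the mother (a maternal effect, common in fish embryos
that still run largely on maternally deposited mRNA and yolk). Separating
maternal from stock-of-origin dominance matters, for example, when assessing
what escaped farmed females can introgress into wild salmon populations.

`hybherit` implements the complete analysis as a tested, reusable pipeline:

* **QC & normalization** — per-array feature tables with vendor flags;
  intensity flooring at 1; within-array Lowess correction of the
  intensity-dependent dye trend on the MA scale; removal of controls,
  saturated and outlier probes; retention of probes "positive and
  significant" against background on ≥ 75 % of arrays in ≥ 2 of the 4 groups.
* **Probe→gene collapse** — BLAST/KEGG-annotated probes only; lowest-p probe
  per gene.
* **Differential expression** — Welch t (D vs W) with Benjamini–Hochberg
  p ≤ 0.05 and fold change ≥ 1.25; Welch one-way ANOVA across the four cross
  types at FDR 10 % with Student–Newman–Keuls post-hoc contrasts.
* **Heritability classification** — per gene and hybrid,
  α = (W−D)/2, δ = (W+D)/2 − hybrid; δ/α ∈ (−0.5, 0.5) additive,
  (−1.5, −0.5] wild dominant, [0.5, 1.5) domesticated dominant, beyond ±1.5
  over-dominant; maternal/paternal/parental effect categories from the
  significant post-hoc contrasts.
* **Gene-set perturbation** — GAGE-style one-on-group comparisons of each
  domesticated replicate against the wild group mean, set-vs-all t-tests in
  up/down/two-way directions, dependence-adjusted Stouffer combination,
  essential-gene extraction.
* **Synthetic experiments** — a generator that emulates the full design
  (4 crosses × 6 dual-channel arrays, multi-probe genes, QC structure, dye
  bias, planted inheritance modes and perturbed gene sets) with a
  machine-readable truth record, so every stage is testable end to end.

## Worked example

Run the full pipeline on the default synthetic experiment (2000 genes, 500
with planted W/D effects of 1.0 log2 units, replicate SD 0.25, seed 11):

```python
from hybherit import RunConfig, SimulationConfig, run_pipeline

report = run_pipeline(RunConfig(simulate=SimulationConfig(seed=11),
                                outdir="out", seed=11))
for stage, count in report.counts.items():
    print(stage, count)
print("mode accuracy: %.3f" % report.accuracy["accuracy"])
```

prints

```
probes_read 4107
probes_post_qc 3779
probes_annotated 2373
genes_collapsed 1209
genes_de 410
genes_anova_significant 440
genes_categorized 422
mode accuracy: 0.919
```

reading: 4107 probes were generated, 3779 survive the QC retention rule,
2373 carry annotations, collapsing to 1209 unique genes; 410 genes pass the
Welch-t + fold-change contrast between the pure stocks, 440 differ across
the four cross types by ANOVA, and 422 receive inheritance calls. 91.9 % of
the per-gene, per-hybrid mode calls match the planted truth.

The per-hybrid class summary (`report.tables["herit_summary"]`):

```
hybrid  n_genes  wild_over_dominant  wild_dominant  additive  domesticated_dominant  domesticated_over_dominant
    DW      418                 8.9           12.9      48.8                   19.9                         9.6
    WD      415                 8.2           23.6      47.2                   13.3                         7.7
```

Columns are percentages. The planted mode mix was 10/20/40/20/10 plus 15 %
maternal genes — maternal genes surface as wild-dominant in the W-mother
hybrid (WD) and domesticated-dominant in the D-mother hybrid (DW), which is
exactly the asymmetry visible between the two rows.

The enrichment table flags both planted gene sets and nothing else: the
coordinated "up" set (p_adj ≈ 5e-35, direction `up`) and the bidirectional
set, invisible one-directionally but overwhelming in the two-way test
(p_adj ≈ 2e-22).

The same run is available from a shell:

```bash
hybherit simulate --seed 11 --outdir data/
hybherit run --config run.yaml --seed 11 --outdir out/
```

where `run.yaml` either points at feature tables / sample sheet / annotation
/ GMT files or contains a `simulate:` block.

## Layout

```
src/hybherit/
  containers.py    ExpressionMatrix, cross-type codes
  array_io.py      feature tables, flooring, Lowess, QC retention
  collapse.py      annotation filter, lowest-p probe collapse
  diffexpr.py      Welch t / Welch ANOVA / BH / SNK, DE scans
  heritability.py  alpha-delta classification, effect categories
  enrichment.py    GMT IO, one-on-group GAGE-style tests, essential genes
  simulate.py      synthetic experiment generator + truth scoring
  pipeline.py      orchestration, clustering, figures
  cli.py           `hybherit` command (run / simulate / herit / enrich)
docs/methods.md    model and design documentation
tests/             unit, property and end-to-end suites
```
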