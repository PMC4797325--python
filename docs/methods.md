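# Methods

`hybherit` analyses two-colour microarray experiments that compare a wild (W)
and a domesticated (D) fish stock together with their reciprocal F1 hybrids
(W♀×D♂ = WD, D♀×W♂ = DW). This note documents the models, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Design and data model

Each array hybridises one Cy3-labelled test sample against a Cy5-labelled
common reference pool, so every expression value is a log2(Cy3/Cy5) ratio
against the same baseline and all 4 cross types × R replicates (default
R = 6, i.e. 24 arrays) are mutually comparable. Replicates are biological
pools; the pipeline never models individuals.

## QC and normalization (`array_io`)

1. **Flooring.** Background-subtracted intensities below 1 are set to 1 in
   both channels, so every log ratio is finite. Values already ≥ 1 are
   untouched.
2. **Lowess.** Per array, a locally weighted regression of M = log2(Cy3/Cy5)
   on A = ½·log2(Cy3·Cy5) is fitted over non-control probes and subtracted.
   Defaults: span 0.3, tricube weights, 3 robustness iterations (standard
   MA-normalization practice), with an interpolation step of 1 % of the
   A-range for speed. Normalization is within-array only; the common
   reference channel makes between-array scaling unnecessary for ratio
   contrasts. Arrays with fewer than 10 non-control probes are rejected —
   no meaningful trend can be fitted.
3. **Retention rule.** A probe is removed everywhere if it is a technical
   control, or flagged saturated or population-outlier on *any* array. The
   global removal is deliberate: it yields a rectangular matrix with no
   missing values, which every downstream stage assumes. A surviving probe
   is retained iff it is "positive and significant" against background on at
   least ⌈0.75·n⌉ arrays (5 of 6) in at least two of the four cross-type
   groups. The above-background call is consumed as a boolean input column
   (the scanner software's two-sided background t-test); it is not
   re-derived from pixel statistics.

## Probe collapsing (`collapse`)

Only probes carrying a BLAST-derived gene symbol and/or a KEGG Orthology
number are analysed. When several probes interrogate one gene, the probe
with the lowest p-value represents it, with ties broken on the
lexicographically smaller probe id (deterministic and seed-free). The
p-value used is the one from the test the collapsed matrix feeds: the
WW-vs-DD Welch t for the stock contrast, the four-group Welch ANOVA for the
heritability branch. The two collapsed gene sets may therefore differ
slightly and are kept separate. Collapsing happens on raw p-values;
BH adjustment is then applied on the collapsed set.

## Differential expression (`diffexpr`)

* **Stock contrast:** per-gene Welch t (unpaired, unequal variance,
  Welch–Satterthwaite df), Benjamini–Hochberg step-up across genes,
  significance at adjusted p ≤ 0.05 **and** linear fold change
  max(FC, 1/FC) ≥ 1.25 with FC = 2^(mean_D − mean_W).
* **Four-group scan:** Welch's heteroscedastic one-way ANOVA, BH at FDR
  10 %, then a Student–Newman–Keuls stepwise post-hoc on the four group
  means for gating genes only. SNK classically assumes equal variances
  while the omnibus test is Welch-type; the two are paired here regardless,
  because that combination defines the analysis being reproduced — the SNK
  uses the classical pooled error mean square with N − k df, α = 0.05, and
  the harmonic mean of the two compared group sizes. A range is tested only
  when every enclosing range rejected; a single accepting range blocks all
  comparisons inside it. Post-hoc results are gene-local and not adjusted
  across genes.
* Degenerate inputs (all observations identical) return p = 1 by
  convention; a zero-variance group whose mean differs from the others
  returns p = 0.

## Heritability classification (`heritability`)

For gene-level group means on the normalized log2-ratio scale (a config
option exposes back-transformed linear intensities instead):

    α = (W − D)/2        δ = (W + D)/2 − hybrid        ratio = δ/α

Classes: additive for −0.5 < δ/α < 0.5; wild dominant for
−1.5 < δ/α ≤ −0.5; domesticated dominant for 0.5 ≤ δ/α < 1.5; over-dominant
beyond ±1.5 (split by sign into wild/domesticated over-dominance in the
summary table). The boundary points ±0.5 and ±1.5 are measure-zero; they are
assigned deterministically to the dominant and over-dominant classes
respectively. α = 0 leaves the ratio undefined — such genes are reported in
a separate column, never dropped. Genes with |δ/α| > 5 are omitted from the
scatter figure only; the summary table always includes them.

Genes whose only significant post-hoc contrast is WW-vs-DD carry no
inheritance information and are excluded. For each remaining gene, calls are
made per hybrid, for each hybrid that appears in at least one significant
contrast.

**Parental-effect categories.** The default scheme uses line-sharing logic:
a contrast supports a *maternal* effect when the two crosses share the
paternal line but differ in the maternal line ({WW,DW} or {WD,DD}); a
*paternal* effect when they share the mother ({WW,WD} or {DW,DD}); both
kinds → *parental*; only the hybrid-vs-hybrid contrast → *hybrid-only*. An
alternative "literal" scheme reproducing the category lists as published for
this design is available behind a switch; those lists enumerate all three
contrasts against a pure cross for both parent categories (including
same-mother contrasts under "maternal"), which cannot isolate a
parent-of-origin effect — hence the line-sharing default.

## Gene-set perturbation (`enrichment`)

Follows the generally-applicable gene-set analysis scheme: each domesticated
replicate is compared one-on-group against the mean of all wild replicates,
giving one fold-change profile per test replicate. Per set and direction, an
unequal-variance two-sample t-test contrasts set members against all genes —
one-sided upper (up), one-sided lower (down), or upper on |fold change|
(two-way perturbed, the signature of coordinated but mixed-direction
change). Sets need 10–500 members present in the matrix; the "Human
Diseases" functional group is excluded by default (a config default, not a
computation). Significance: BH within each direction, q ≤ 0.1. The
published description of this threshold reads "corrected p value was >0.1",
an evident typo for ≤ 0.1 (the cited method's standard), and is implemented
as ≤ 0.1. Two-way results are additionally focused at combined raw
p ≤ 0.02 (switchable to adjusted).

**Combination across replicate comparisons.** Per-replicate p-values are
combined by Stouffer's probit method. The one-on-group construction makes
the comparisons *dependent*: every fold-change column subtracts the same
control-group mean, inducing an exchangeable inter-column correlation of
about 1/(n_control + 1) (≈ 0.14 at n = 6). A plain independence denominator
√k is therefore anti-conservative, so the pipeline uses
√(k + k(k−1)·ρ̂) with ρ̂ the mean off-diagonal correlation of the
fold-change columns (clipped to [0, 0.95]; |fold changes| for the two-way
direction). This keeps null combined p-values uniform, which the test suite
verifies by Kolmogorov–Smirnov on 500 null sets. The standalone
`combine_comparisons` keeps the plain independence form for genuinely
independent inputs.

**Essential genes** of a significant set are members whose mean
domesticated-minus-wild difference deviates from the all-gene mean by more
than one SD of all genes' differences *and* whose per-gene Welch t p ≤ 0.05
(unadjusted). At the default design (n = 6, SD 0.25) the t criterion is the
binding one, so the null inclusion rate sits at ≈ 5 % — the conjunction
tightens magnitude, not error rate.

When a gene belongs to several sets, its primary function is the candidate
set with the most members among the analysed gene list, ties broken
lexicographically.

## Synthetic experiments (`simulate`)

The generator emulates the full design: 4 × 6 arrays on 6 slides (one
replicate of each cross per slide), genes with 1–3 probes each, technical
controls, planted saturated/outlier/low-signal probes, an annotation table
covering 62 % of genes, and GMT gene sets with planted perturbations.

* Baseline log2 ratios ~ N(0, 0.5); DE genes (default 25 % of 2000 genes,
  i.e. 500) get a W/D difference of 1.0 log2 units with random sign.
* Modes are planted through the hybrid mean: mid-parent (additive), one
  parental mean (dominant), or mid-parent − ratio·α with ratio ±2
  (over-dominant; half an α beyond the ±1.5 boundary, so the true class
  survives default noise). Maternal genes (default 15 % of DE genes) copy
  their mother's mean, so the two hybrids disagree and the per-hybrid true
  modes differ (WD → wild-dominant, DW → domesticated-dominant).
* Default mode proportions (wild-over, wild-dom, additive, dom-dom,
  dom-over) = (0.1, 0.2, 0.4, 0.2, 0.1); replicate noise N(0, 0.25) per gene
  per array plus N(0, 0.05) per probe, additive Gaussian on the log2 scale
  (standard for two-colour ratios).
* Channels: per-probe abundance ~ N(10, 1.5) on the log2 scale, the log
  ratio split symmetrically across Cy3/Cy5 so spot intensity A is
  independent of expression, then a sinusoidal intensity-dependent dye bias
  of amplitude 0.3 log2 units injected into Cy3 (which the Lowess step must
  remove).
* Planted gene sets shift the domesticated mean of annotated non-DE member
  genes by ±1 log2 (same-sign for "up"/"down", alternating for "two-way");
  50 null sets of 30 genes are drawn alongside.

Everything derives from one integer seed; identical configs produce
byte-identical files.

**What passing tests show — and do not.** The generator's noise is Gaussian,
homoscedastic and probe-independent; real arrays have heavy-tailed,
intensity-dependent variance, spatial artifacts and correlated probes
(a heavy-tail switch exists for robustness checks). Recovery rates measured
here (≈ 92 % mode accuracy among detected genes at effect 1.0 log2,
SD 0.25, n = 6) therefore bound what the pipeline can do under its own
assumptions, not its accuracy on any real experiment.

## Orchestration and problem sizes (`pipeline`)

The pipeline runs QC → collapse → DE → heritability and enrichment from a
single config and records probe/gene counts at every stage. Hierarchical
clustering of DE genes uses 1 − Pearson distance with average linkage
(linkage method is a free choice; average is the common default for
expression heatmaps and is configurable); constant-expression genes get
distance 1 to everything, with a logged warning. Figures are artifacts —
the tested outputs are leaf orderings and plotted-point counts. The δ/α
scatter omits |ratio| > 5.

Default validation sizes — 2000 genes (≈ 4100 probes) for the end-to-end
run, 5000 genes for null calibrations, 500 null sets for the uniformity
check — are large enough for stable rates while keeping a full test-plus-
acceptance cycle under a minute on one core. The generator scales to the
~44k-probe realistic design (`n_genes≈20000, probes_per_gene=(1,3)`) when
needed.

## Known limitations

* The SNK/Welch pairing is internally inconsistent (documented above); a
  rank-based or Games–Howell post-hoc would be the statistically cleaner
  choice but would change the reproduced analysis.
* The heritability scheme is a point classification of group means; it
  propagates no uncertainty and is not a quantitative-genetic variance
  decomposition.
* The ρ̂-adjusted Stouffer assumes exchangeable correlation between
  replicate comparisons; strong per-gene variance heterogeneity would make
  the correlation gene-dependent.
* Dye-swap designs, image-level QC and probe-sequence effects are out of
  scope.
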