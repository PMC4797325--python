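"""Annotation-based probe filtering and probe→gene collapsing.

Only transcripts carrying a BLAST-derived gene identifier and/or a KEGG
Orthology number are analysed; when several probes interrogate the same gene
the probe with the lowest p-value (from whichever test the downstream branch
uses) represents it.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


def read_annotation(path) -> pd.DataFrame:
    """Read the probe annotation table (probe_id, gene_id, ko_id).

    Empty strings mean missing; probe_id must be unique.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_id", "ko_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if ann["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in annotation table")
    return ann.set_index("probe_id")


def _is_annotated(ann: pd.DataFrame) -> pd.Series:
    return (ann["gene_id"].fillna("") != "") | (ann["ko_id"].fillna("") != "")


def drop_unannotated(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Remove matrix rows whose probe has neither gene_id nor ko_id.

    Probes absent from the annotation table are treated as unannotated and
    logged.
    """
    probe_ids = matrix.values.index
    known = probe_ids.intersection(annotation.index)
    unknown = probe_ids.difference(annotation.index)
    if len(unknown):
        log.warning("%d probes absent from annotation table; dropped", len(unknown))
    annotated = known[_is_annotated(annotation.loc[known])]
    keep = [p for p in probe_ids if p in set(annotated)]
    return matrix.subset_rows(keep)


def collapse_to_genes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    pvalues: pd.Series,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Collapse multiple probes per gene to the lowest-p probe.

    ``pvalues`` is indexed by probe_id and must cover every matrix row; ties
    break on the lexicographically smaller probe_id.  Probes whose annotation
    has no gene_id fall back to their KEGG Orthology number as the gene key.
    Returns the gene-level matrix (rows = gene ids) and the chosen
    gene_id -> probe_id mapping.
    """
    probe_ids = matrix.values.index
    missing = probe_ids.difference(pvalues.index)
    if len(missing):
        raise ValueError(f"p-values missing for {len(missing)} probes")
    ann = annotation.reindex(probe_ids)
    gene_key = ann["gene_id"].where(ann["gene_id"].fillna("") != "", ann["ko_id"])
    if (gene_key.fillna("") == "").any():
        raise ValueError("collapse requires annotated probes; run drop_unannotated first")

    choice = (
        pd.DataFrame({"gene": gene_key, "p": pvalues.loc[probe_ids], "probe": probe_ids})
        .sort_values(["gene", "p", "probe"], kind="mergesort")
        .groupby("gene", sort=True)
        .first()
    )
    chosen = choice["probe"]
    values = matrix.values.loc[chosen.to_numpy()].copy()
    values.index = chosen.index
    return ExpressionMatrix(values, matrix.samples), chosen
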