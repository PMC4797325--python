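"""Shared in-memory containers for the reciprocal-cross expression pipeline.

The experiment compares embryos from a wild (W) and a domesticated (D)
Atlantic-salmon stock together with their reciprocal F1 hybrids.  Cross types
are encoded mother-first:

* ``WW`` — pure wild (W female x W male)
* ``WD`` — W female x D male
* ``DW`` — D female x W male
* ``DD`` — pure domesticated

Expression values are log2 ratios of the Cy3 test channel over the common
Cy5 reference channel, after flooring and Lowess normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CROSS_TYPES: tuple[str, ...] = ("WW", "WD", "DW", "DD")

#: hybrid code -> (maternal line, paternal line)
HYBRID_PARENTS: dict[str, tuple[str, str]] = {"WD": ("W", "D"), "DW": ("D", "W")}

SAMPLE_SHEET_COLUMNS = ("array_id", "file", "cross_type", "replicate", "slide_id")

FEATURE_COLUMNS = (
    "probe_id",
    "cy3",
    "cy5",
    "is_control",
    "flag_saturated",
    "flag_outlier",
    "flag_above_background",
)


@dataclass
class ExpressionMatrix:
    """Probe- or gene-level log-ratio matrix with aligned sample metadata.

    Parameters
    ----------
    values
        Rows are probe or gene identifiers, columns are array identifiers,
        entries are normalized log2(Cy3/Cy5) ratios.  No missing entries.
    samples
        Indexed by array identifier; columns ``cross_type`` (one of
        :data:`CROSS_TYPES`), ``replicate`` and ``slide_id``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("row identifiers must be unique")
        missing = [a for a in self.values.columns if a not in self.samples.index]
        if missing:
            raise ValueError(f"arrays without sample metadata: {missing}")
        self.samples = self.samples.loc[list(self.values.columns)]
        bad = set(self.samples["cross_type"]) - set(CROSS_TYPES)
        if bad:
            raise ValueError(f"unknown cross types: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("matrix contains non-finite entries")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def arrays_for(self, cross_type: str) -> list[str]:
        """Array identifiers belonging to one cross type, replicate-ordered."""
        sub = self.samples[self.samples["cross_type"] == cross_type]
        return list(sub.sort_values("replicate").index)

    def group_values(self, cross_type: str) -> np.ndarray:
        """Rows x replicates value block for one cross type."""
        return self.values[self.arrays_for(cross_type)].to_numpy(dtype=float)

    def group_means(self) -> pd.DataFrame:
        """Per-row mean log ratio for each cross type (columns = cross types)."""
        return pd.DataFrame(
            {ct: self.values[self.arrays_for(ct)].mean(axis=1) for ct in CROSS_TYPES}
        )

    def subset_rows(self, row_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(row_ids)], self.samples)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "id"
        out.to_csv(path, sep="\t")


def read_matrix_tsv(path, samples: pd.DataFrame) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, samples)
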