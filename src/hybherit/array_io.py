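"""Two-colour feature-table IO, intensity flooring, Lowess normalization and QC.

Input is one tab-delimited feature table per array (background-subtracted Cy3
test and Cy5 reference intensities plus vendor QC flags) and a sample sheet
assigning arrays to the four cross types.  The QC chain mirrors standard
two-colour practice: floor intensities at 1, correct the intensity-dependent
dye trend on the MA scale per array, drop technical controls and probes
flagged saturated or population-outlier on any array, and retain only probes
called "positive and significant" against background on at least 75 % of the
arrays in at least two of the four experimental groups.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .containers import CROSS_TYPES, ExpressionMatrix

log = logging.getLogger(__name__)

_FLAG_DEFAULTS = {
    # pass-state defaults used when a flag column is absent from an input file
    "is_control": False,
    "flag_saturated": False,
    "flag_outlier": False,
    "flag_above_background": True,
}

_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False,
    "t": True, "f": False, "yes": True, "no": False,
}


def _coerce_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    if np.issubdtype(col.dtype, np.number):
        return col.astype(bool)
    return col.astype(str).str.strip().str.lower().map(_BOOL_MAP).astype(bool)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the array sample sheet; index = array_id.

    Columns: file, cross_type (WW/WD/DW/DD), replicate, slide_id.
    (cross_type, replicate) pairs must be unique across the experiment.
    """
    sheet = pd.read_csv(path, sep="\t", dtype={"array_id": str, "slide_id": str})
    required = {"array_id", "file", "cross_type", "replicate", "slide_id"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    unknown = set(sheet["cross_type"]) - set(CROSS_TYPES)
    if unknown:
        raise ValueError(
            f"unknown cross_type label(s) {sorted(unknown)}; expected {CROSS_TYPES}"
        )
    sheet["replicate"] = sheet["replicate"].astype(int)
    if sheet.duplicated(["cross_type", "replicate"]).any():
        dup = sheet[sheet.duplicated(["cross_type", "replicate"], keep=False)]
        raise ValueError(
            "duplicate (cross_type, replicate) pairs: "
            + ", ".join(f"{r.cross_type}/{r.replicate}" for r in dup.itertuples())
        )
    return sheet.set_index("array_id")


def read_feature_table(path) -> pd.DataFrame:
    """Read one per-array feature table, indexed by probe_id.

    Missing flag columns default to their pass state (not control, not
    saturated, not outlier, above background) with a logged warning.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in tab.columns:
        raise ValueError(f"{path}: missing probe_id column")
    for col in ("cy3", "cy5"):
        if col not in tab.columns:
            raise ValueError(f"{path}: missing intensity column {col}")
    for col, default in _FLAG_DEFAULTS.items():
        if col in tab.columns:
            tab[col] = _coerce_bool(tab[col])
        else:
            log.warning("%s: flag column %s absent, defaulting to pass", path, col)
            tab[col] = default
    tab = tab.set_index("probe_id")
    if not tab.index.is_unique:
        raise ValueError(f"{path}: duplicate probe ids")
    if (tab[["cy3", "cy5"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative intensities")
    return tab


def read_feature_tables(paths, sample_sheet) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Read all per-array feature tables named by a sample sheet.

    ``paths`` maps array_id -> file path, or is a directory-like prefix the
    sample-sheet ``file`` column is resolved against when None entries occur.
    Returns (features keyed by array_id, sample table).  All arrays must share
    one probe universe; a mismatch is a hard error naming the offending array.
    """
    samples = sample_sheet if isinstance(sample_sheet, pd.DataFrame) else read_sample_sheet(sample_sheet)
    if not isinstance(paths, dict):
        raise TypeError("paths must map array_id -> feature-table path")
    missing = [a for a in samples.index if a not in paths]
    if missing:
        raise ValueError(f"no feature file for arrays: {missing}")
    features: dict[str, pd.DataFrame] = {}
    ref_ids: pd.Index | None = None
    ref_array = None
    for array_id in samples.index:
        tab = read_feature_table(paths[array_id])
        if ref_ids is None:
            ref_ids, ref_array = tab.index, array_id
        elif not tab.index.equals(ref_ids):
            only_new = tab.index.difference(ref_ids)
            only_ref = ref_ids.difference(tab.index)
            raise ValueError(
                f"probe universe mismatch: array {array_id} vs {ref_array}; "
                f"unique to {array_id}: {list(only_new[:5])}, "
                f"unique to {ref_array}: {list(only_ref[:5])}"
            )
        features[array_id] = tab
    return features, samples


def floor_intensities(features):
    """Raise intensities below 1 to exactly 1 (both channels).

    Accepts a single feature table or a dict of them; returns the same shape.
    Values already >= 1 are untouched, so the floor makes every subsequent
    log ratio finite.
    """
    if isinstance(features, dict):
        return {a: floor_intensities(tab) for a, tab in features.items()}
    out = features.copy()
    out["cy3"] = out["cy3"].clip(lower=1.0)
    out["cy5"] = out["cy5"].clip(lower=1.0)
    return out


def _ma(tab: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cy3 = tab["cy3"].to_numpy(dtype=float)
    cy5 = tab["cy5"].to_numpy(dtype=float)
    m = np.log2(cy3 / cy5)
    a = 0.5 * np.log2(cy3 * cy5)
    return m, a


def lowess_normalize(
    features: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    span: float = 0.3,
    iterations: int = 3,
) -> ExpressionMatrix:
    """Within-array Lowess normalization on the MA scale.

    For each array a locally weighted regression (tricube weights,
    ``iterations`` robustness passes) of M = log2(cy3/cy5) on
    A = 0.5*log2(cy3*cy5) is fitted over non-control probes and subtracted,
    removing intensity-dependent dye bias.  Intensities must be floored first.
    Control probes never enter the output matrix.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    columns: dict[str, pd.Series] = {}
    index = None
    for array_id in samples.index:
        tab = features[array_id]
        work = tab[~tab["is_control"]]
        if work.shape[0] < 10:
            raise ValueError(
                f"array {array_id}: only {work.shape[0]} non-control probes; "
                "cannot fit an intensity trend"
            )
        if (work[["cy3", "cy5"]].to_numpy() < 1).any():
            raise ValueError(f"array {array_id}: intensities not floored")
        m, a = _ma(work)
        spread = float(a.max() - a.min())
        trend = _sm_lowess(
            m, a, frac=span, it=iterations, delta=0.01 * spread, return_sorted=False
        )
        corrected = pd.Series(m - trend, index=work.index)
        if index is None:
            index = work.index
        columns[array_id] = corrected
    values = pd.DataFrame(columns).loc[index]
    return ExpressionMatrix(values, samples)


def qc_filter(
    features: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    frac_threshold: float = 0.75,
    min_groups: int = 2,
) -> list[str]:
    """Apply the global probe-retention rule; return the sorted retained set.

    A probe is removed everywhere if it is a technical control, or flagged
    saturated or population-outlier on *any* array.  A surviving probe is
    retained iff, in at least ``min_groups`` cross-type groups, it is above
    background on at least ``ceil(frac_threshold * group size)`` of that
    group's arrays (>= 5 of 6 at the default 75 %).
    """
    if not 0 < frac_threshold <= 1:
        raise ValueError("frac_threshold must be in (0, 1]")
    array_ids = list(samples.index)
    first = features[array_ids[0]]
    probe_ids = first.index

    is_control = first["is_control"].to_numpy()
    saturated = np.zeros(len(probe_ids), dtype=bool)
    outlier = np.zeros(len(probe_ids), dtype=bool)
    above = {}
    for a in array_ids:
        tab = features[a]
        saturated |= tab["flag_saturated"].to_numpy()
        outlier |= tab["flag_outlier"].to_numpy()
        above[a] = tab["flag_above_background"].to_numpy()
    removed = is_control | saturated | outlier

    groups_ok = np.zeros(len(probe_ids), dtype=int)
    for ct in CROSS_TYPES:
        group_arrays = [a for a in array_ids if samples.loc[a, "cross_type"] == ct]
        if not group_arrays:
            continue
        need = math.ceil(frac_threshold * len(group_arrays))
        count = np.sum([above[a] for a in group_arrays], axis=0)
        groups_ok += (count >= need).astype(int)

    keep = (~removed) & (groups_ok >= min_groups)
    retained = sorted(probe_ids[keep])
    log.info(
        "QC: %d/%d probes retained (%d removed by control/saturated/outlier)",
        len(retained), len(probe_ids), int(removed.sum()),
    )
    return retained
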