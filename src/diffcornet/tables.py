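"""Sample table container and CSV dialect for two-group metabolomics panels.

A :class:`SampleTable` holds a samples x metabolites concentration matrix
(µM) together with per-sample metadata (group label and covariates) and a
per-entry status flag distinguishing quantified values from below-LOD
censored and missing entries.

CSV dialect
-----------
First columns: ``sample_id, group, age, bmi, activity, menarche_age``;
remaining columns are metabolite concentrations. A below-LOD entry is
written as the literal token ``<LOD``; a missing entry is an empty field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

GROUP_PRE = "pre"
GROUP_POST = "post"
GROUPS = (GROUP_PRE, GROUP_POST)

#: entry status flags
QUANTIFIED = "quantified"
BELOW_LOD = "below_lod"
MISSING = "missing"
IMPUTED_LOD = "imputed_lod"      # was below-LOD, filled with half-minimum
IMPUTED_MEAN = "imputed_mean"    # was missing, filled with the column mean
_VALID_STATUS = frozenset({QUANTIFIED, BELOW_LOD, MISSING, IMPUTED_LOD, IMPUTED_MEAN})

COVARIATE_COLUMNS = ["age", "bmi", "activity", "menarche_age"]
METADATA_COLUMNS = ["group"] + COVARIATE_COLUMNS

LOD_TOKEN = "<LOD"


@dataclasses.dataclass
class SampleTable:
    """Samples x metabolites concentration matrix with metadata and statuses.

    Parameters
    ----------
    metadata : DataFrame indexed by sample id with columns
        ``group`` (one of ``"pre"``/``"post"``) and the covariates
        ``age`` (years), ``bmi`` (kg/m²), ``activity`` (unitless score),
        ``menarche_age`` (years).
    values : DataFrame of concentrations, same index, one column per
        metabolite.  Below-LOD and missing entries are NaN.
    status : DataFrame of per-entry status strings, aligned with ``values``.
    """

    metadata: pd.DataFrame
    values: pd.DataFrame
    status: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.metadata.index.equals(self.values.index):
            raise DataError("metadata and values must share the sample index")
        if not self.values.index.equals(self.status.index) or not self.values.columns.equals(
            self.status.columns
        ):
            raise DataError("values and status must be aligned")
        bad_groups = set(self.metadata["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise DataError(f"unknown group labels: {sorted(bad_groups)}")
        bad_status = set(np.unique(self.status.to_numpy())) - _VALID_STATUS
        if bad_status:
            raise DataError(f"unknown status flags: {sorted(bad_status)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        counts = self.metadata["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise DataError(f"unknown group {group!r}; expected one of {GROUPS}")
        return (self.metadata["group"] == group).to_numpy()

    def values_for(self, group: str) -> pd.DataFrame:
        """Concentration sub-matrix for one group."""
        return self.values.loc[self.group_mask(group)]

    def measurable_fraction(self) -> pd.Series:
        """Per metabolite, the fraction of samples with a quantified entry.

        Below-LOD and missing entries both count as non-measurable.
        """
        return (self.status == QUANTIFIED).mean(axis=0)

    def copy(self) -> "SampleTable":
        return SampleTable(self.metadata.copy(), self.values.copy(), self.status.copy())


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    """Write a sample table in the package CSV dialect."""
    out = table.metadata[METADATA_COLUMNS].copy()
    vals = table.values
    stat = table.status
    for col in vals.columns:
        cells = vals[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        cells = cells.where(stat[col] != BELOW_LOD, LOD_TOKEN)
        cells = cells.where(stat[col] != MISSING, "")
        out[col] = cells
    out.index.name = "sample_id"
    out.to_csv(path)


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a sample table written by :func:`write_sample_table`."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    raw = pd.read_csv(path, index_col="sample_id", dtype=str, keep_default_na=False)
    missing_meta = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise DataError(f"missing metadata columns: {missing_meta}")
    metadata = raw[METADATA_COLUMNS].copy()
    for cov in COVARIATE_COLUMNS:
        metadata[cov] = pd.to_numeric(metadata[cov])
    met_cols = [c for c in raw.columns if c not in METADATA_COLUMNS]
    values = pd.DataFrame(index=raw.index, columns=met_cols, dtype=float)
    status = pd.DataFrame(QUANTIFIED, index=raw.index, columns=met_cols)
    for col in met_cols:
        cells = raw[col].str.strip()
        is_lod = cells == LOD_TOKEN
        is_missing = cells == ""
        numeric = pd.to_numeric(cells.where(~(is_lod | is_missing), None))
        values[col] = numeric
        status.loc[is_lod, col] = BELOW_LOD
        status.loc[is_missing, col] = MISSING
    return SampleTable(metadata, values, status)
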