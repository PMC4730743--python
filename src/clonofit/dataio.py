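"""Reading, validation, normalization and aggregation of clonogenic
survival data.

The universal input is a long table with one row per observed surviving
fraction: a *cell line*, a *replicate* (independent experiment), the
radiation *dose* in Gy, and the surviving fraction ``sf`` (dimensionless,
1.0 at the unirradiated control).  Raw colony counts can be supplied
instead and are normalized to surviving fractions via the plating
efficiency of each replicate's own unirradiated control.

Downstream multivariate analyses (clustering, PCA) consume the
cell-line x dose matrix of mean surviving fractions in percent produced
by :func:`mean_sf_matrix`; the dose-0 column (constant 100%) is excluded
there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    DataFormatError,
    NormalizationError,
    ValidationError,
)

#: canonical column names of the long survival table
SF_COLUMNS = ("cell_line", "replicate", "dose_gy", "sf")

#: canonical column names of the colony-count table
COUNT_COLUMNS = ("cell_line", "replicate", "dose_gy", "n_seeded", "n_colonies")


@dataclass(frozen=True)
class SurvivalDataset:
    """Validated long-format clonogenic survival data.

    Attributes
    ----------
    data:
        DataFrame with columns ``cell_line, replicate, dose_gy, sf``.
        Every cell line is observed at every dose of the common grid;
        replicate counts may differ between lines (ragged design).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SF_COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {missing}")
        df = df.loc[:, list(SF_COLUMNS)].reset_index(drop=True)
        if df.empty:
            raise ValidationError("dataset contains no records")
        for col in ("dose_gy", "sf"):
            if not np.issubdtype(df[col].dtype, np.number):
                raise DataFormatError(f"column {col!r} must be numeric")
        bad_dose = df.index[df["dose_gy"] < 0]
        if len(bad_dose):
            raise ValidationError(f"negative dose at row(s) {list(bad_dose)}")
        bad_sf = df.index[~(df["sf"] > 0)]
        if len(bad_sf):
            raise ValidationError(
                f"surviving fraction must be > 0; violated at row(s) {list(bad_sf)}"
            )
        dup = df.duplicated(subset=["cell_line", "replicate", "dose_gy"])
        if dup.any():
            raise ValidationError(
                f"duplicate (cell_line, replicate, dose) at row(s) {list(df.index[dup])}"
            )
        grid = set(df["dose_gy"].unique())
        for line, sub in df.groupby("cell_line", sort=False):
            missing_doses = grid - set(sub["dose_gy"].unique())
            if missing_doses:
                raise CompletenessError(
                    f"cell line {line!r} has no observation at dose(s) "
                    f"{sorted(missing_doses)}"
                )
        object.__setattr__(self, "data", df)

    @property
    def cell_lines(self) -> list[str]:
        """Cell-line labels in order of first appearance."""
        return list(dict.fromkeys(self.data["cell_line"]))

    @property
    def n_lines(self) -> int:
        return len(self.cell_lines)

    @property
    def dose_grid(self) -> np.ndarray:
        """Sorted distinct doses (Gy), including 0 if present."""
        return np.sort(self.data["dose_gy"].unique())

    def for_line(self, cell_line: str) -> pd.DataFrame:
        """Rows of one cell line; raises ``KeyError`` for unknown labels."""
        sub = self.data[self.data["cell_line"] == cell_line]
        if sub.empty:
            raise KeyError(f"unknown cell line {cell_line!r}")
        return sub.reset_index(drop=True)


def read_survival_csv(
    path, dialect: Mapping[str, str] | None = None
) -> SurvivalDataset:
    """Read a long-format survival CSV into a validated dataset.

    Parameters
    ----------
    path:
        CSV file with a header row and decimal points.
    dialect:
        Optional map from canonical column names (``cell_line`` ...) to
        the names used in the file.
    """
    df = pd.read_csv(path)
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    return SurvivalDataset(df)


def write_survival_csv(ds: SurvivalDataset, path) -> None:
    """Write a dataset back to CSV (canonical columns, value-exact floats)."""
    ds.data.to_csv(path, index=False)


def normalize_counts(counts: pd.DataFrame) -> SurvivalDataset:
    """Turn raw colony counts into surviving fractions.

    For each replicate the plating efficiency PE is the colonies-per-seeded-
    cell ratio of that replicate's unirradiated (dose 0) control; the
    surviving fraction at any dose is ``(n_colonies / n_seeded) / PE``, so
    the control itself maps to exactly 1.

    Parameters
    ----------
    counts:
        DataFrame with columns ``cell_line, replicate, dose_gy, n_seeded,
        n_colonies``; each (cell_line, replicate) needs a dose-0 row with
        at least one colony.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {missing}")
    df = counts.loc[:, list(COUNT_COLUMNS)].copy()
    if (df["n_seeded"] <= 0).any():
        raise ValidationError("n_seeded must be positive")
    if (df["n_colonies"] < 0).any():
        raise ValidationError("n_colonies must be non-negative")
    if (df["n_colonies"] > df["n_seeded"]).any():
        raise ValidationError("n_colonies cannot exceed n_seeded")

    records = []
    for (line, rep), sub in df.groupby(["cell_line", "replicate"], sort=False):
        ctrl = sub[sub["dose_gy"] == 0]
        if ctrl.empty:
            raise NormalizationError(
                f"no dose-0 control for cell line {line!r}, replicate {rep!r}"
            )
        if len(ctrl) > 1:
            raise ValidationError(
                f"multiple dose-0 controls for cell line {line!r}, replicate {rep!r}"
            )
        pe = float(ctrl["n_colonies"].iloc[0]) / float(ctrl["n_seeded"].iloc[0])
        if pe <= 0:
            raise NormalizationError(
                f"dose-0 control has zero colonies for cell line {line!r}, "
                f"replicate {rep!r}"
            )
        for _, row in sub.iterrows():
            dose = float(row["dose_gy"])
            if dose == 0:
                sf = 1.0
            else:
                sf = (float(row["n_colonies"]) / float(row["n_seeded"])) / pe
            records.append((line, rep, dose, sf))
    out = pd.DataFrame(records, columns=list(SF_COLUMNS))
    return SurvivalDataset(out)


def mean_sf_matrix(ds: SurvivalDataset) -> pd.DataFrame:
    """Cell-line x dose matrix of mean surviving fractions in percent.

    Rows are cell lines (order of first appearance), columns the nonzero
    doses of the grid in ascending order; each entry is 100 x the mean
    over replicates of the surviving fraction at that dose.  Dose 0 is
    excluded (constant 100% by construction).
    """
    nonzero = [d for d in ds.dose_grid if d > 0]
    if not nonzero:
        raise ValidationError("dose grid has no nonzero dose")
    sub = ds.data[ds.data["dose_gy"] > 0]
    mat = (
        sub.pivot_table(
            index="cell_line", columns="dose_gy", values="sf", aggfunc="mean"
        )
        * 100.0
    )
    mat = mat.reindex(index=ds.cell_lines, columns=nonzero)
    mat.index.name = "cell_line"
    mat.columns.name = "dose_gy"
    return mat


def dataset_from_records(records: Sequence[tuple]) -> SurvivalDataset:
    """Build a dataset from ``(cell_line, replicate, dose, sf)`` tuples."""
    return SurvivalDataset(pd.DataFrame(records, columns=list(SF_COLUMNS)))
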