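"""Foci tables: reported activation peaks grouped into experiments.

The input of a coordinate-based meta-analysis is a tidy table with one row
per reported activation peak: the study and experiment (contrast) it came
from, the group label (e.g. Grammatical / Ungrammatical), the number of
subjects (which sets the kernel width), the coordinate space, and x/y/z mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coords import tal_to_mni

__all__ = ["FociTable", "load_foci_table", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("study_id", "experiment_id", "group", "n", "space", "x", "y", "z")
_SPACES = ("MNI", "Talairach")


class FociValidationError(ValueError):
    """Schema or row-level validation failure in a foci table."""


@dataclass
class FociTable:
    """Validated set of activation peaks grouped into experiments.

    Wraps a pandas DataFrame with columns ``study_id, experiment_id, group,
    n, space, x, y, z``; row order is preserved from the source.
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.df = _validate(self.df)

    # -- accessors --------------------------------------------------------
    def __len__(self):
        return len(self.df)

    @property
    def n_experiments(self) -> int:
        return self.df["experiment_id"].nunique()

    @property
    def experiment_ids(self) -> list:
        """Distinct experiment ids, first-appearance order."""
        return list(dict.fromkeys(self.df["experiment_id"]))

    @property
    def n_talairach(self) -> int:
        """Rows flagged for Talairach->MNI conversion."""
        return int((self.df["space"] == "Talairach").sum())

    def groups(self) -> list:
        return list(dict.fromkeys(self.df["group"]))

    def subset(self, experiment_ids) -> "FociTable":
        keep = self.df["experiment_id"].isin(set(experiment_ids))
        return FociTable(self.df.loc[keep].reset_index(drop=True))

    def by_group(self, group_label) -> "FociTable":
        return FociTable(
            self.df.loc[self.df["group"] == group_label].reset_index(drop=True)
        )

    def to_mni(self, matrix=None) -> "FociTable":
        """Return a copy with Talairach rows converted to MNI."""
        df = self.df.copy()
        tal = df["space"] == "Talairach"
        if tal.any():
            xyz = df.loc[tal, ["x", "y", "z"]].to_numpy(float)
            df.loc[tal, ["x", "y", "z"]] = tal_to_mni(xyz, matrix=matrix)
            df.loc[tal, "space"] = "MNI"
        return FociTable(df)

    def experiments(self):
        """Yield ``(experiment_id, group, n_subjects, foci_mm)`` in
        first-appearance order; foci must already be in MNI space."""
        if self.n_talairach:
            raise FociValidationError(
                "table contains unconverted Talairach rows; call to_mni() first"
            )
        for exp_id in self.experiment_ids:
            sub = self.df[self.df["experiment_id"] == exp_id]
            yield (
                exp_id,
                sub["group"].iloc[0],
                int(sub["n"].iloc[0]),
                sub[["x", "y", "z"]].to_numpy(float),
            )

    def save(self, path, sep="\t") -> None:
        self.df.to_csv(path, sep=sep, index=False)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FociValidationError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)

    for col in ("x", "y", "z", "n"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FociValidationError(f"non-numeric {col!r} in row {row}")
        df[col] = vals
    bad_n = (df["n"] < 1) | (df["n"] != df["n"].astype(int))
    if bad_n.any():
        row = int(np.flatnonzero(bad_n)[0])
        raise FociValidationError(
            f"n_subjects must be a positive integer; offending row {row}"
        )
    df["n"] = df["n"].astype(int)

    bad_space = ~df["space"].isin(_SPACES)
    if bad_space.any():
        row = int(np.flatnonzero(bad_space)[0])
        raise FociValidationError(
            f"space must be one of {_SPACES}; offending row {row}"
        )
    bad_group = df["group"].isna() | (df["group"].astype(str).str.len() == 0)
    if bad_group.any():
        row = int(np.flatnonzero(bad_group)[0])
        raise FociValidationError(f"empty group label in row {row}")

    # one n_subjects per experiment
    n_per_exp = df.groupby("experiment_id")["n"].nunique()
    multi = n_per_exp[n_per_exp > 1]
    if len(multi):
        raise FociValidationError(
            f"experiment {multi.index[0]!r} has conflicting n_subjects values"
        )
    return df


def load_foci_table(path, dialect: str | None = None) -> FociTable:
    """Load and validate a foci table from TSV/CSV.

    ``dialect`` forces the separator (``"tsv"`` or ``"csv"``); by default it
    is inferred from the file extension, falling back to tab.
    """
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"study_id": str, "experiment_id": str})
    return FociTable(df)
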