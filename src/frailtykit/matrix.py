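"""Three-valued person x deficit matrices.

A :class:`DeficitMatrix` is the common currency between ascertainment,
scoring and comparison: one row per person, one column per deficit,
cells coded 1.0 (present), 0.0 (absent) or NaN (missing). EHR-derived
matrices never contain missing cells -- absence of a code is coded 0 --
while survey matrices keep unanswered items as NaN so that the frailty
denominator can be restricted to assessed deficits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

EHR = "EHR"
SURVEY = "SURVEY"
SOURCES = (EHR, SURVEY)

#: numeric source coding used in every regression model: SURVEY=0, EHR=1
SOURCE_CODE = {SURVEY: 0, EHR: 1}


@dataclass
class DeficitMatrix:
    """Person x deficit grid with three-valued cells.

    Parameters
    ----------
    data:
        DataFrame indexed by person id with one float column per deficit;
        values must be 0.0, 1.0 or NaN.
    source:
        ``"EHR"`` or ``"SURVEY"``. EHR matrices must be complete.
    """

    data: pd.DataFrame
    source: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise DataError(f"unknown source tag {self.source!r}; expected one of {SOURCES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate person ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate deficit names: {dups[:5]}")
        values = self.data.to_numpy(dtype=float, na_value=np.nan)
        bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"cell ({self.data.index[i]!r}, {self.data.columns[j]!r}) = "
                f"{self.data.iat[i, j]!r} is not 0, 1 or missing"
            )
        if self.source == EHR and np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise DataError(
                f"EHR matrix has a missing cell at ({self.data.index[i]!r}, "
                f"{self.data.columns[j]!r}); EHR absence must be coded 0"
            )
        self.data = self.data.astype(float)

    @property
    def person_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def deficit_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_persons(self) -> int:
        return len(self.data)

    def missing_counts(self) -> pd.Series:
        """Number of missing cells per person."""
        return self.data.isna().sum(axis=1)

    def to_csv(self, path) -> None:
        """Serialise with empty string for missing cells and integer 0/1."""
        out = self.data.copy()
        # keep 0/1 as integers in the file for readability
        formatted = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
        formatted.index.name = "person_id"
        formatted.to_csv(path)

    @classmethod
    def from_csv(cls, path, source: str) -> "DeficitMatrix":
        raw = pd.read_csv(path, index_col="person_id", dtype=str, keep_default_na=False)
        data = raw.replace("", np.nan).astype(float)
        return cls(data=data, source=source)
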