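"""Deficit ascertainment from raw tables.

Turns coded-event, prescription and survey-wide tables into a
three-valued :class:`~frailtykit.matrix.DeficitMatrix` under the
cumulative-deficit ascertainment rules:

* a coded deficit is present iff any event carries a code from its
  codelist dated strictly before the index date; persons with no
  matching record are coded absent (0), never missing;
* polypharmacy is present iff prescriptions span at least five distinct
  BNF (chapter, paragraph) drug classes in the 84 days from the index
  date, restricted to medication chapters 1-15;
* survey items pass through as answered, with unanswered items kept
  missing (no carry-forward from earlier waves, no imputation to 0);
* survey respondents missing more than 20 of the 58 items are excluded.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import PolypharmacySpec
from .errors import ConfigurationError, DataError
from .matrix import EHR, SOURCE_CODE, SURVEY, DeficitMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Codelist:
    """A named deficit and the set of clinical codes that define it."""

    deficit_name: str
    codes: frozenset

    def __post_init__(self) -> None:
        if not self.codes:
            raise ConfigurationError(f"codelist for {self.deficit_name!r} is empty")


def load_codelists(path) -> dict[str, Codelist]:
    """Read a codelist CSV (columns deficit_name, code) into Codelist objects.

    Codes are whitespace-trimmed on read and compared exactly thereafter.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"deficit_name", "code"}
    if not required.issubset(df.columns):
        raise DataError(f"codelist file must have columns {sorted(required)}")
    out: dict[str, Codelist] = {}
    for name, group in df.groupby("deficit_name", sort=False):
        codes = frozenset(c.strip() for c in group["code"].dropna())
        out[str(name)] = Codelist(deficit_name=str(name), codes=codes)
    return out


def _parse_dates(series: pd.Series, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="mixed")
    bad = parsed.isna() & series.notna()
    if bad.any():
        rows = series.index[bad].tolist()
        raise DataError(f"unparseable {column} at rows {rows[:10]}")
    if parsed.isna().any():
        rows = series.index[parsed.isna()].tolist()
        raise DataError(f"missing {column} at rows {rows[:10]}")
    return parsed


def apply_cohort_criteria(
    persons: pd.DataFrame,
    index_date: dt.date,
    min_age: int = 65,
    min_registration_years: int = 9,
) -> pd.DataFrame:
    """Apply the eligibility filter: age >= 65 and (EHR) >= 9 years registered.

    Survey persons face the age criterion only. The registration
    criterion is inclusive: registered exactly ``min_registration_years``
    before the index date qualifies.
    """
    index_ts = pd.Timestamp(index_date)
    keep = persons["age"] >= min_age
    is_ehr = persons["source"] == SOURCE_CODE[EHR]
    if is_ehr.any():
        reg = persons.loc[is_ehr, "registration_start"]
        if reg.isna().any():
            bad = persons.loc[is_ehr].loc[reg.isna(), "person_id"].tolist()
            raise DataError(f"EHR persons missing registration_start: {bad[:10]}")
        cutoff = pd.to_datetime(reg) + pd.DateOffset(years=min_registration_years)
        keep = keep & (~is_ehr | (cutoff <= index_ts).reindex(persons.index, fill_value=False))
    return persons.loc[keep].copy()


def ascertain_coded_deficit(
    coded_events: pd.DataFrame,
    codelist: Codelist,
    index_date: dt.date,
    person_ids: Iterable | None = None,
) -> pd.Series:
    """Flag each person 1 iff any event matches the codelist strictly before index.

    ``person_ids`` fixes the output universe (persons without any
    matching event are coded 0); when omitted, the universe is the set of
    persons appearing in ``coded_events``.
    """
    index_ts = pd.Timestamp(index_date)
    dates = _parse_dates(coded_events["event_date"], "event_date")
    codes = coded_events["code"].astype(str).str.strip()
    hit = codes.isin(codelist.codes) & (dates < index_ts)
    positives = set(coded_events.loc[hit, "person_id"])
    universe = pd.Index(person_ids) if person_ids is not None else pd.Index(
        coded_events["person_id"].unique()
    )
    flags = pd.Series(
        [1 if pid in positives else 0 for pid in universe], index=universe, dtype=int
    )
    flags.index.name = "person_id"
    return flags


def ascertain_polypharmacy(
    prescriptions: pd.DataFrame,
    index_date: dt.date,
    spec: PolypharmacySpec = PolypharmacySpec(),
    person_ids: Iterable | None = None,
) -> pd.Series:
    """Flag polypharmacy: >= min_paragraphs distinct drug classes in the window.

    The window is half-open, ``[index_date, index_date + window_days)``.
    Rows with a missing BNF paragraph are dropped by default (their count
    is logged); with ``spec.missing_paragraph_policy == "count"`` each
    such row is treated as its own distinct class, giving an upper bound.
    """
    index_ts = pd.Timestamp(index_date)
    window_end = index_ts + pd.Timedelta(days=spec.window_days)
    dates = _parse_dates(prescriptions["issue_date"], "issue_date")
    chapters = pd.to_numeric(prescriptions["bnf_chapter"], errors="coerce")
    paragraphs = prescriptions["bnf_paragraph"]

    lo, hi = spec.chapter_range
    in_scope = (
        (dates >= index_ts)
        & (dates < window_end)
        & chapters.between(lo, hi)
        & ~paragraphs.isin(spec.excluded_paragraphs)
    )
    missing_par = paragraphs.isna() | (paragraphs.astype(str).str.strip() == "")
    n_missing = int((in_scope & missing_par).sum())
    if n_missing:
        log.warning("dropping %d in-window prescriptions with missing BNF paragraph", n_missing)

    scoped = prescriptions.loc[in_scope]
    scoped_missing = missing_par[in_scope]
    known = scoped.loc[~scoped_missing]
    n_classes = (
        known.drop_duplicates(subset=["person_id", "bnf_chapter", "bnf_paragraph"])
        .groupby("person_id")
        .size()
    )
    if spec.missing_paragraph_policy == "count":
        # upper bound: every missing-paragraph row is its own distinct class
        n_unknown = scoped.loc[scoped_missing].groupby("person_id").size()
        n_classes = n_classes.add(n_unknown, fill_value=0)

    universe = pd.Index(person_ids) if person_ids is not None else pd.Index(
        prescriptions["person_id"].unique()
    )
    flags = (n_classes.reindex(universe, fill_value=0) >= spec.min_paragraphs).astype(int)
    flags.index.name = "person_id"
    return flags


def build_ehr_matrix(
    coded_events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelists: Mapping[str, Codelist],
    index_date: dt.date,
    person_ids: Iterable,
    polypharmacy_spec: PolypharmacySpec = PolypharmacySpec(),
    polypharmacy_name: str = "polypharmacy",
) -> DeficitMatrix:
    """Ascertain every coded deficit plus polypharmacy into one EHR matrix."""
    cols = {}
    for name, codelist in codelists.items():
        cols[name] = ascertain_coded_deficit(coded_events, codelist, index_date, person_ids)
    cols[polypharmacy_name] = ascertain_polypharmacy(
        prescriptions, index_date, polypharmacy_spec, person_ids
    )
    return DeficitMatrix(data=pd.DataFrame(cols).astype(float), source=EHR)


def build_survey_matrix(survey_wide: pd.DataFrame) -> DeficitMatrix:
    """Pass a wide survey table (1/0/missing) into a survey DeficitMatrix.

    Cells stay exactly as answered at the current wave; missing answers
    remain missing rather than being imputed to absent.
    """
    df = survey_wide.copy()
    if "person_id" in df.columns:
        df = df.set_index("person_id")
    try:
        values = df.to_numpy(dtype=float, na_value=np.nan)
    except (ValueError, TypeError) as exc:
        raise DataError(f"survey cells must be 0, 1 or missing: {exc}") from exc
    return DeficitMatrix(data=pd.DataFrame(values, index=df.index, columns=df.columns), source=SURVEY)


def filter_survey_completeness(
    matrix: DeficitMatrix, total_deficits: int = 58, max_missing: int = 20
) -> tuple[DeficitMatrix, int]:
    """Drop survey rows missing more than ``max_missing`` of the deficits.

    Equivalent to requiring at least ``total_deficits - max_missing``
    assessed items (38 of 58 under the defaults). Returns the retained
    matrix and the number of excluded persons.
    """
    if matrix.source != SURVEY:
        raise DataError("completeness filter applies to survey matrices only")
    if len(matrix.deficit_names) != total_deficits:
        raise DataError(
            f"matrix has {len(matrix.deficit_names)} deficits, expected {total_deficits}"
        )
    missing = matrix.missing_counts()
    keep = missing <= max_missing
    excluded = int((~keep).sum())
    return DeficitMatrix(data=matrix.data.loc[keep], source=SURVEY), excluded
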