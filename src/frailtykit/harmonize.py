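"""Cross-source deficit harmonisation.

Two frailty indices built on different data sources rarely measure the
same item lists. A :class:`DeficitMapping` records, for every deficit in
either index, how it relates to the other source: ``one_to_one``
(directly comparable pairs), ``one_to_many`` (one broad deficit in one
source covered by several granular items in the other) and
``one_to_none`` (unique to one source). The mapping must partition each
side's deficit list; deficits explicitly annotated ``overlap`` in the
note column are exempt from the no-duplicates rule, mirroring items that
genuinely appear under two broader headings.

Only one-to-one pairs feed the per-deficit comparison models.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MappingValidationError
from .matrix import DeficitMatrix

RELATIONS = ("one_to_one", "one_to_many", "one_to_none")


@dataclass
class DeficitMapping:
    """Validated relation-typed deficit pairs across the two sources."""

    records: pd.DataFrame  # columns: ehr_deficit, survey_deficit, relation, note

    def __post_init__(self) -> None:
        df = self.records
        for col in ("ehr_deficit", "survey_deficit", "relation"):
            if col not in df.columns:
                raise MappingValidationError(f"mapping is missing column {col!r}")
        if "note" not in df.columns:
            df = df.assign(note="")
        df = df.copy()
        for col in ("ehr_deficit", "survey_deficit", "note"):
            df[col] = df[col].fillna("").astype(str).str.strip()
        self.records = df
        self._validate()

    def _validate(self) -> None:
        df = self.records
        bad_rel = df.loc[~df["relation"].isin(RELATIONS)]
        if not bad_rel.empty:
            raise MappingValidationError(
                f"unknown relation labels at rows {bad_rel.index.tolist()[:5]}: "
                f"{sorted(bad_rel['relation'].unique())}"
            )
        empty_both = df.loc[(df["ehr_deficit"] == "") & (df["survey_deficit"] == "")]
        if not empty_both.empty:
            raise MappingValidationError(
                f"rows {empty_both.index.tolist()[:5]} name no deficit on either side"
            )
        o2o = df.loc[df["relation"] == "one_to_one"]
        half = o2o.loc[(o2o["ehr_deficit"] == "") | (o2o["survey_deficit"] == "")]
        if not half.empty:
            raise MappingValidationError(
                f"one_to_one rows must name both sides; rows {half.index.tolist()[:5]}"
            )
        o2n = df.loc[df["relation"] == "one_to_none"]
        two_sided = o2n.loc[(o2n["ehr_deficit"] != "") & (o2n["survey_deficit"] != "")]
        if not two_sided.empty:
            raise MappingValidationError(
                f"one_to_none rows must name exactly one side; rows {two_sided.index.tolist()[:5]}"
            )
        o2m = df.loc[df["relation"] == "one_to_many"]
        half_m = o2m.loc[(o2m["ehr_deficit"] == "") | (o2m["survey_deficit"] == "")]
        if not half_m.empty:
            raise MappingValidationError(
                f"one_to_many rows must pair a broad deficit with a member; "
                f"rows {half_m.index.tolist()[:5]}"
            )
        # no deficit may appear under two relations unless annotated 'overlap'
        for side in ("ehr_deficit", "survey_deficit"):
            named = df.loc[df[side] != "", [side, "relation", "note"]]
            rel_per_deficit = named.groupby(side)["relation"].nunique()
            dup = rel_per_deficit.index[rel_per_deficit > 1]
            overlap_ok = set(named.loc[named["note"].str.contains("overlap"), side])
            offending = [d for d in dup if d not in overlap_ok]
            if offending:
                raise MappingValidationError(
                    f"deficit(s) {offending[:5]} appear under more than one relation"
                )
            # within one_to_one, each deficit may appear once
            o2o_side = df.loc[df["relation"] == "one_to_one", side]
            dup_o2o = o2o_side[o2o_side.duplicated()].unique().tolist()
            dup_o2o = [d for d in dup_o2o if d not in overlap_ok]
            if dup_o2o:
                raise MappingValidationError(
                    f"deficit(s) {dup_o2o[:5]} appear in more than one one_to_one pair"
                )

    def deficits(self, side: str) -> set[str]:
        col = f"{side}_deficit"
        return set(self.records.loc[self.records[col] != "", col])

    def one_to_one_pairs(self) -> list[tuple[str, str]]:
        o2o = self.records.loc[self.records["relation"] == "one_to_one"]
        return list(zip(o2o["ehr_deficit"], o2o["survey_deficit"]))

    def validate_against(self, ehr_deficits, survey_deficits) -> None:
        """Check the mapping exactly partitions both matrices' deficit sets."""
        for side, observed in (("ehr", set(ehr_deficits)), ("survey", set(survey_deficits))):
            mapped = self.deficits(side)
            unmapped = observed - mapped
            phantom = mapped - observed
            if unmapped:
                raise MappingValidationError(
                    f"{side} deficits absent from the mapping: {sorted(unmapped)[:5]}"
                )
            if phantom:
                raise MappingValidationError(
                    f"mapping names unknown {side} deficits: {sorted(phantom)[:5]}"
                )


def load_mapping(path) -> DeficitMapping:
    """Load and validate a mapping CSV (ehr_deficit, survey_deficit, relation[, note])."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return DeficitMapping(records=df)


def relation_counts(mapping: DeficitMapping) -> dict[str, int]:
    """Count pairs and per-side deficits in each relation class."""
    df = mapping.records
    o2m = df.loc[df["relation"] == "one_to_many"]
    o2n = df.loc[df["relation"] == "one_to_none"]
    return {
        "one_to_one_pairs": int((df["relation"] == "one_to_one").sum()),
        "one_to_many_ehr": int(o2m["ehr_deficit"].nunique()),
        "one_to_many_survey": int(o2m["survey_deficit"].nunique()),
        "one_to_none_ehr": int((o2n["ehr_deficit"] != "").sum()),
        "one_to_none_survey": int((o2n["survey_deficit"] != "").sum()),
    }


def select_comparable(
    mapping: DeficitMapping,
    ehr_matrix: DeficitMatrix,
    survey_matrix: DeficitMatrix,
    ehr_persons: pd.DataFrame,
    survey_persons: pd.DataFrame,
) -> pd.DataFrame:
    """Stack one-to-one deficit pairs into a long modelling table.

    One row per person per pair, columns person_id, deficit_pair (the EHR
    name labels the pair), present, age, sex, source. Survey cells that
    are missing for a given pair are dropped from that pair's rows only.
    """
    pairs = mapping.one_to_one_pairs()
    pieces = []
    covars = {
        "ehr": ehr_persons.set_index("person_id")[["age", "sex", "source"]],
        "survey": survey_persons.set_index("person_id")[["age", "sex", "source"]],
    }
    for ehr_name, survey_name in pairs:
        if ehr_name not in ehr_matrix.data.columns:
            raise MappingValidationError(f"mapped deficit {ehr_name!r} absent from EHR matrix")
        if survey_name not in survey_matrix.data.columns:
            raise MappingValidationError(
                f"mapped deficit {survey_name!r} absent from survey matrix"
            )
        for matrix, name in ((ehr_matrix, ehr_name), (survey_matrix, survey_name)):
            col = matrix.data[name].dropna()
            side = "ehr" if matrix is ehr_matrix else "survey"
            piece = pd.DataFrame(
                {
                    "person_id": col.index,
                    "deficit_pair": ehr_name,
                    "present": col.to_numpy().astype(int),
                }
            ).join(covars[side], on="person_id")
            pieces.append(piece)
    if not pieces:
        return pd.DataFrame(
            columns=["person_id", "deficit_pair", "present", "age", "sex", "source"]
        )
    return pd.concat(pieces, ignore_index=True)
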