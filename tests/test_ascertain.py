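"""Ascertainment rules: eligibility, coded deficits, polypharmacy, survey pass-through."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import frailtykit as fk
from frailtykit.cohort import PolypharmacySpec
from frailtykit.params import POLYPHARMACY

INDEX = dt.date(2018, 1, 1)


# ------------------------------------------------------------- eligibility

class TestCohortCriteria:
    @staticmethod
    def _person(pid, age, source, reg=None):
        return {
            "person_id": pid,
            "age": age,
            "sex": 0,
            "source": source,
            "registration_start": pd.Timestamp(reg) if reg else pd.NaT,
            "latent_u": 0.0,
        }

    def test_age_64_excluded_age_65_included(self):
        persons = pd.DataFrame(
            [self._person("a", 64, 0), self._person("b", 65, 0)]
        )
        kept = fk.apply_cohort_criteria(persons, INDEX)
        assert kept["person_id"].tolist() == ["b"]

    def test_registration_of_exactly_nine_years_is_inclusive(self):
        persons = pd.DataFrame(
            [
                self._person("exact", 70, 1, "2009-01-01"),   # exactly 9 years
                self._person("short", 70, 1, "2009-01-02"),   # one day short
            ]
        )
        kept = fk.apply_cohort_criteria(persons, INDEX)
        assert kept["person_id"].tolist() == ["exact"]

    def test_survey_persons_skip_registration_criterion(self):
        persons = pd.DataFrame([self._person("s", 80, 0)])
        assert len(fk.apply_cohort_criteria(persons, INDEX)) == 1

    def test_missing_ehr_registration_names_person(self):
        persons = pd.DataFrame([self._person("ghost", 80, 1)])
        with pytest.raises(fk.DataError, match="ghost"):
            fk.apply_cohort_criteria(persons, INDEX)

    def test_mixed_table_matches_brute_force_scan(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(10):
            src = int(rng.integers(0, 2))
            reg = None
            if src == 1:
                reg = pd.Timestamp(INDEX) - pd.Timedelta(days=int(rng.integers(1000, 5000)))
            rows.append(self._person(f"p{i}", int(rng.integers(60, 90)), src, reg))
        persons = pd.DataFrame(rows)

        def eligible(row):  # independent row scan
            if row["age"] < 65:
                return False
            if row["source"] == 1:
                return row["registration_start"] + pd.DateOffset(years=9) <= pd.Timestamp(INDEX)
            return True

        expected = sum(eligible(r) for _, r in persons.iterrows())
        assert len(fk.apply_cohort_criteria(persons, INDEX)) == expected


# ---------------------------------------------------------- coded deficits

CODELIST = fk.Codelist("diabetes", frozenset({"DM1", "DM2"}))


class TestCodedDeficit:
    def test_event_day_before_index_counts(self):
        events = pd.DataFrame(
            {"person_id": ["a"], "code": ["DM1"], "event_date": ["2017-12-31"]}
        )
        flags = fk.ascertain_coded_deficit(events, CODELIST, INDEX)
        assert flags["a"] == 1

    def test_event_on_index_date_does_not_count(self):
        events = pd.DataFrame(
            {"person_id": ["a"], "code": ["DM1"], "event_date": ["2018-01-01"]}
        )
        flags = fk.ascertain_coded_deficit(events, CODELIST, INDEX, person_ids=["a"])
        assert flags["a"] == 0

    def test_non_matching_code_does_not_count(self):
        events = pd.DataFrame(
            {"person_id": ["a"], "code": ["XX9"], "event_date": ["2016-05-01"]}
        )
        flags = fk.ascertain_coded_deficit(events, CODELIST, INDEX, person_ids=["a"])
        assert flags["a"] == 0

    def test_unparseable_date_raises_with_row(self):
        events = pd.DataFrame(
            {"person_id": ["a"], "code": ["DM1"], "event_date": ["not-a-date"]}
        )
        with pytest.raises(fk.DataError, match="event_date"):
            fk.ascertain_coded_deficit(events, CODELIST, INDEX)

    @staticmethod
    def _random_events(n=500, seed=23):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in rng.integers(0, 60, n)],
                "code": rng.choice(["DM1", "DM2", "OT1", "OT2"], n),
                "event_date": pd.Timestamp(INDEX)
                + pd.to_timedelta(rng.integers(-700, 700, n), "D"),
            }
        )

    def test_matches_nested_loop_oracle_on_random_fixture(self):
        events = self._random_events()
        ids = [f"p{i}" for i in range(60)]
        flags = fk.ascertain_coded_deficit(events, CODELIST, INDEX, person_ids=ids)
        for pid in ids:  # brute-force: scan every row per person
            expected = 0
            for _, row in events.iterrows():
                if (
                    row["person_id"] == pid
                    and row["code"] in CODELIST.codes
                    and row["event_date"] < pd.Timestamp(INDEX)
                ):
                    expected = 1
            assert flags[pid] == expected

    def test_invariant_to_order_and_duplication(self):
        events = self._random_events(seed=29)
        ids = [f"p{i}" for i in range(60)]
        base = fk.ascertain_coded_deficit(events, CODELIST, INDEX, person_ids=ids)
        shuffled = events.sample(frac=1, random_state=1).reset_index(drop=True)
        doubled = pd.concat([events, events], ignore_index=True)
        pd.testing.assert_series_equal(
            base, fk.ascertain_coded_deficit(shuffled, CODELIST, INDEX, person_ids=ids)
        )
        pd.testing.assert_series_equal(
            base, fk.ascertain_coded_deficit(doubled, CODELIST, INDEX, person_ids=ids)
        )

    def test_adding_events_never_clears_a_flag(self):
        events = self._random_events(seed=31)
        ids = [f"p{i}" for i in range(60)]
        before = fk.ascertain_coded_deficit(events, CODELIST, INDEX, person_ids=ids)
        extra = pd.DataFrame(
            {"person_id": ["p3"], "code": ["DM2"], "event_date": ["2015-06-01"]}
        )
        after = fk.ascertain_coded_deficit(
            pd.concat([events, extra], ignore_index=True), CODELIST, INDEX, person_ids=ids
        )
        assert (after >= before).all()


# ------------------------------------------------------------ polypharmacy

def _rx(pid, paragraph, days_after_index, chapter=None):
    chapter = int(paragraph.split(".")[0]) if chapter is None else chapter
    return {
        "person_id": pid,
        "bnf_chapter": chapter,
        "bnf_paragraph": paragraph,
        "issue_date": pd.Timestamp(INDEX) + pd.Timedelta(days=days_after_index),
    }


class TestPolypharmacy:
    def test_five_distinct_paragraphs_in_window(self):
        rx = pd.DataFrame([_rx("a", f"0{c}.01", d) for c, d in zip(range(1, 6), range(5))])
        assert fk.ascertain_polypharmacy(rx, INDEX)["a"] == 1

    def test_five_prescriptions_same_paragraph_do_not_count(self):
        rx = pd.DataFrame([_rx("a", "02.01", d) for d in range(5)])
        assert fk.ascertain_polypharmacy(rx, INDEX, person_ids=["a"])["a"] == 0

    def test_out_of_scope_chapters_ignored(self):
        rx = pd.DataFrame([_rx("a", f"16.{p:02d}", 1, chapter=16) for p in range(1, 8)])
        assert fk.ascertain_polypharmacy(rx, INDEX, person_ids=["a"])["a"] == 0

    def test_window_is_half_open_from_index(self):
        # day 83 in, day 84 out, day before index out
        inside = pd.DataFrame(
            [_rx("a", f"0{c}.01", 83) for c in range(1, 6)]
        )
        too_late = pd.DataFrame(
            [_rx("a", f"0{c}.01", 84) for c in range(1, 6)]
        )
        before = pd.DataFrame(
            [_rx("a", f"0{c}.01", -1) for c in range(1, 6)]
        )
        assert fk.ascertain_polypharmacy(inside, INDEX, person_ids=["a"])["a"] == 1
        assert fk.ascertain_polypharmacy(too_late, INDEX, person_ids=["a"])["a"] == 0
        assert fk.ascertain_polypharmacy(before, INDEX, person_ids=["a"])["a"] == 0

    def test_excluded_paragraphs_do_not_count(self):
        spec = PolypharmacySpec(excluded_paragraphs=frozenset({"01.01"}))
        rx = pd.DataFrame([_rx("a", f"0{c}.01", 1) for c in range(1, 6)])
        assert fk.ascertain_polypharmacy(rx, INDEX, spec, person_ids=["a"])["a"] == 0

    def test_missing_paragraph_policies(self):
        rows = [_rx("a", f"0{c}.01", 1) for c in range(1, 5)]
        rows.append({"person_id": "a", "bnf_chapter": 9, "bnf_paragraph": None,
                     "issue_date": pd.Timestamp(INDEX) + pd.Timedelta(days=1)})
        rx = pd.DataFrame(rows)
        drop = fk.ascertain_polypharmacy(rx, INDEX, person_ids=["a"])
        count = fk.ascertain_polypharmacy(
            rx, INDEX, PolypharmacySpec(missing_paragraph_policy="count"), person_ids=["a"]
        )
        assert drop["a"] == 0 and count["a"] == 1

    @staticmethod
    def _random_rx(n=400, seed=37):
        rng = np.random.default_rng(seed)
        chapters = rng.integers(1, 19, n)
        return pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in rng.integers(0, 40, n)],
                "bnf_chapter": chapters,
                "bnf_paragraph": [
                    f"{c:02d}.{p:02d}" for c, p in zip(chapters, rng.integers(1, 5, n))
                ],
                "issue_date": pd.Timestamp(INDEX)
                + pd.to_timedelta(rng.integers(-30, 120, n), "D"),
            }
        )

    def test_matches_brute_force_set_count(self):
        rx = self._random_rx()
        ids = [f"p{i}" for i in range(40)]
        flags = fk.ascertain_polypharmacy(rx, INDEX, person_ids=ids)
        window_end = pd.Timestamp(INDEX) + pd.Timedelta(days=84)
        for pid in ids:
            classes = set()
            for _, row in rx.iterrows():
                if (
                    row["person_id"] == pid
                    and 1 <= row["bnf_chapter"] <= 15
                    and pd.Timestamp(INDEX) <= row["issue_date"] < window_end
                ):
                    classes.add((row["bnf_chapter"], row["bnf_paragraph"]))
            assert flags[pid] == int(len(classes) >= 5)

    def test_invariant_under_row_permutation(self):
        rx = self._random_rx(seed=41)
        ids = [f"p{i}" for i in range(40)]
        base = fk.ascertain_polypharmacy(rx, INDEX, person_ids=ids)
        perm = rx.sample(frac=1, random_state=2).reset_index(drop=True)
        pd.testing.assert_series_equal(
            base, fk.ascertain_polypharmacy(perm, INDEX, person_ids=ids)
        )


# ------------------------------------------------------------ survey tables

class TestSurveyMatrix:
    def test_all_zero_row_becomes_all_absent(self):
        wide = pd.DataFrame({"d1": [0.0], "d2": [0.0]}, index=pd.Index(["a"], name="person_id"))
        matrix = fk.build_survey_matrix(wide)
        assert (matrix.data.loc["a"] == 0).all()

    def test_missing_cells_stay_missing(self):
        wide = pd.DataFrame(
            {"d1": [1.0, np.nan], "d2": [np.nan, 0.0]},
            index=pd.Index(["a", "b"], name="person_id"),
        )
        matrix = fk.build_survey_matrix(wide)
        assert np.isnan(matrix.data.loc["a", "d2"])
        assert np.isnan(matrix.data.loc["b", "d1"])

    def test_three_by_three_identity(self):
        wide = pd.DataFrame(
            np.eye(3), columns=["d1", "d2", "d3"],
            index=pd.Index(list("abc"), name="person_id"),
        )
        matrix = fk.build_survey_matrix(wide)
        np.testing.assert_array_equal(matrix.data.to_numpy(), np.eye(3))

    def test_cell_outside_domain_rejected(self):
        wide = pd.DataFrame({"d1": [2.0]}, index=pd.Index(["a"], name="person_id"))
        with pytest.raises(fk.DataError):
            fk.build_survey_matrix(wide)


class TestCompletenessFilter:
    @staticmethod
    def _matrix(missing_per_row):
        n_items = 58
        rows = []
        for k in missing_per_row:
            row = np.zeros(n_items)
            row[:k] = np.nan
            rows.append(row)
        data = pd.DataFrame(
            rows, columns=[f"d{i}" for i in range(n_items)],
            index=pd.Index([f"p{i}" for i in range(len(rows))], name="person_id"),
        )
        return fk.DeficitMatrix(data=data, source=fk.SURVEY)

    def test_boundary_20_retained_21_excluded(self):
        matrix = self._matrix([20, 21])
        retained, excluded = fk.filter_survey_completeness(matrix)
        assert retained.person_ids == ["p0"]
        assert excluded == 1

    def test_crafted_100_rows_match_brute_force(self):
        rng = np.random.default_rng(53)
        missing = rng.integers(0, 40, 100)
        matrix = self._matrix(missing)
        retained, excluded = fk.filter_survey_completeness(matrix)
        expected_kept = sum(1 for k in missing if k <= 20)
        assert retained.n_persons == expected_kept
        assert excluded == 100 - expected_kept


# ---------------------------------------------------------------- round trip

class TestGeneratorRoundTrip:
    def test_ehr_flags_recovered_exactly(self, ehr_cohort, params, codelists):
        """Ascertainment inverts the generator: no missingness channel in EHR."""
        persons, records = ehr_cohort
        matrix = fk.build_ehr_matrix(
            records.coded_events,
            records.prescriptions,
            codelists,
            params.index_date,
            person_ids=persons["person_id"],
            polypharmacy_spec=params.polypharmacy,
            polypharmacy_name=POLYPHARMACY,
        )
        truth = records.truth[matrix.data.columns]
        assert (matrix.data.astype(int) == truth).all().all()
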