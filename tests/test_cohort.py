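"""Record parsing, exclusion rules and growth-pair construction."""

import numpy as np
import pandas as pd
import pytest

from vetweight import (
    age_in_months,
    apply_exclusions,
    build_growth_pairs,
    default_limits,
    read_records,
    write_records,
)
from vetweight.cohort import SchemaError, SpeciesLimits


def _rec(animal_id, dob, date, weight, species="dog", invoice="inv1"):
    return {
        "animal_id": animal_id,
        "species": species,
        "sex": "female",
        "dob": pd.Timestamp(dob) if dob else pd.NaT,
        "date": pd.Timestamp(date),
        "weight_kg": weight,
        "invoice_id": invoice,
        "practice_id": "pr1",
        "group_id": "g1",
    }


def frame(rows):
    return pd.DataFrame(rows)


class TestReadRecords:
    def test_round_trip_with_generator_output(self, dog_cohort, tmp_path):
        path = tmp_path / "records.csv"
        write_records(dog_cohort["records"], path)
        back, errors = read_records(path)
        assert errors.empty
        orig = dog_cohort["records"]
        assert len(back) == len(orig)
        np.testing.assert_allclose(
            back["weight_kg"].to_numpy(), orig["weight_kg"].to_numpy(), rtol=1e-9
        )
        assert (back["date"].dt.date == orig["date"].dt.date).all()

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "animal_id,species,sex,dob,date,weight_kg,invoice_id,practice_id,group_id\n"
        )
        records, errors = read_records(path)
        assert records.empty and errors.empty

    def test_bad_decimal_reported_per_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "animal_id,species,sex,dob,date,weight_kg,invoice_id,practice_id,group_id\n"
            'a1,dog,female,2020-01-01,2021-01-01,"12,0",inv1,p,g\n'
            "a2,dog,male,2020-01-01,2021-01-01,8.5,inv2,p,g\n"
            "a3,dog,male,2020-01-01,not-a-date,9.5,inv3,p,g\n"
        )
        records, errors = read_records(path)
        assert len(records) == 1
        assert records.iloc[0]["animal_id"] == "a2"
        assert len(errors) == 2  # matches the planted defect count

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "noweight.csv"
        path.write_text("animal_id,species,dob,date\n")
        with pytest.raises(SchemaError):
            read_records(path)


class TestAgeInMonths:
    def test_zero_elapsed(self):
        assert age_in_months("2020-01-01", "2020-01-01") == 0.0

    def test_thirty_days(self):
        assert age_in_months("2020-01-01", "2020-01-31") == pytest.approx(
            30 / 30.4375
        )

    def test_leap_year_span(self):
        # 2020 is a leap year: 366 calendar days
        assert age_in_months("2020-01-01", "2021-01-01") == pytest.approx(
            366 / 30.4375
        )

    def test_reversed_dates_error(self):
        with pytest.raises(ValueError):
            age_in_months("2021-01-01", "2020-01-01")


class TestApplyExclusions:
    def test_overweight_dog_removed(self):
        df = frame([_rec("a1", "2015-01-01", "2020-01-01", 130.0)])
        kept, log = apply_exclusions(df)
        assert kept.empty
        assert log.iloc[0]["rule_id"] == "weight_range"

    def test_plausible_cat_retained(self):
        df = frame(
            [_rec("c1", "2015-06-01", "2020-06-01", 4.0, species="cat")]
        )
        kept, log = apply_exclusions(df)
        assert len(kept) == 1 and log.empty

    def test_growth_jump_drops_later_record(self):
        df = frame(
            [
                _rec("d1", "2020-01-01", "2020-03-01", 2.0),
                _rec("d1", "2020-01-01", "2020-04-01", 25.0),  # ratio 12.5 > 10
            ]
        )
        kept, log = apply_exclusions(df)
        assert len(kept) == 1
        assert kept.iloc[0]["weight_kg"] == 2.0
        assert (log["rule_id"] == "growth_jump").all()

    def test_jump_uses_previous_retained_record(self):
        # after the spike is dropped, the third record is compared with the
        # first and survives
        df = frame(
            [
                _rec("d1", "2020-01-01", "2020-03-01", 2.0),
                _rec("d1", "2020-01-01", "2020-04-01", 25.0),
                _rec("d1", "2020-01-01", "2020-05-01", 2.4),
            ]
        )
        kept, _ = apply_exclusions(df)
        assert list(kept["weight_kg"]) == [2.0, 2.4]

    def test_missing_invoice_and_dob(self):
        df = frame(
            [
                _rec("a", "2019-01-01", "2020-01-01", 10.0, invoice=pd.NA),
                _rec("b", None, "2020-01-01", 10.0),
                _rec("c", "2019-01-01", "2020-01-01", 10.0),
            ]
        )
        kept, log = apply_exclusions(df, require_invoice=True)
        assert list(kept["animal_id"]) == ["c"]
        assert set(log["rule_id"]) == {"missing_invoice", "missing_dob"}
        kept2, _ = apply_exclusions(df, require_invoice=False)
        assert list(kept2["animal_id"]) == ["a", "c"]

    def test_planted_violations_match_per_rule_bruteforce(self):
        limits = default_limits()
        rows = [
            _rec("ok", "2019-01-01", "2020-01-01", 10.0),
            _rec("heavy", "2019-01-01", "2020-01-01", 126.0),
            _rec("light", "2019-01-01", "2020-01-01", 0.05),
            _rec("old", "1990-01-01", "2020-01-01", 10.0),  # 30 y > 22.5
            _rec("noinv", "2019-01-01", "2020-01-01", 10.0, invoice=pd.NA),
            _rec("nodob", None, "2020-01-01", 10.0),
            _rec("jump", "2019-10-01", "2020-01-01", 2.0),
            _rec("jump", "2019-10-01", "2020-02-01", 30.0),
        ]
        df = frame(rows)
        kept, log = apply_exclusions(df)

        # independent per-rule brute-force filter, intersected
        lim = limits["dog"]
        ok = set()
        for i, r in df.iterrows():
            if pd.isna(r["invoice_id"]) or pd.isna(r["dob"]):
                continue
            if not lim.weight_min_kg <= r["weight_kg"] <= lim.weight_max_kg:
                continue
            age_y = (r["date"] - r["dob"]).days / 365.25
            if not lim.age_min_y <= age_y <= lim.age_max_y:
                continue
            ok.add(i)
        # jump rule by hand: the 30 kg record follows 2 kg one month earlier
        ok.discard(7)
        assert sorted(kept["animal_id"]) == sorted(
            df.loc[sorted(ok), "animal_id"]
        )

    def test_conservation_and_idempotence(self, dog_cohort):
        records = dog_cohort["records"]
        kept, log = apply_exclusions(records)
        assert len(kept) + len(log) == len(records)
        again, log2 = apply_exclusions(kept)
        assert log2.empty
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True), kept.reset_index(drop=True)
        )

    def test_order_invariance(self, dog_cohort):
        records = dog_cohort["records"]
        shuffled = records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        kept1, _ = apply_exclusions(records)
        kept2, _ = apply_exclusions(shuffled)
        k1 = kept1.sort_values(["animal_id", "date", "weight_kg"]).reset_index(
            drop=True
        )
        k2 = kept2.sort_values(["animal_id", "date", "weight_kg"]).reset_index(
            drop=True
        )
        pd.testing.assert_frame_equal(k1, k2)

    def test_unknown_species_errors(self):
        df = frame([_rec("x", "2019-01-01", "2020-01-01", 1.0, species="ferret")])
        with pytest.raises(ValueError):
            apply_exclusions(df)


class TestBuildGrowthPairs:
    def test_single_pair_values(self):
        dob = "2020-01-01"
        d1 = pd.Timestamp(dob) + pd.Timedelta(days=round(2.0 * 30.4375))
        d2 = pd.Timestamp(dob) + pd.Timedelta(days=round(3.0 * 30.4375))
        df = frame([_rec("a", dob, d1, 2.0), _rec("a", dob, d2, 3.0)])
        pairs = build_growth_pairs(df, max_age_months=14)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["prop_gain"] == pytest.approx(0.5)
        assert row["age_months"] == pytest.approx(2.0, abs=0.02)
        assert row["interval_months"] == pytest.approx(1.0, abs=0.02)

    def test_single_record_no_pairs(self):
        df = frame([_rec("a", "2020-01-01", "2020-03-01", 2.0)])
        assert build_growth_pairs(df, 14).empty

    def test_three_records_match_enumeration(self):
        dob = "2020-01-01"
        dates = ["2020-02-01", "2020-04-01", "2020-07-01"]
        weights = [2.0, 4.0, 7.0]
        df = frame([_rec("a", dob, d, w) for d, w in zip(dates, weights)])
        pairs = build_growth_pairs(df, max_age_months=14)
        # exhaustive enumeration of consecutive pairs
        expected = [
            (weights[i + 1] - weights[i]) / weights[i] for i in range(2)
        ]
        assert list(pairs["prop_gain"]) == pytest.approx(expected)

    def test_same_day_duplicate_keeps_last_entered(self):
        df = frame(
            [
                _rec("a", "2020-01-01", "2020-03-01", 2.0),
                _rec("a", "2020-01-01", "2020-03-01", 2.5),
                _rec("a", "2020-01-01", "2020-05-01", 3.0),
            ]
        )
        pairs = build_growth_pairs(df, 14)
        assert len(pairs) == 1
        assert pairs.iloc[0]["prop_gain"] == pytest.approx(3.0 / 2.5 - 1.0)

    def test_pair_validity_invariants(self, dog_pairs):
        assert (dog_pairs["interval_months"] > 0).all()
        assert (dog_pairs["prop_gain"] > -1).all()
        assert (dog_pairs["age_months"] <= 60).all()


def test_species_limits_validation():
    with pytest.raises(ValueError):
        SpeciesLimits(10.0, 5.0, 0.0, 20.0, 10.0, 14.0)
    with pytest.raises(ValueError):
        SpeciesLimits(1.0, 5.0, 0.0, 20.0, 0.5, 14.0)
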