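import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breechscan import (
    apply_exclusions,
    apply_planned_cs_rule,
    classify_undiagnosed_breech,
    read_birth_records,
    summarise,
    write_birth_records,
    generate_cohort,
    SimConfig,
)
from breechscan.cohort import RowValidationError, SchemaError, TERM_DAYS

from conftest import CUT, breech_cohort, make_record


class TestReadWrite:
    def test_well_formed_file_round_trips(self, tmp_path):
        records = [make_record(record_id=f"r{i}") for i in range(3)]
        path = tmp_path / "records.csv"
        write_birth_records(records, path)
        assert read_birth_records(path) == records

    def test_synthetic_cohort_round_trips_exactly(self, tmp_path):
        records, _ = generate_cohort(SimConfig(n_before=600, n_after=400, seed=3))
        path = tmp_path / "cohort.csv"
        write_birth_records(records, path)
        assert read_birth_records(path) == records

    def test_invalid_apgar_rejected_with_row_and_field(self, tmp_path):
        records = [make_record(record_id="ok")]
        path = tmp_path / "records.csv"
        write_birth_records(records, path)
        text = path.read_text().replace("ok,", "bad,").splitlines()
        # rewrite apgar5 column of the data row to 12
        header = text[0].split(",")
        row = text[1].split(",")
        row[header.index("apgar5")] = "12"
        path.write_text("\n".join([text[0], ",".join(row)]) + "\n")
        with pytest.raises(RowValidationError) as excinfo:
            read_birth_records(path)
        assert "apgar5" in str(excinfo.value)
        assert "row 2" in str(excinfo.value)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text("record_id,site\nr0,routine_us\n")
        with pytest.raises(SchemaError, match="birth_date"):
            read_birth_records(path)

    def test_column_mapping_renames_are_honoured(self, tmp_path):
        records = [make_record()]
        path = tmp_path / "records.csv"
        write_birth_records(records, path)
        text = path.read_text().replace("record_id", "id")
        path.write_text(text)
        assert read_birth_records(path, column_map={"record_id": "id"}) == records


class TestExclusions:
    def test_term_boundary_37_weeks(self):
        preterm = make_record(gestational_age_days=TERM_DAYS - 1)
        term = make_record(gestational_age_days=TERM_DAYS)
        kept, tally = apply_exclusions([preterm, term])
        assert kept == [term]
        assert tally == {"preterm": 1}

    def test_twin_excluded_as_multiple_pregnancy(self):
        kept, tally = apply_exclusions([make_record(plurality=2)])
        assert kept == []
        assert tally == {"multiple_pregnancy": 1}

    def test_anomaly_excluded(self):
        kept, tally = apply_exclusions([make_record(congenital_anomaly=True)])
        assert kept == [] and tally == {"congenital_anomaly": 1}

    def test_generator_planted_exclusion_counts_recovered(self):
        records, truth = generate_cohort(SimConfig(n_before=2000, n_after=2000, seed=9))
        kept, tally = apply_exclusions(records)
        for reason, key in [
            ("multiple_pregnancy", "excluded_multiple"),
            ("preterm", "excluded_preterm"),
            ("congenital_anomaly", "excluded_anomaly"),
        ]:
            assert tally[reason] == truth["before"][key] + truth["after"][key]
        assert len(kept) == truth["before"]["n_eligible"] + truth["after"]["n_eligible"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(50, 300))
    def test_conservation_and_idempotence(self, seed, n):
        records, _ = generate_cohort(SimConfig(n_before=n, n_after=n, seed=seed))
        kept, tally = apply_exclusions(records)
        assert len(kept) + sum(tally.values()) == len(records)
        again, tally2 = apply_exclusions(kept)
        assert again == kept and sum(tally2.values()) == 0


class TestPlannedCesareanRule:
    def test_neonatal_outcome_keeps_planned_cesareans(self):
        records = [
            make_record(
                presentation_at_birth="breech",
                planned_cesarean_for_breech=True,
                onset="planned_cesarean",
                mode_of_birth="elective_cesarean",
            ),
            make_record(record_id="r1"),
        ]
        assert apply_planned_cs_rule(records, "apgar_lt7") == records

    def test_non_neonatal_outcome_drops_planned_cesareans(self):
        planned = [
            make_record(
                record_id=f"p{i}",
                presentation_at_birth="breech",
                planned_cesarean_for_breech=True,
                onset="planned_cesarean",
                mode_of_birth="elective_cesarean",
            )
            for i in range(2)
        ]
        other = [make_record(record_id="x")]
        out = apply_planned_cs_rule(planned + other, "undiagnosed_breech")
        assert out == other

    def test_unknown_outcome_is_configuration_error(self):
        with pytest.raises(KeyError, match="unknown outcome"):
            apply_planned_cs_rule([], "nonexistent_outcome")

    def test_generator_planted_planned_cs_count_removed(self):
        records, truth = generate_cohort(SimConfig(n_before=3000, n_after=3000, seed=4))
        kept, _ = apply_exclusions(records)
        removed = len(kept) - len(apply_planned_cs_rule(kept, "undiagnosed_breech"))
        planted = (
            truth["before"]["n_planned_cs_breech"]
            + truth["after"]["n_planned_cs_breech"]
        )
        assert removed == planted


class TestUndiagnosedClassification:
    @pytest.mark.parametrize(
        "diagnosed,onset,expected",
        [
            (False, "spontaneous_labour", True),
            (False, "prelabour_rom", True),
            (False, "induction", True),
            (True, "planned_cesarean", False),
            (True, "spontaneous_labour", False),
            (False, "planned_cesarean", False),
        ],
    )
    def test_definition(self, diagnosed, onset, expected):
        record = make_record(
            presentation_at_birth="breech",
            antenatally_diagnosed_breech=diagnosed,
            onset=onset,
            mode_of_birth="emergency_cesarean",
        )
        assert classify_undiagnosed_breech(record) is expected

    def test_non_breech_record_is_logic_error(self):
        with pytest.raises(ValueError, match="breech"):
            classify_undiagnosed_breech(make_record())


class TestSummarise:
    def test_study_scale_percentages(self, epoch):
        records = breech_cohort(578, 82, 251, 7)
        summary = summarise(records, epoch, "undiagnosed_breech")
        assert summary.events == (82, 7)
        assert summary.totals == (578, 251)
        p1, p2 = summary.percentages
        assert round(p1, 1) == 14.2 and round(p2, 1) == 2.8

    def test_single_epoch_cohort_raises(self, epoch):
        records = [make_record(birth_date=dt.date(2019, 1, 1))]
        with pytest.raises(ValueError, match="after"):
            summarise(records, epoch, "undiagnosed_breech", denominator="all_births")

    def test_generator_summary_matches_truth(self, epoch):
        config = SimConfig(n_before=3000, n_after=3000, seed=11, cut_date=CUT)
        records, truth = generate_cohort(config)
        kept, _ = apply_exclusions(records)
        pool = apply_planned_cs_rule(kept, "undiagnosed_breech")
        summary = summarise(pool, epoch, "undiagnosed_breech")
        assert summary.events == (
            truth["before"]["n_undiagnosed"],
            truth["after"]["n_undiagnosed"],
        )
        assert summary.totals == tuple(
            truth[e]["n_breech"] - truth[e]["n_planned_cs_breech"]
            for e in ("before", "after")
        )
        for outcome in ("apgar_lt7", "nnu_admission", "hie", "perinatal_death"):
            s = summarise(apply_planned_cs_rule(kept, outcome), epoch, outcome)
            assert s.events == tuple(
                truth[e]["outcomes"][outcome]["breech_events"]
                for e in ("before", "after")
            )
            assert s.totals == tuple(
                truth[e]["outcomes"][outcome]["breech_total"]
                for e in ("before", "after")
            )

    def test_percentages_exact_and_swap_symmetry(self, epoch):
        records = breech_cohort(40, 9, 30, 2)
        summary = summarise(records, epoch, "undiagnosed_breech")
        assert summary.percentages == (100 * 9 / 40, 100 * 2 / 30)
        swapped = summary.swapped()
        assert swapped.events == summary.events[::-1]
        assert swapped.totals == summary.totals[::-1]
        assert swapped.epoch_labels == summary.epoch_labels[::-1]

    def test_missing_apgar_dropped_from_denominator_only(self, epoch):
        import dataclasses

        records = breech_cohort(10, 2, 10, 1)
        records[0] = dataclasses.replace(records[0], apgar5=None)
        s = summarise(records, epoch, "apgar_lt7")
        assert s.totals == (9, 10)
        s2 = summarise(records, epoch, "undiagnosed_breech")
        assert s2.totals == (10, 10)
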