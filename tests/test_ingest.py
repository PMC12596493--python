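import datetime as dt

import pytest

from conftest import make_records
from multimorbnet.ingest import (
    AdmissionRecord,
    Dialect,
    FilterReport,
    IngestError,
    age_band_of,
    filter_scope,
    normalize_records,
    prepare_strata,
    read_records,
    select_baseline,
    stratify,
    write_records,
)


def _write(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "record_id,patient_id,sex,age,admission_date,codes\n"


class TestReadRecords:
    def test_parses_a_row_into_a_record(self, tmp_path):
        path = _write(tmp_path, HEADER + "r1,p1,male,45,2010-01-02,I10;E11\n")
        records, report = read_records(path)
        assert len(records) == 1 and not report.row_errors
        rec = records[0]
        assert rec.codes == {"I10", "E11"}
        assert rec.sex == "male"
        assert rec.age_years == 45
        assert rec.admission_date == dt.date(2010, 1, 2)

    def test_empty_codes_field_is_a_row_error(self, tmp_path):
        path = _write(tmp_path, HEADER + "r1,p1,male,45,2010-01-02,\n")
        records, report = read_records(path)
        assert records == []
        assert len(report.row_errors) == 1 and "row 2" in report.row_errors[0]

    def test_duplicate_record_id_is_fatal(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER + "r1,p1,male,45,2010-01-02,I10\nr1,p2,female,50,2011-01-01,E11\n",
        )
        with pytest.raises(IngestError, match="r1"):
            read_records(path)

    def test_missing_column_is_fatal(self, tmp_path):
        path = _write(tmp_path, "record_id,patient_id,sex,age,codes\nr1,p1,male,45,I10\n")
        with pytest.raises(IngestError, match="admission_date"):
            read_records(path)

    def test_bad_age_and_date_collected_not_fatal(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "r1,p1,male,forty,2010-01-02,I10\n"
            + "r2,p2,male,45,not-a-date,I10\n"
            + "r3,p3,female,45,2010-01-02,I10\n",
        )
        records, report = read_records(path)
        assert [r.record_id for r in records] == ["r3"]
        assert len(report.row_errors) == 2

    def test_round_trip_through_writer(self, tmp_path):
        records = make_records([{"I10", "E11"}, {"K29"}], ages=[41, 58])
        path = tmp_path / "out.csv"
        write_records(records, path)
        back, report = read_records(path)
        assert back == records and not report.row_errors

    def test_alternative_dialect(self, tmp_path):
        d = Dialect(delimiter="\t", code_sep="|")
        path = _write(
            tmp_path, HEADER.replace(",", "\t") + "r1\tp1\tmale\t45\t2010-01-02\tI10|E11\n"
        )
        records, _ = read_records(path, d)
        assert records[0].codes == {"I10", "E11"}


class TestNormalizeAndScope:
    def test_codes_truncate_and_collapse_to_categories(self):
        (rec,) = make_records([{"E11.9", "E11.2", "I10"}])
        (out,) = normalize_records([rec])
        assert out.codes == {"E11", "I10"}

    def test_unparseable_codes_dropped_and_tallied(self):
        (rec,) = make_records([{"I10", "banana"}])
        report = FilterReport()
        (out,) = normalize_records([rec], report)
        assert out.codes == {"I10"}
        assert report.bad_codes["banana"] == 1

    def test_out_of_scope_codes_removed(self):
        (rec,) = make_records([{"I10", "S72"}])
        out = filter_scope(rec)
        assert out.codes == {"I10"}

    def test_record_with_only_chapters_15_to_22_rejected(self):
        (rec,) = make_records([{"S72", "Z51"}])
        report = FilterReport()
        assert filter_scope(rec, report) is None
        assert report.rejected_out_of_scope == 1

    def test_in_scope_record_unchanged_and_idempotent(self):
        (rec,) = make_records([{"E11", "K29"}])
        once = filter_scope(rec)
        assert once is rec
        assert filter_scope(once) is once


class TestBaseline:
    def test_keeps_earliest_admission(self):
        recs = [
            AdmissionRecord("r2", "p1", "male", 47, dt.date(2011, 3, 2), frozenset({"E11"})),
            AdmissionRecord("r1", "p1", "male", 45, dt.date(2009, 5, 1), frozenset({"I10"})),
        ]
        assert [r.record_id for r in select_baseline(recs)] == ["r1"]

    def test_single_record_patient_kept(self):
        recs = make_records([{"I10"}])
        assert select_baseline(recs) == recs

    def test_date_tie_broken_by_smallest_record_id(self):
        recs = [
            AdmissionRecord("rb", "p1", "male", 45, dt.date(2010, 1, 1), frozenset({"E11"})),
            AdmissionRecord("ra", "p1", "male", 45, dt.date(2010, 1, 1), frozenset({"I10"})),
        ]
        assert [r.record_id for r in select_baseline(recs)] == ["ra"]


class TestStratify:
    def test_band_bounds_inclusive(self):
        assert age_band_of(44) == (40, 44)
        assert age_band_of(45) == (45, 49)
        assert age_band_of(59) == (55, 59)

    def test_sex_age_strata_partition_the_cohort(self):
        recs = make_records(
            [{"I10"}] * 6, ages=[40, 44, 45, 59, 50, 55]
        ) + make_records([{"E11"}] * 2, sex="female", ages=[42, 57], patient_prefix="q")
        strata = stratify(recs, "sex_age")
        assert sum(s.n_records for s in strata.values()) == len(recs)
        labels = {lbl for lbl, s in strata.items() if s.n_records}
        assert "male_40-44" in labels and "female_55-59" in labels
        for s in strata.values():
            for r in s.records:
                assert s.age_band[0] <= r.age_years <= s.age_band[1]

    def test_all_scheme_is_identity_partition(self):
        recs = make_records([{"I10"}, {"E11"}], ages=[41, 58])
        strata = stratify(recs, "all")
        assert list(strata) == ["all_40-59"]
        assert strata["all_40-59"].n_records == 2

    def test_prepare_strata_filters_age(self):
        recs = make_records([{"I10"}, {"E11"}, {"K29"}], ages=[39, 45, 60])
        report = FilterReport()
        strata = prepare_strata(recs, "all", report)
        assert sum(s.n_records for s in strata.values()) == 1
        assert report.age_out_of_range == 2
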