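import datetime as dt

import pytest

from pmed.fixtures import study_calendar, study_records
from pmed.qc_gate import (
    BusinessCalendar,
    PathologyQC,
    PathologyRead,
    RnaQC,
    SampleRecord,
    effective_day1,
    gate_sample,
    pathology_qc_check,
    rna_qc_check,
    sample_record_from_dict,
    sample_record_to_dict,
    turnaround_days,
)


def d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


class TestRnaQC:
    def test_low_rin_fails_with_rin_reason(self):
        ok, reason = rna_qc_check(RnaQC(100, 1.84, 5.5))
        assert not ok and "RIN" in reason

    def test_missing_rin_passes_with_override(self):
        ok, _ = rna_qc_check(RnaQC(100, 2.09, None, electropherogram_override=True))
        assert ok

    def test_missing_rin_without_override_fails(self):
        ok, reason = rna_qc_check(RnaQC(100, 2.09, None))
        assert not ok and "RIN" in reason

    def test_boundaries_are_inclusive_for_ratio_and_rin(self):
        ok, _ = rna_qc_check(RnaQC(100, 1.8, 6.0))
        assert ok

    def test_yield_boundary_is_strict(self):
        ok, reason = rna_qc_check(RnaQC(20, 2.0, 8.0))
        assert not ok and "yield" in reason


class TestPathologyQC:
    def test_borderline_reads_pass_on_their_mean(self):
        # means (50, 45, 5): tumor exactly at the 50% boundary
        ok, _ = pathology_qc_check(PathologyQC(reads=[
            PathologyRead(50, 50, 0), PathologyRead(50, 40, 10)]))
        assert ok

    def test_necrosis_boundary_inclusive_on_mean(self):
        # means (80, 20, 20): one read at 25% necrosis is rescued by the other
        ok, _ = pathology_qc_check(PathologyQC(reads=[
            PathologyRead(80, 20, 15), PathologyRead(80, 20, 25)]))
        assert ok

    def test_no_tumor_flag_fails_with_printed_reason(self):
        ok, reason = pathology_qc_check(PathologyQC(no_tumor_flag=True))
        assert not ok and reason == "No neoplastic tissue observed"

    def test_no_reads_and_no_flag_is_an_error(self):
        with pytest.raises(ValueError):
            pathology_qc_check(PathologyQC(reads=[]))

    def test_high_normal_fraction_fails(self):
        ok, reason = pathology_qc_check(PathologyQC(reads=[
            PathologyRead(40, 55, 5), PathologyRead(45, 50, 5)]))
        assert not ok and "tumor" in reason and "normal" in reason


class TestGateSample:
    def test_shipping_failure_wins_before_everything(self):
        rec = SampleRecord("X", shipping_ok=False, rna_vari=RnaQC(100, 2.0, 3.0))
        decision = gate_sample(rec)
        assert decision.status == "fail" and decision.failed_stage == "shipping"

    def test_vari_rna_blocks_pathology(self):
        rec = SampleRecord("X", rna_vari=RnaQC(100, 2.0, 5.0),
                           pathology=PathologyQC(no_tumor_flag=True))
        assert gate_sample(rec).failed_stage == "rna_vari"

    def test_crl_recheck_runs_after_pathology(self):
        rec = SampleRecord(
            "X", rna_vari=RnaQC(100, 2.0, 7.0),
            pathology=PathologyQC(reads=[PathologyRead(80, 10, 10)]),
            rna_crl=RnaQC(100, 2.0, 5.8),
        )
        assert gate_sample(rec).failed_stage == "rna_crl"

    def test_all_pass_record_passes_without_stage(self):
        rec = SampleRecord(
            "X", rna_vari=RnaQC(100, 2.0, 8.0),
            pathology=PathologyQC(reads=[PathologyRead(80, 10, 10)]),
        )
        decision = gate_sample(rec)
        assert decision.status == "pass" and decision.failed_stage is None

    def test_missing_mandatory_stage_fails(self):
        rec = SampleRecord("X", rna_vari=RnaQC(100, 2.0, 8.0))
        assert gate_sample(rec).failed_stage == "pathology"


class TestEffectiveDay1:
    cal = study_calendar()

    @pytest.mark.parametrize(
        "receipt, expected",
        [
            ("2011-07-22", "2011-07-25"),  # Friday -> Monday
            ("2011-09-02", "2011-09-06"),  # Friday before a Monday holiday -> Tuesday
            ("2011-09-07", "2011-09-07"),  # Wednesday stays
            ("2011-09-03", "2011-09-06"),  # Saturday -> next business day past holiday
            ("2011-09-05", "2011-09-06"),  # holiday Monday -> Tuesday
        ],
    )
    def test_day1_defaulting(self, receipt, expected):
        assert effective_day1(d(receipt), self.cal) == d(expected)

    def test_idempotent_on_business_days(self):
        for receipt in ["2011-06-13", "2011-09-07", "2011-11-22"]:
            day1 = effective_day1(d(receipt), self.cal)
            assert effective_day1(day1, self.cal) == day1


class TestTurnaround:
    cal = study_calendar()

    def rec(self, receipt: str, report: str) -> SampleRecord:
        return SampleRecord("X", receipt_date=d(receipt), report_date=d(report))

    @pytest.mark.parametrize(
        "receipt, report, expected",
        [
            ("2011-06-13", "2011-06-17", 5),  # Mon..Fri inclusive
            ("2011-09-02", "2011-09-13", 6),  # Friday receipt, Monday holiday
            ("2011-09-30", "2011-10-09", 7),  # Sunday report costs the weekend
            ("2011-09-08", "2011-09-13", 4),
        ],
    )
    def test_business_day_counts(self, receipt, report, expected):
        assert turnaround_days(self.rec(receipt, report), self.cal) == expected

    def test_monotone_across_business_day_reports(self):
        days = [
            turnaround_days(self.rec("2011-09-02", report.isoformat()), self.cal)
            for k in range(14)
            if self.cal.is_business_day(report := d("2011-09-06") + dt.timedelta(days=k))
        ]
        assert days == sorted(days)

    def test_report_before_day1_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            turnaround_days(self.rec("2011-07-22", "2011-07-23"), self.cal)

    def test_missing_dates_rejected(self):
        with pytest.raises(ValueError):
            turnaround_days(SampleRecord("X"), self.cal)


class TestRecordSerialization:
    def test_round_trip_all_subjects(self):
        for rec in study_records():
            assert sample_record_from_dict(sample_record_to_dict(rec)) == rec


class TestStudyFixtureContent:
    records = {r.subject_id: r for r in study_records()}

    def test_printed_rna_values(self):
        assert self.records["MH-101"].rna_vari.rin == 5.5
        assert self.records["RB-185"].rna_crl.rin == 5.8
        assert self.records["FS-202"].rna_vari.rin is None
        assert self.records["FS-202"].rna_vari.electropherogram_override

    def test_printed_dates(self):
        fs202 = self.records["FS-202"]
        assert fs202.receipt_date == d("2011-09-30")  # a Friday
        assert fs202.report_date == d("2011-10-09")  # a Sunday

    def test_shipping_loss(self):
        assert not self.records["RV-282"].shipping_ok
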