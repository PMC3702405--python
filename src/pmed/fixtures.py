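"""The 20-subject canine-osteosarcoma feasibility cohort as literal records.

These records transcribe the study's published per-subject QC and timing
values — RNA purity ratios and integrity numbers at the primary (VARI) and
profiling (CRL) labs, the two pathology reads (1st/2nd cut), the shipping
mishap, and the surgery / receipt / shipment / data-upload / report dates —
so that the QC gate and the turnaround engine can be exercised against the
cohort's known outcomes: 13 of 20 pass, 4 of the 7 failures are RIN-caused,
and the adjusted turnaround of the 13 reported samples averages 5.08
business days.

RNA yields were not published per subject (the study reports no yield
failures); records carry a nominal 100 ng, comfortably above the >20 ng
gate.  Two subjects (FS-202, RB-187) had no RIN computed — an instrument
software error — but passed electropherogram visual inspection, recorded
here as the override flag.  The single public holiday in the study window
is Labor Day, 2011-09-05.
"""

from __future__ import annotations

import datetime as dt

from .qc_gate import (
    BusinessCalendar,
    PathologyQC,
    PathologyRead,
    RnaQC,
    SampleRecord,
)

__all__ = ["STUDY_HOLIDAYS", "study_calendar", "study_records"]

STUDY_HOLIDAYS = frozenset({dt.date(2011, 9, 5)})


def study_calendar() -> BusinessCalendar:
    return BusinessCalendar(holidays=STUDY_HOLIDAYS)


def _d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _rna(a260: float, rin: float | None, override: bool = False) -> RnaQC:
    return RnaQC(yield_ng=100.0, a260_280=a260, rin=rin,
                 electropherogram_override=override)


def _path(first: tuple, second: tuple, source: str = "frozen") -> PathologyQC:
    return PathologyQC(
        reads=[PathologyRead(*first), PathologyRead(*second)], source=source
    )


def study_records() -> list[SampleRecord]:
    """All 20 subjects in enrollment order."""
    return [
        SampleRecord(
            "AH-301", surgery_date=_d("2011-06-10"), receipt_date=_d("2011-06-13"),
            rna_ship_date=_d("2011-06-13"), data_upload_date=_d("2011-06-16"),
            report_date=_d("2011-06-17"),
            rna_vari=_rna(2.27, 8.0), pathology=_path((75, 5, 20), (75, 10, 15)),
        ),
        SampleRecord(
            "FS-201", surgery_date=_d("2011-06-20"), receipt_date=_d("2011-06-21"),
            rna_ship_date=_d("2011-06-21"), data_upload_date=_d("2011-06-27"),
            report_date=_d("2011-06-27"),
            rna_vari=_rna(2.08, 7.8), pathology=_path((80, 20, 15), (80, 20, 25)),
        ),
        SampleRecord(
            "RV-281", surgery_date=_d("2011-07-21"), receipt_date=_d("2011-07-22"),
            rna_ship_date=_d("2011-07-25"), data_upload_date=_d("2011-07-28"),
            report_date=_d("2011-07-29"),
            rna_vari=_rna(2.11, 9.3), pathology=_path((75, 20, 10), (75, 20, 10)),
        ),
        # Failed RIN at the primary lab; pathology never performed.
        SampleRecord(
            "MH-101", surgery_date=_d("2011-08-02"), receipt_date=_d("2011-08-03"),
            rna_vari=_rna(1.84, 5.5),
        ),
        SampleRecord(
            "TL-141", surgery_date=_d("2011-08-18"), receipt_date=_d("2011-08-19"),
            rna_ship_date=_d("2011-08-22"), data_upload_date=_d("2011-08-25"),
            report_date=_d("2011-08-26"),
            rna_vari=_rna(2.11, 6.8), pathology=_path((60, 30, 10), (50, 50, 0)),
        ),
        SampleRecord(
            "RB-181", surgery_date=_d("2011-08-19"), receipt_date=_d("2011-08-25"),
            rna_ship_date=_d("2011-08-25"), data_upload_date=_d("2011-08-31"),
            report_date=_d("2011-08-31"),
            rna_vari=_rna(2.11, 7.5), pathology=_path((80, 10, 10), (85, 5, 10)),
        ),
        SampleRecord(
            "RB-182", surgery_date=_d("2011-09-01"), receipt_date=_d("2011-09-02"),
            rna_ship_date=_d("2011-09-07"), data_upload_date=_d("2011-09-13"),
            report_date=_d("2011-09-13"),
            rna_vari=_rna(2.07, 8.5), pathology=_path((60, 20, 20), (60, 30, 10)),
        ),
        # Passed at the primary lab but no RIN could be generated on re-QC.
        SampleRecord(
            "RB-183", surgery_date=_d("2011-09-03"), receipt_date=_d("2011-09-08"),
            rna_ship_date=_d("2011-09-08"),
            rna_vari=_rna(2.09, 6.8), pathology=_path((90, 10, 0), (80, 10, 10)),
            rna_crl=_rna(2.09, None),
        ),
        SampleRecord(
            "VS-121", surgery_date=_d("2011-09-06"), receipt_date=_d("2011-09-07"),
            rna_ship_date=_d("2011-09-07"), data_upload_date=_d("2011-09-13"),
            report_date=_d("2011-09-13"),
            rna_vari=_rna(2.06, 6.4), pathology=_path((90, 5, 5), (95, 0, 5)),
        ),
        SampleRecord(
            "AZ-221", surgery_date=_d("2011-09-07"), receipt_date=_d("2011-09-08"),
            rna_ship_date=_d("2011-09-08"), data_upload_date=_d("2011-09-13"),
            report_date=_d("2011-09-13"),
            rna_vari=_rna(2.09, 8.1), pathology=_path((50, 50, 0), (50, 40, 10), "FFPE"),
        ),
        # Courier delay over a weekend; dry ice evaporated, sample at RT.
        SampleRecord(
            "RV-282", surgery_date=_d("2011-09-08"), receipt_date=_d("2011-09-12"),
            shipping_ok=False,
        ),
        SampleRecord(
            "NC-161", surgery_date=_d("2011-09-13"), receipt_date=_d("2011-09-15"),
            rna_ship_date=_d("2011-09-15"), data_upload_date=_d("2011-09-20"),
            report_date=_d("2011-09-20"),
            rna_vari=_rna(2.1, 8.0), pathology=_path((80, 15, 5), (80, 10, 10)),
        ),
        # RIN software error; electropherogram passed visual inspection.
        SampleRecord(
            "FS-202", surgery_date=_d("2011-09-24"), receipt_date=_d("2011-09-30"),
            rna_ship_date=_d("2011-10-03"), data_upload_date=_d("2011-10-07"),
            report_date=_d("2011-10-09"),
            rna_vari=_rna(2.09, None, override=True),
            pathology=_path((60, 30, 10), (65, 25, 10)),
        ),
        SampleRecord(
            "FS-203", surgery_date=_d("2011-09-29"), receipt_date=_d("2011-09-30"),
            rna_ship_date=_d("2011-10-03"),
            rna_vari=_rna(2.03, 7.2),
            pathology=PathologyQC(no_tumor_flag=True),
        ),
        SampleRecord(
            "RB-184", surgery_date=_d("2011-10-01"), receipt_date=_d("2011-10-05"),
            rna_ship_date=_d("2011-10-05"), data_upload_date=_d("2011-10-11"),
            report_date=_d("2011-10-11"),
            rna_vari=_rna(2.15, 6.8), pathology=_path((65, 30, 5), (70, 30, 0)),
        ),
        SampleRecord(
            "RB-185", surgery_date=_d("2011-10-05"), receipt_date=_d("2011-10-07"),
            rna_ship_date=_d("2011-10-10"),
            rna_vari=_rna(1.8, 6.9), pathology=_path((90, 5, 5), (75, 20, 15), "FFPE"),
            rna_crl=_rna(1.8, 5.8),
        ),
        SampleRecord(
            "RB-186", surgery_date=_d("2011-10-10"), receipt_date=_d("2011-10-14"),
            rna_vari=_rna(2.11, 5.4),
        ),
        SampleRecord(
            "RV-283", surgery_date=_d("2011-10-20"), receipt_date=_d("2011-10-21"),
            rna_ship_date=_d("2011-10-24"), data_upload_date=_d("2011-10-27"),
            report_date=_d("2011-10-28"),
            rna_vari=_rna(2.09, 8.4), pathology=_path((60, 40, 0), (60, 40, 0), "FFPE"),
        ),
        SampleRecord(
            "NC-162", surgery_date=_d("2011-10-31"), receipt_date=_d("2011-11-02"),
            rna_ship_date=_d("2011-11-02"),
            rna_vari=_rna(2.08, 7.4),
            pathology=PathologyQC(
                reads=[PathologyRead(0, 70, 30), PathologyRead(0, 70, 30)],
                no_tumor_flag=True,
            ),
        ),
        SampleRecord(
            "RB-187", surgery_date=_d("2011-11-10"), receipt_date=_d("2011-11-16"),
            rna_ship_date=_d("2011-11-16"), data_upload_date=_d("2011-11-22"),
            report_date=_d("2011-11-22"),
            rna_vari=_rna(2.09, None, override=True),
            pathology=_path((65, 25, 10), (65, 25, 10)),
        ),
    ]
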