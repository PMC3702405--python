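"""Staged sample QC gate and business-day turnaround accounting.

A sample travels shipping -> RNA QC at the primary lab -> pathology ->
RNA re-QC at the profiling lab -> cDNA QC -> array QC; the first failing
stage censors the sample with a recorded reason.  Shipping, primary RNA QC
and pathology are mandatory; the later stages are evaluated only when their
measurements exist (a sample that never reached the array is judged on what
was measured before it failed, and an all-pass record with no later-stage
data passes).

Thresholds (all boundary semantics exactly as operated by the study site):
RNA yield > 20 ng, A260/280 >= 1.8, RIN >= 6.0 (a missing RIN passes only
under an explicit electropherogram visual-inspection override); pathology
mean viable tumor >= 50%, mean viable normal < 50%, mean necrosis <= 20%
across the available reads; cDNA yield >= 5 ug, A260/280 >= 1.8; chip
metrics per :func:`pmed.expression.array_qc`.

Turnaround is counted in business days on a configurable calendar
(Sat/Sun weekends plus explicit holidays).  "Day 1" is the receipt date,
except that Friday, weekend or holiday receipts default to the next
business day.  The turnaround is the inclusive business-day count from
effective day 1 through the report date; when the report goes out on a
non-business day, the days past the last business day are counted as
calendar days (a Sunday report costs the Saturday and Sunday).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .expression import ArrayQCMetrics, array_qc

__all__ = [
    "RnaQC",
    "PathologyRead",
    "PathologyQC",
    "CdnaQC",
    "SampleRecord",
    "QCDecision",
    "BusinessCalendar",
    "STAGES",
    "rna_qc_check",
    "pathology_qc_check",
    "cdna_qc_check",
    "gate_sample",
    "effective_day1",
    "turnaround_days",
    "qc_summary",
    "sample_record_to_dict",
    "sample_record_from_dict",
]

STAGES = ("shipping", "rna_vari", "pathology", "rna_crl", "cdna", "array")


@dataclass
class RnaQC:
    yield_ng: float
    a260_280: float
    rin: float | None = None
    electropherogram_override: bool = False


@dataclass
class PathologyRead:
    pct_viable_tumor: float
    pct_viable_normal: float
    pct_necrosis: float


@dataclass
class PathologyQC:
    reads: list[PathologyRead] = field(default_factory=list)
    source: str = "frozen"  # "frozen" | "FFPE"
    no_tumor_flag: bool = False


@dataclass
class CdnaQC:
    yield_ug: float
    a260_280: float


@dataclass
class SampleRecord:
    subject_id: str
    surgery_date: dt.date | None = None
    receipt_date: dt.date | None = None
    rna_ship_date: dt.date | None = None
    data_upload_date: dt.date | None = None
    report_date: dt.date | None = None
    shipping_ok: bool = True
    rna_vari: RnaQC | None = None
    rna_crl: RnaQC | None = None
    pathology: PathologyQC | None = None
    cdna: CdnaQC | None = None
    array: ArrayQCMetrics | None = None


@dataclass
class QCDecision:
    status: str  # "pass" | "fail"
    failed_stage: str | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status == "fail" and self.failed_stage not in STAGES:
            raise ValueError("failed decision must name a stage")


@dataclass
class BusinessCalendar:
    """Sat/Sun weekends plus an explicit holiday set."""

    holidays: frozenset = frozenset()

    def _np_holidays(self) -> np.ndarray:
        return np.array(sorted(self.holidays), dtype="datetime64[D]")

    def is_business_day(self, d: dt.date) -> bool:
        return bool(np.is_busday(np.datetime64(d, "D"), holidays=self._np_holidays()))


def rna_qc_check(q: RnaQC, rin_threshold: float = 6.0) -> tuple[bool, str]:
    """RNA QC: yield > 20 ng, A260/280 >= 1.8, RIN >= threshold (or override)."""
    reasons = []
    if not q.yield_ng > 20:
        reasons.append(f"RNA yield {q.yield_ng:g} ng not > 20 ng")
    if not q.a260_280 >= 1.8:
        reasons.append(f"A260/280 {q.a260_280:g} below 1.8")
    if q.rin is not None:
        if not q.rin >= rin_threshold:
            reasons.append(f"RIN {q.rin:g} below {rin_threshold:g}")
    elif not q.electropherogram_override:
        reasons.append("RIN unavailable (no score generated) and no electropherogram override")
    return (not reasons, "; ".join(reasons))


def pathology_qc_check(p: PathologyQC) -> tuple[bool, str]:
    """Pathology QC on the mean of the available reads.

    Pass iff no-tumor flag is clear, mean viable tumor >= 50%, mean viable
    normal < 50% and mean necrosis <= 20%.
    """
    if p.no_tumor_flag:
        return False, "No neoplastic tissue observed"
    if not p.reads:
        raise ValueError("pathology record has no reads and no no-tumor flag")
    t = float(np.mean([r.pct_viable_tumor for r in p.reads]))
    n = float(np.mean([r.pct_viable_normal for r in p.reads]))
    x = float(np.mean([r.pct_necrosis for r in p.reads]))
    reasons = []
    if not t >= 50:
        reasons.append(f"viable tumor {t:g}% below 50%")
    if not n < 50:
        reasons.append(f"viable normal {n:g}% not below 50%")
    if not x <= 20:
        reasons.append(f"necrosis {x:g}% above 20%")
    return (not reasons, "; ".join(reasons))


def cdna_qc_check(c: CdnaQC) -> tuple[bool, str]:
    reasons = []
    if not c.yield_ug >= 5:
        reasons.append(f"cDNA yield {c.yield_ug:g} ug below 5 ug")
    if not c.a260_280 >= 1.8:
        reasons.append(f"A260/280 {c.a260_280:g} below 1.8")
    return (not reasons, "; ".join(reasons))


def gate_sample(s: SampleRecord, rin_threshold: float = 6.0) -> QCDecision:
    """Evaluate the staged gate; the first failing stage wins."""
    if not s.shipping_ok:
        return QCDecision("fail", "shipping", "Sample lost due to shipping error")

    if s.rna_vari is None:
        return QCDecision("fail", "rna_vari", "no primary-lab RNA QC record")
    ok, reason = rna_qc_check(s.rna_vari, rin_threshold)
    if not ok:
        return QCDecision("fail", "rna_vari", reason)

    if s.pathology is None:
        return QCDecision("fail", "pathology", "no pathology record")
    ok, reason = pathology_qc_check(s.pathology)
    if not ok:
        return QCDecision("fail", "pathology", reason)

    if s.rna_crl is not None:
        ok, reason = rna_qc_check(s.rna_crl, rin_threshold)
        if not ok:
            return QCDecision("fail", "rna_crl", reason)

    if s.cdna is not None:
        ok, reason = cdna_qc_check(s.cdna)
        if not ok:
            return QCDecision("fail", "cdna", reason)

    if s.array is not None:
        ok, failed = array_qc(s.array)
        if not ok:
            return QCDecision("fail", "array", "failed criteria: " + ", ".join(failed))

    return QCDecision("pass")


def effective_day1(receipt: dt.date, cal: BusinessCalendar | None = None) -> dt.date:
    """First processing day: the receipt date, unless it is a Friday, a
    weekend day or a holiday, in which case the next business day."""
    cal = cal or BusinessCalendar()
    d = np.datetime64(receipt, "D")
    hol = cal._np_holidays()
    if receipt.weekday() <= 3 and np.is_busday(d, holidays=hol):
        return receipt
    rolled = np.busday_offset(d + 1, 0, roll="forward", holidays=hol)
    return rolled.astype(dt.date)


def turnaround_days(s: SampleRecord, cal: BusinessCalendar | None = None) -> int:
    """Inclusive business-day count from effective day 1 through report date.

    A report sent on a non-business day additionally counts the calendar
    days past the last business day before it.
    """
    if s.receipt_date is None or s.report_date is None:
        raise ValueError(f"{s.subject_id}: turnaround needs receipt and report dates")
    cal = cal or BusinessCalendar()
    day1 = effective_day1(s.receipt_date, cal)
    if s.report_date < day1:
        raise ValueError(f"{s.subject_id}: report date precedes effective day 1")
    hol = cal._np_holidays()
    start = np.datetime64(day1, "D")
    report = np.datetime64(s.report_date, "D")
    if np.is_busday(report, holidays=hol):
        return int(np.busday_count(start, report, holidays=hol)) + 1
    last_bd = np.busday_offset(report, 0, roll="backward", holidays=hol)
    business = int(np.busday_count(start, last_bd, holidays=hol)) + 1
    trailing = int((report - last_bd).astype(int))
    return business + trailing


def _date(v) -> dt.date | None:
    if v in (None, ""):
        return None
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(v)


def sample_record_to_dict(s: SampleRecord) -> dict:
    """JSON-ready form of a sample record (ISO-8601 dates)."""

    def _iso(d: dt.date | None) -> str | None:
        return None if d is None else d.isoformat()

    out: dict = {
        "subject_id": s.subject_id,
        "surgery_date": _iso(s.surgery_date),
        "receipt_date": _iso(s.receipt_date),
        "rna_ship_date": _iso(s.rna_ship_date),
        "data_upload_date": _iso(s.data_upload_date),
        "report_date": _iso(s.report_date),
        "shipping_ok": s.shipping_ok,
    }
    if s.rna_vari is not None:
        out["rna_vari"] = vars(s.rna_vari)
    if s.rna_crl is not None:
        out["rna_crl"] = vars(s.rna_crl)
    if s.pathology is not None:
        out["pathology"] = {
            "reads": [vars(r) for r in s.pathology.reads],
            "source": s.pathology.source,
            "no_tumor_flag": s.pathology.no_tumor_flag,
        }
    if s.cdna is not None:
        out["cdna"] = vars(s.cdna)
    if s.array is not None:
        out["array"] = vars(s.array)
    return out


def sample_record_from_dict(d: dict) -> SampleRecord:
    p = d.get("pathology")
    return SampleRecord(
        subject_id=d["subject_id"],
        surgery_date=_date(d.get("surgery_date")),
        receipt_date=_date(d.get("receipt_date")),
        rna_ship_date=_date(d.get("rna_ship_date")),
        data_upload_date=_date(d.get("data_upload_date")),
        report_date=_date(d.get("report_date")),
        shipping_ok=bool(d.get("shipping_ok", True)),
        rna_vari=RnaQC(**d["rna_vari"]) if d.get("rna_vari") else None,
        rna_crl=RnaQC(**d["rna_crl"]) if d.get("rna_crl") else None,
        pathology=PathologyQC(
            reads=[PathologyRead(**r) for r in p.get("reads", [])],
            source=p.get("source", "frozen"),
            no_tumor_flag=bool(p.get("no_tumor_flag", False)),
        ) if p else None,
        cdna=CdnaQC(**d["cdna"]) if d.get("cdna") else None,
        array=ArrayQCMetrics(**d["array"]) if d.get("array") else None,
    )


def qc_summary(decisions: dict[str, QCDecision]) -> dict[str, float]:
    """Cohort-level pass-rate arithmetic, including the RIN-rescue counterfactual.

    ``rin_rescued_pass_rate_pct`` is the pass rate if every RIN-caused
    failure had instead yielded profiling-grade RNA.
    """
    n = len(decisions)
    n_pass = sum(d.status == "pass" for d in decisions.values())
    n_rin = sum(
        d.status == "fail" and "RIN" in d.reason and d.failed_stage in ("rna_vari", "rna_crl")
        for d in decisions.values()
    )
    return {
        "n": n,
        "n_pass": n_pass,
        "n_fail": n - n_pass,
        "n_rin_fail": n_rin,
        "pass_rate_pct": 100.0 * n_pass / n if n else float("nan"),
        "rin_rescued_pass_rate_pct": 100.0 * (n_pass + n_rin) / n if n else float("nan"),
    }
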