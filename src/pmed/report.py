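"""The report object and its JSON / plain-text renderings.

A report carries the subject, run metadata (seed, thresholds, versions,
QC verdict), the ranked drug list, the contraindicated list, per-method
evidence and the dropped-feature audit trail.  JSON rendering is
deterministic (sorted keys, fixed float repr) so equal reports render to
identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .ensemble import DrugScore
from .predictors import MethodPrediction
from .qc_gate import QCDecision

__all__ = ["PMedReport", "render_report", "report_from_json"]


@dataclass
class PMedReport:
    subject_id: str
    metadata: dict = field(default_factory=dict)
    qc: QCDecision | None = None
    ranked: list[DrugScore] = field(default_factory=list)
    contraindicated: list[DrugScore] = field(default_factory=list)
    predictions: list[MethodPrediction] = field(default_factory=list)
    dropped_features: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [d.rank for d in self.ranked]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..K without gaps")


def _score_dict(d: DrugScore) -> dict:
    return {
        "drug_id": d.drug_id,
        "rank": d.rank,
        "n_methods": d.n_methods,
        "summated_score": round(d.summated_score, 10),
        "contraindicated": d.contraindicated,
        "per_method_p": {m.value: p for m, p in sorted(d.per_method_p.items())},
    }


def _report_dict(r: PMedReport) -> dict:
    return {
        "subject_id": r.subject_id,
        "metadata": r.metadata,
        "qc": None if r.qc is None else {
            "status": r.qc.status,
            "failed_stage": r.qc.failed_stage,
            "reason": r.qc.reason,
        },
        "ranked": [_score_dict(d) for d in r.ranked],
        "contraindicated": [_score_dict(d) for d in r.contraindicated],
        "predictions": [
            {
                "drug_id": p.drug_id,
                "method": p.method.value,
                "score": round(p.score, 10),
                "p_value": p.p_value,
                "direction": p.direction.value,
                "evidence": [[e, round(c, 10)] for e, c in p.evidence],
            }
            for p in r.predictions
        ],
        "dropped_features": r.dropped_features,
    }


def render_report(r: PMedReport, format: str = "json") -> str:
    """Render to ``json`` (machine-readable, deterministic) or ``text``."""
    if format == "json":
        return json.dumps(_report_dict(r), indent=1, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")

    lines = [f"PMed report — subject {r.subject_id}", "=" * 40]
    if r.qc is not None:
        lines.append(f"QC: {r.qc.status.upper()}"
                     + (f" at stage {r.qc.failed_stage}: {r.qc.reason}"
                        if r.qc.status == "fail" else ""))
    if not r.ranked:
        lines.append("No indicated agents.")
    else:
        lines.append(f"{'rank':>4}  {'drug':<16} {'methods':>7} {'score':>10}")
        for d in r.ranked:
            lines.append(
                f"{d.rank:>4}  {d.drug_id:<16} {d.n_methods:>7} {d.summated_score:>10.3f}"
            )
    if r.contraindicated:
        lines.append("Contraindicated agents: " + ", ".join(d.drug_id for d in r.contraindicated))
    return "\n".join(lines) + "\n"


def report_from_json(text: str) -> dict:
    """Parse a JSON rendering back to its dictionary form (for round-trip checks)."""
    return json.loads(text)
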