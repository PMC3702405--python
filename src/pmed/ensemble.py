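"""Ensemble aggregation: summated drug scores and the final ranking.

Every method that indicates a drug contributes -log10(p) to that drug's
summated score (p floored at 1e-16 so the sum stays finite).  Drugs with
any contraindicating evidence are pulled out of the main ranking and listed
separately — a conservative reading of "DO NOT recommend".  The remaining
drugs are ordered by (number of indicating methods desc, summated score
desc, drug id asc), a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knowledge_base import Method
from .predictors import Direction, MethodPrediction, P_FLOOR

__all__ = ["DrugScore", "summate", "rank_drugs"]


@dataclass
class DrugScore:
    drug_id: str
    per_method_p: dict[Method, float] = field(default_factory=dict)
    n_methods: int = 0
    summated_score: float = 0.0
    contraindicated: bool = False
    rank: int | None = None
    contra_evidence: list = field(default_factory=list)


def summate(preds: list[MethodPrediction], floor: float = P_FLOOR) -> list[DrugScore]:
    """Aggregate per-method predictions into unranked per-drug scores.

    Indicating methods contribute -log10(max(p, floor)); any contraindicate
    prediction sets the flag.  A drug with only contraindications keeps a
    zero summated score.
    """
    seen: set[tuple[str, Method, Direction]] = set()
    scores: dict[str, DrugScore] = {}
    for p in preds:
        if not 0 < p.p_value <= 1:
            raise ValueError(f"{p.drug_id}/{p.method.value}: p {p.p_value} outside (0, 1]")
        key = (p.drug_id, p.method, p.direction)
        if key in seen:
            raise ValueError(f"duplicate prediction for {key}")
        seen.add(key)
        ds = scores.setdefault(p.drug_id, DrugScore(p.drug_id))
        if p.direction is Direction.contraindicated:
            ds.contraindicated = True
            ds.contra_evidence.extend(p.evidence)
        else:
            ds.per_method_p[p.method] = p.p_value
            ds.n_methods += 1
            ds.summated_score += -float(np.log10(max(p.p_value, floor)))
    return sorted(scores.values(), key=lambda d: d.drug_id)


def rank_drugs(scores: list[DrugScore]) -> tuple[list[DrugScore], list[DrugScore]]:
    """Split off contraindicated drugs and rank the rest 1..K.

    Sort key: indicating-method count descending, then summated score
    descending, then drug id ascending.
    Returns (ranked, contraindicated).
    """
    contra = sorted((d for d in scores if d.contraindicated), key=lambda d: d.drug_id)
    main = sorted(
        (d for d in scores if not d.contraindicated),
        key=lambda d: (-d.n_methods, -d.summated_score, d.drug_id),
    )
    for i, d in enumerate(main, start=1):
        d.rank = i
    return main, contra
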