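"""The five drug-prediction methods.

Each method maps a human-gene-level Z-profile plus the knowledge base to a
list of per-drug :class:`MethodPrediction` records carrying a
method-specific score, a p-value in (0, 1], a direction (only biomarker
rules can contraindicate) and the gene/rule/instance evidence behind it.

Methods
-------
biomarker_rules
    Binary IF-Z-THEN-(contra)indicate rules; the drug's score is the most
    extreme qualifying |Z| and its p the one-sided standard-normal tail.
target_expression
    A drug is indicated when it inhibits a target whose Z >= +3; score is
    the best target Z, p its one-sided normal tail.
response_signature
    Connectivity-map reversal scoring: KS-style rank enrichment of the
    tumor's capped up/down DEG sets in each drug-perturbation rank profile,
    averaged over a drug's instances; drugs that reverse the disease
    signature (negative connectivity) are candidates, with a one-sided
    permutation p-value over random same-size query sets.
sensitivity_signature
    Parametric gene-set enrichment (PGSEA): a mean-shift z statistic of the
    drug's sensitivity set against the whole-profile distribution, with
    resistance-associated genes folded by negation about the profile mean.
network_activity
    Upstream-activity inference on direct transcriptional out-edges of each
    drug target: hypergeometric enrichment of DEGs among the target's
    regulon, signed by edge-direction concordance.

The normal-tail p-value constructions of the first two methods are this
package's own, chosen to be monotone in evidence strength and compatible
with the ensemble's sum of -log10(p).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import Level, ZProfile
from .knowledge_base import KnowledgeBase, Method, ResponseSignature

__all__ = [
    "Direction",
    "DEGSelection",
    "MethodPrediction",
    "select_degs",
    "biomarker_rules_predict",
    "target_expression_predict",
    "connectivity_score",
    "response_signature_predict",
    "sensitivity_signature_predict",
    "network_activity_predict",
    "predict_all",
]

P_FLOOR = 1e-16  # p-values are floored here before any log transform


class Direction(str, enum.Enum):
    indicated = "indicated"
    contraindicated = "contraindicated"


@dataclass
class DEGSelection:
    """Up/down differentially expressed gene sets at |Z| >= threshold, capped."""

    up_genes: frozenset
    down_genes: frozenset
    cap: int = 500
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("a gene cannot be both up and down")
        if len(self.up_genes) + len(self.down_genes) > self.cap:
            raise ValueError("DEG selection exceeds its cap")

    @property
    def all_genes(self) -> frozenset:
        return self.up_genes | self.down_genes


@dataclass
class MethodPrediction:
    drug_id: str
    method: Method
    score: float
    p_value: float
    direction: Direction = Direction.indicated
    evidence: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.method = Method(self.method)
        self.direction = Direction(self.direction)
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if self.direction is Direction.contraindicated and self.method is not Method.biomarker_rules:
            raise ValueError("only biomarker rules can contraindicate")


def _require_human_gene(z: ZProfile) -> None:
    if z.level is not Level.human_gene:
        raise ValueError(f"predictors operate on human_gene profiles, got {z.level.value}")


def select_degs(z: ZProfile, threshold: float = 2.0, cap: int = 500) -> DEGSelection:
    """Genes with |Z| >= threshold; if more than *cap*, keep the cap genes of
    largest |Z| (ties broken by gene id ascending).  Signs are preserved."""
    _require_human_gene(z)
    if cap <= 0:
        raise ValueError("cap must be positive")
    qualifying = [(g, v) for g, v in z.values.items() if abs(v) >= threshold]
    if len(qualifying) > cap:
        qualifying.sort(key=lambda gv: (-abs(gv[1]), gv[0]))
        qualifying = qualifying[:cap]
    up = frozenset(g for g, v in qualifying if v > 0)
    down = frozenset(g for g, v in qualifying if v < 0)
    return DEGSelection(up, down, cap=cap, z_threshold=threshold)


# ---------------------------------------------------------------------------
# Biomarker rules


def biomarker_rules_predict(z: ZProfile, kb: KnowledgeBase) -> list[MethodPrediction]:
    _require_human_gene(z)
    fired: dict[tuple[str, Direction], list[tuple[str, float]]] = {}
    non_evaluable: dict[str, list[tuple[str, float]]] = {}
    for rule in kb.rules:
        if rule.gene not in z.values:
            non_evaluable.setdefault(rule.drug_id, []).append((f"rule:{rule.rule_id}:absent", 0.0))
            continue
        value = z.values[rule.gene]
        hit = value > rule.threshold_z if rule.comparator == "greater" else value < rule.threshold_z
        if not hit:
            continue
        direction = (
            Direction.indicated if rule.verdict == "indicate" else Direction.contraindicated
        )
        fired.setdefault((rule.drug_id, direction), []).append((f"rule:{rule.rule_id}", value))

    preds = []
    for (drug_id, direction), evidence in sorted(fired.items()):
        score = max(abs(v) for _, v in evidence)
        preds.append(
            MethodPrediction(
                drug_id, Method.biomarker_rules, score,
                max(float(stats.norm.sf(score)), P_FLOOR), direction,
                evidence + non_evaluable.get(drug_id, []),
            )
        )
    return preds


# ---------------------------------------------------------------------------
# Drug target expression


def target_expression_predict(
    z: ZProfile, kb: KnowledgeBase, threshold: float = 3.0
) -> list[MethodPrediction]:
    """Indicate drugs inhibiting a target over-expressed at Z >= threshold."""
    _require_human_gene(z)
    qualifying: dict[str, list[tuple[str, float]]] = {}
    for t in kb.targets:
        if t.action != "inhibits":
            continue
        value = z.values.get(t.target_gene)
        if value is not None and value >= threshold:
            qualifying.setdefault(t.drug_id, []).append((t.target_gene, value))
    preds = []
    for drug_id, evidence in sorted(qualifying.items()):
        score = max(v for _, v in evidence)
        preds.append(
            MethodPrediction(
                drug_id, Method.target_expression, score,
                max(float(stats.norm.sf(score)), P_FLOOR),
                evidence=sorted(evidence),
            )
        )
    return preds


# ---------------------------------------------------------------------------
# Drug response signatures (connectivity-map reversal)


def _ks_statistic(positions: np.ndarray, n: int) -> float:
    """Signed KS enrichment of a gene set at 1-based *positions* in a ranked
    list of length *n*: a = max_j[j/t - r_j/n], b = max_j[r_j/n - (j-1)/t],
    returns a if a > b else -b."""
    r = np.sort(np.asarray(positions, dtype=float))
    t = len(r)
    j = np.arange(1, t + 1, dtype=float)
    a = float((j / t - r / n).max())
    b = float((r / n - (j - 1) / t).max())
    return a if a > b else -b


def connectivity_score(degs: DEGSelection, sig: ResponseSignature) -> float:
    """Connectivity of the query up/down sets with one drug rank profile.

    Positive: the drug mimics the disease signature (pushes up-genes up);
    negative: the drug reverses it.  Value in [-1, 1].
    """
    if not degs.up_genes and not degs.down_genes:
        raise ValueError("empty DEG selection")
    rank_of = {g: i + 1 for i, g in enumerate(sig.ranked_genes)}
    missing = degs.all_genes - rank_of.keys()
    if missing:
        raise ValueError(f"genes outside signature universe: {sorted(missing)[:5]}")
    n = len(sig.ranked_genes)
    ks_up = (
        _ks_statistic(np.array([rank_of[g] for g in degs.up_genes]), n)
        if degs.up_genes else None
    )
    ks_down = (
        _ks_statistic(np.array([rank_of[g] for g in degs.down_genes]), n)
        if degs.down_genes else None
    )
    if ks_up is not None and ks_down is not None:
        return (ks_up - ks_down) / 2.0
    return ks_up if ks_up is not None else -ks_down


def _mean_connectivity(
    up_pos: np.ndarray | None, down_pos: np.ndarray | None, rank_arrays: list[np.ndarray], n: int
) -> float:
    """Mean connectivity over instances, given index arrays into each instance's
    rank lookup (up_pos/down_pos are universe indices; rank_arrays[i][g] is the
    1-based rank of universe gene g in instance i)."""
    total = 0.0
    for ranks in rank_arrays:
        ks_up = _ks_statistic(ranks[up_pos], n) if up_pos is not None else None
        ks_down = _ks_statistic(ranks[down_pos], n) if down_pos is not None else None
        if ks_up is not None and ks_down is not None:
            total += (ks_up - ks_down) / 2.0
        else:
            total += ks_up if ks_up is not None else -ks_down
    return total / len(rank_arrays)


def response_signature_predict(
    degs: DEGSelection,
    kb: KnowledgeBase,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[MethodPrediction]:
    """Candidate drugs whose perturbation signatures reverse the DEG sets.

    Per drug the score is the mean connectivity across its signature
    instances; only drugs with negative (reversing) scores are emitted.
    The p-value is one-sided toward reversal from *n_perm* random query
    sets of the same sizes drawn from the universe, with the +1/(n+1)
    correction so p is never zero.
    """
    if not degs.up_genes and not degs.down_genes:
        raise ValueError("empty DEG selection")
    if not kb.response_signatures:
        raise ValueError("knowledge base has no response signatures")

    universe = sorted(kb.gene_universe)
    index_of = {g: i for i, g in enumerate(universe)}
    missing = degs.all_genes - index_of.keys()
    if missing:
        raise ValueError(f"DEG genes outside universe: {sorted(missing)[:5]}")
    n = len(universe)
    n_up, n_down = len(degs.up_genes), len(degs.down_genes)
    up_pos = np.array(sorted(index_of[g] for g in degs.up_genes)) if n_up else None
    down_pos = np.array(sorted(index_of[g] for g in degs.down_genes)) if n_down else None

    by_drug: dict[str, list[ResponseSignature]] = {}
    for sig in kb.response_signatures:
        by_drug.setdefault(sig.drug_id, []).append(sig)

    rng = np.random.default_rng(seed)
    # Shared permutation draws across drugs: one set of random query sets,
    # evaluated against each drug's instances.
    perm_sets = []
    for _ in range(n_perm):
        draw = rng.choice(n, size=n_up + n_down, replace=False)
        perm_sets.append((draw[:n_up] if n_up else None, draw[n_up:] if n_down else None))

    preds = []
    for drug_id in sorted(by_drug):
        instances = by_drug[drug_id]
        rank_arrays = []
        for sig in instances:
            ranks = np.empty(n, dtype=np.int64)
            for pos, g in enumerate(sig.ranked_genes):
                ranks[index_of[g]] = pos + 1
            rank_arrays.append(ranks)
        observed = _mean_connectivity(up_pos, down_pos, rank_arrays, n)
        if observed >= 0:
            continue  # not a reversal candidate
        null = np.array(
            [_mean_connectivity(u, d, rank_arrays, n) for u, d in perm_sets]
        )
        p = (1 + int((null <= observed).sum())) / (n_perm + 1)
        preds.append(
            MethodPrediction(
                drug_id, Method.response_signature, observed, max(p, P_FLOOR),
                evidence=[(s.instance_id, observed) for s in instances],
            )
        )
    return preds


# ---------------------------------------------------------------------------
# Drug sensitivity signatures (PGSEA)


def sensitivity_signature_predict(z: ZProfile, kb: KnowledgeBase) -> list[MethodPrediction]:
    """Parametric gene-set enrichment of each drug's sensitivity set.

    With profile mean mu and sd sigma (over all genes in *z*), each set gene
    contributes v_g = mu + sign_g * (Z_g - mu): resistance-associated genes
    (sign -1) are folded by negation about the profile mean, so an
    up-shifted resistance set scores negative and the statistic is invariant
    under adding a constant to every Z.  zstat = (mean(v) - mu) * sqrt(m) / sigma;
    drugs with zstat > 0 are predicted, p is the upper normal tail.
    """
    _require_human_gene(z)
    all_z = np.fromiter(z.values.values(), dtype=float)
    if len(all_z) < 2:
        raise ValueError("profile too small for PGSEA")
    mu = float(all_z.mean())
    sigma = float(all_z.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate profile: zero Z variance")

    preds = []
    for sig in kb.sensitivity_signatures:
        present = {g: s for g, s in sig.entries.items() if g in z.values}
        m = len(present)
        if m < 2:
            continue  # too few measurable genes; drug not evaluable
        v = np.array([mu + s * (z.values[g] - mu) for g, s in present.items()])
        zstat = (float(v.mean()) - mu) * np.sqrt(m) / sigma
        if zstat <= 0:
            continue
        preds.append(
            MethodPrediction(
                sig.drug_id, Method.sensitivity_signature, float(zstat),
                max(float(stats.norm.sf(zstat)), P_FLOOR),
                evidence=sorted((g, s * z.values[g]) for g, s in present.items()),
            )
        )
    preds.sort(key=lambda p: p.drug_id)
    return preds


# ---------------------------------------------------------------------------
# Network target activity


def network_activity_predict(
    degs: DEGSelection, kb: KnowledgeBase, alpha: float = 0.05
) -> list[MethodPrediction]:
    """Upstream target activity from direct transcriptional out-edges.

    For each drug-target node u: with D(u) its transcriptional regulon and
    k the DEGs among it, the enrichment p is the hypergeometric upper tail
    of >= k DEGs in |D(u)| draws from the universe.  The activity sign is
    (concordant - discordant) where a DEG is concordant when
    edge effect x DEG direction = +1.  u is active iff p < alpha and
    sign > 0; a drug is predicted iff it inhibits an active target, scored
    by -log10 of its best target p.
    """
    if not kb.network:
        raise ValueError("knowledge base has no interaction network")
    out_edges: dict[str, list] = {}
    for e in kb.network:
        if e.transcriptional:
            out_edges.setdefault(e.source_gene, []).append(e)

    n_universe = len(kb.gene_universe)
    n_degs = len(degs.all_genes)

    target_p: dict[str, float] = {}
    target_k: dict[str, int] = {}
    for u in sorted({t.target_gene for t in kb.targets}):
        edges = out_edges.get(u)
        if not edges:
            continue  # target absent from network: non-evaluable
        k = concordant = discordant = 0
        for e in edges:
            if e.target_gene in degs.up_genes:
                direction = +1
            elif e.target_gene in degs.down_genes:
                direction = -1
            else:
                continue
            k += 1
            if e.effect * direction == +1:
                concordant += 1
            elif e.effect * direction == -1:
                discordant += 1
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, n_degs, len(edges)))
        if p < alpha and (concordant - discordant) > 0:
            target_p[u] = max(p, P_FLOOR)
            target_k[u] = k

    preds = []
    by_drug: dict[str, list[str]] = {}
    for t in kb.targets:
        if t.action == "inhibits" and t.target_gene in target_p:
            by_drug.setdefault(t.drug_id, []).append(t.target_gene)
    for drug_id, actives in sorted(by_drug.items()):
        best_p = min(target_p[u] for u in actives)
        preds.append(
            MethodPrediction(
                drug_id, Method.network_activity, -float(np.log10(best_p)), best_p,
                evidence=[(u, float(target_k[u])) for u in sorted(actives)],
            )
        )
    return preds


# ---------------------------------------------------------------------------


def predict_all(
    z: ZProfile,
    kb: KnowledgeBase,
    seed: int = 0,
    deg_threshold: float = 2.0,
    deg_cap: int = 500,
    target_threshold: float = 3.0,
    network_alpha: float = 0.05,
    n_perm: int = 1000,
) -> list[MethodPrediction]:
    """Run all five methods on one human-gene profile and concatenate results.

    The DEG-driven methods are skipped gracefully when no gene passes the
    DEG threshold or their evidence store is empty.
    """
    preds: list[MethodPrediction] = []
    preds += biomarker_rules_predict(z, kb)
    preds += target_expression_predict(z, kb, threshold=target_threshold)
    preds += sensitivity_signature_predict(z, kb)
    degs = select_degs(z, threshold=deg_threshold, cap=deg_cap)
    if degs.all_genes:
        if kb.response_signatures:
            preds += response_signature_predict(degs, kb, n_perm=n_perm, seed=seed)
        if kb.network:
            preds += network_activity_predict(degs, kb, alpha=network_alpha)
    return preds
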