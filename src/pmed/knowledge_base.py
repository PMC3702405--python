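"""Drug-centric evidence stores consumed by the five prediction methods.

A :class:`KnowledgeBase` bundles a drug list with five method-specific
stores — mechanism-of-action targets, binary biomarker rules, drug-response
rank signatures, drug-sensitivity gene sets, and a directed gene-interaction
network — over a single human-gene namespace.  Gene identifiers are plain
string tokens playing the role of human Entrez IDs; there is no live
database access, so a KB directory is a complete, diff-able description of
everything the predictors may cite as evidence.

On-disk layout (bound by a ``manifest.yaml``): tabular stores are
tab-delimited with a header row and ``#`` comments; the drug list and the
response-signature rank profiles are JSON; the gene universe is one
identifier per line.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "Method",
    "Drug",
    "DrugTargetEntry",
    "BiomarkerRule",
    "ResponseSignature",
    "SensitivitySignature",
    "NetworkEdge",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "save_knowledge_base",
    "drugs_predictable_by",
]


class KnowledgeBaseError(ValueError):
    """Raised for parse failures, duplicate identifiers or dangling references.

    The message always names the offending file (and line where known).
    """


class Method(str, enum.Enum):
    """The five prediction methods."""

    biomarker_rules = "biomarker_rules"
    target_expression = "target_expression"
    response_signature = "response_signature"
    sensitivity_signature = "sensitivity_signature"
    network_activity = "network_activity"


@dataclass(frozen=True)
class Drug:
    drug_id: str
    name: str
    canine_dosing_note: str | None = None


@dataclass(frozen=True)
class DrugTargetEntry:
    """One mechanism-of-action link: *drug* inhibits/activates *target_gene*."""

    drug_id: str
    target_gene: str
    action: str  # "inhibits" | "activates"


@dataclass(frozen=True)
class BiomarkerRule:
    """IF gene expressed >/< threshold (Z units) THEN (contra)indicate drug.

    ``weight`` exists for future disease-context weighting but is fixed at
    1.0 and never read by scoring.
    """

    rule_id: str
    gene: str
    comparator: str  # "greater" | "less"
    threshold_z: float
    verdict: str  # "indicate" | "contraindicate"
    drug_id: str
    weight: float = 1.0


@dataclass(frozen=True)
class ResponseSignature:
    """One drug-perturbation instance: a total ranking of the gene universe.

    ``ranked_genes[0]`` is the gene most up-regulated by the drug.
    """

    drug_id: str
    instance_id: str
    ranked_genes: tuple[str, ...]


@dataclass(frozen=True)
class SensitivitySignature:
    """Gene set whose expression tracks in-vitro sensitivity to the drug.

    ``entries`` maps gene -> +1 (sensitivity-associated) or -1
    (resistance-associated).
    """

    drug_id: str
    entries: dict[str, int]


@dataclass(frozen=True)
class NetworkEdge:
    source_gene: str
    target_gene: str
    effect: int  # +1 activation, -1 inhibition, 0 unspecified
    transcriptional: bool


@dataclass
class KnowledgeBase:
    drugs: dict[str, Drug]
    targets: list[DrugTargetEntry] = field(default_factory=list)
    rules: list[BiomarkerRule] = field(default_factory=list)
    response_signatures: list[ResponseSignature] = field(default_factory=list)
    sensitivity_signatures: list[SensitivitySignature] = field(default_factory=list)
    network: list[NetworkEdge] = field(default_factory=list)
    gene_universe: frozenset[str] = frozenset()

    def validate(self) -> None:
        """Check every typed invariant; raise :class:`KnowledgeBaseError` on the first violation."""
        for d in self.drugs.values():
            if not d.name:
                raise KnowledgeBaseError(f"drug {d.drug_id!r}: empty name")

        def _gene(g: str, where: str) -> None:
            if g not in self.gene_universe:
                raise KnowledgeBaseError(f"{where}: gene {g!r} not in gene universe")

        def _drug(d: str, where: str) -> None:
            if d not in self.drugs:
                raise KnowledgeBaseError(f"{where}: unknown drug {d!r}")

        seen_targets: set[tuple[str, str]] = set()
        for t in self.targets:
            _drug(t.drug_id, "targets")
            _gene(t.target_gene, "targets")
            if t.action not in ("inhibits", "activates"):
                raise KnowledgeBaseError(f"targets: bad action {t.action!r}")
            key = (t.drug_id, t.target_gene)
            if key in seen_targets:
                raise KnowledgeBaseError(f"targets: duplicate pair {key}")
            seen_targets.add(key)

        seen_rules: set[str] = set()
        for r in self.rules:
            _drug(r.drug_id, f"rules[{r.rule_id}]")
            _gene(r.gene, f"rules[{r.rule_id}]")
            if r.comparator not in ("greater", "less"):
                raise KnowledgeBaseError(f"rules[{r.rule_id}]: bad comparator {r.comparator!r}")
            if r.verdict not in ("indicate", "contraindicate"):
                raise KnowledgeBaseError(f"rules[{r.rule_id}]: bad verdict {r.verdict!r}")
            if not pd.notna(r.threshold_z) or abs(r.threshold_z) == float("inf"):
                raise KnowledgeBaseError(f"rules[{r.rule_id}]: non-finite threshold")
            if r.rule_id in seen_rules:
                raise KnowledgeBaseError(f"rules: duplicate rule_id {r.rule_id!r}")
            seen_rules.add(r.rule_id)

        universe = self.gene_universe
        seen_inst: set[tuple[str, str]] = set()
        for s in self.response_signatures:
            _drug(s.drug_id, f"response_signatures[{s.instance_id}]")
            key = (s.drug_id, s.instance_id)
            if key in seen_inst:
                raise KnowledgeBaseError(f"response_signatures: duplicate instance {key}")
            seen_inst.add(key)
            if set(s.ranked_genes) != universe or len(s.ranked_genes) != len(universe):
                raise KnowledgeBaseError(
                    f"response_signatures[{s.instance_id}]: ranked_genes is not a "
                    "permutation of the gene universe"
                )

        for s in self.sensitivity_signatures:
            _drug(s.drug_id, "sensitivity_signatures")
            if len(s.entries) < 2:
                raise KnowledgeBaseError(
                    f"sensitivity_signatures[{s.drug_id}]: set size {len(s.entries)} < 2"
                )
            for g, sign in s.entries.items():
                _gene(g, f"sensitivity_signatures[{s.drug_id}]")
                if sign not in (+1, -1):
                    raise KnowledgeBaseError(
                        f"sensitivity_signatures[{s.drug_id}]: bad sign {sign!r} for {g!r}"
                    )

        seen_edges: set[tuple[str, str, bool]] = set()
        for e in self.network:
            _gene(e.source_gene, "network")
            _gene(e.target_gene, "network")
            if e.source_gene == e.target_gene:
                raise KnowledgeBaseError(f"network: self-loop on {e.source_gene!r}")
            if e.effect not in (+1, -1, 0):
                raise KnowledgeBaseError(f"network: bad effect {e.effect!r}")
            key = (e.source_gene, e.target_gene, e.transcriptional)
            if key in seen_edges:
                raise KnowledgeBaseError(f"network: duplicate edge {key}")
            seen_edges.add(key)


_STORE_FILES = {
    "genes": "genes.txt",
    "drugs": "drugs.json",
    "targets": "targets.tsv",
    "rules": "rules.tsv",
    "sensitivity": "sensitivity.tsv",
    "network": "network.tsv",
    "response_signatures": "response_signatures.json",
}


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise KnowledgeBaseError(f"{path}: parse failure: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"{path}: missing columns {missing}")
    return df


def load_knowledge_base(directory: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge-base directory.

    The directory must contain a ``manifest.yaml`` naming each store file
    (defaults are used for any store the manifest omits).  Empty tabular
    stores are legal.  Raises :class:`KnowledgeBaseError` naming the
    offending file for parse failures, duplicates or dangling references.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    files = dict(_STORE_FILES)
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh) or {}
        files.update({k: v for k, v in manifest.get("stores", {}).items()})

    genes_path = directory / files["genes"]
    if not genes_path.exists():
        raise KnowledgeBaseError(f"{genes_path}: gene universe file missing")
    universe = frozenset(
        line.strip() for line in genes_path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )

    drugs_path = directory / files["drugs"]
    try:
        raw_drugs = json.loads(drugs_path.read_text())
    except Exception as exc:  # noqa: BLE001
        raise KnowledgeBaseError(f"{drugs_path}: parse failure: {exc}") from exc
    drugs: dict[str, Drug] = {}
    for rec in raw_drugs:
        d = Drug(rec["drug_id"], rec["name"], rec.get("canine_dosing_note"))
        if d.drug_id in drugs:
            raise KnowledgeBaseError(f"{drugs_path}: duplicate drug_id {d.drug_id!r}")
        drugs[d.drug_id] = d

    kb = KnowledgeBase(drugs=drugs, gene_universe=universe)

    tpath = directory / files["targets"]
    if tpath.exists():
        df = _read_tsv(tpath, ["drug_id", "target_gene", "action"])
        kb.targets = [
            DrugTargetEntry(r.drug_id, r.target_gene, r.action)
            for r in df.itertuples(index=False)
        ]

    rpath = directory / files["rules"]
    if rpath.exists():
        df = _read_tsv(
            rpath, ["rule_id", "gene", "comparator", "threshold_z", "verdict", "drug_id"]
        )
        kb.rules = [
            BiomarkerRule(
                r.rule_id, r.gene, r.comparator, float(r.threshold_z), r.verdict,
                r.drug_id, float(getattr(r, "weight", 1.0) or 1.0),
            )
            for r in df.itertuples(index=False)
        ]

    spath = directory / files["sensitivity"]
    if spath.exists():
        df = _read_tsv(spath, ["drug_id", "gene", "sign"])
        by_drug: dict[str, dict[str, int]] = {}
        for r in df.itertuples(index=False):
            entries = by_drug.setdefault(r.drug_id, {})
            if r.gene in entries:
                raise KnowledgeBaseError(
                    f"{spath}: duplicate gene {r.gene!r} in set for drug {r.drug_id!r}"
                )
            entries[r.gene] = int(r.sign)
        kb.sensitivity_signatures = [
            SensitivitySignature(d, entries) for d, entries in sorted(by_drug.items())
        ]

    npath = directory / files["network"]
    if npath.exists():
        df = _read_tsv(npath, ["source_gene", "target_gene", "effect", "transcriptional"])
        kb.network = [
            NetworkEdge(
                r.source_gene, r.target_gene, int(r.effect),
                str(r.transcriptional).lower() in ("1", "true", "yes"),
            )
            for r in df.itertuples(index=False)
        ]

    sigpath = directory / files["response_signatures"]
    if sigpath.exists():
        try:
            raw = json.loads(sigpath.read_text())
        except Exception as exc:  # noqa: BLE001
            raise KnowledgeBaseError(f"{sigpath}: parse failure: {exc}") from exc
        kb.response_signatures = [
            ResponseSignature(rec["drug_id"], rec["instance_id"], tuple(rec["ranked_genes"]))
            for rec in raw
        ]

    try:
        kb.validate()
    except KnowledgeBaseError as exc:
        raise KnowledgeBaseError(f"{directory}: {exc}") from exc
    return kb


def save_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write a KB directory that :func:`load_knowledge_base` round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"format": "pmed-kb/1", "stores": _STORE_FILES}, fh)

    (directory / _STORE_FILES["genes"]).write_text(
        "".join(f"{g}\n" for g in sorted(kb.gene_universe))
    )
    with open(directory / _STORE_FILES["drugs"], "w") as fh:
        json.dump(
            [
                {"drug_id": d.drug_id, "name": d.name, "canine_dosing_note": d.canine_dosing_note}
                for d in sorted(kb.drugs.values(), key=lambda d: d.drug_id)
            ],
            fh, indent=1,
        )

    pd.DataFrame(
        [(t.drug_id, t.target_gene, t.action) for t in kb.targets],
        columns=["drug_id", "target_gene", "action"],
    ).to_csv(directory / _STORE_FILES["targets"], sep="\t", index=False)

    pd.DataFrame(
        [
            (r.rule_id, r.gene, r.comparator, repr(r.threshold_z), r.verdict, r.drug_id, r.weight)
            for r in kb.rules
        ],
        columns=["rule_id", "gene", "comparator", "threshold_z", "verdict", "drug_id", "weight"],
    ).to_csv(directory / _STORE_FILES["rules"], sep="\t", index=False)

    pd.DataFrame(
        [
            (s.drug_id, g, sign)
            for s in sorted(kb.sensitivity_signatures, key=lambda s: s.drug_id)
            for g, sign in sorted(s.entries.items())
        ],
        columns=["drug_id", "gene", "sign"],
    ).to_csv(directory / _STORE_FILES["sensitivity"], sep="\t", index=False)

    pd.DataFrame(
        [
            (e.source_gene, e.target_gene, e.effect, str(e.transcriptional).lower())
            for e in kb.network
        ],
        columns=["source_gene", "target_gene", "effect", "transcriptional"],
    ).to_csv(directory / _STORE_FILES["network"], sep="\t", index=False)

    with open(directory / _STORE_FILES["response_signatures"], "w") as fh:
        json.dump(
            [
                {
                    "drug_id": s.drug_id,
                    "instance_id": s.instance_id,
                    "ranked_genes": list(s.ranked_genes),
                }
                for s in kb.response_signatures
            ],
            fh,
        )


def drugs_predictable_by(kb: KnowledgeBase, method: Method | str) -> set[str]:
    """Drugs with at least one evidence record in *method*'s store.

    For ``network_activity`` a drug is coverable when at least one of its
    targets appears as a source node of the interaction network.
    """
    method = Method(method)
    if method is Method.biomarker_rules:
        return {r.drug_id for r in kb.rules}
    if method is Method.target_expression:
        return {t.drug_id for t in kb.targets}
    if method is Method.response_signature:
        return {s.drug_id for s in kb.response_signatures}
    if method is Method.sensitivity_signature:
        return {s.drug_id for s in kb.sensitivity_signatures}
    sources = {e.source_gene for e in kb.network}
    return {t.drug_id for t in kb.targets if t.target_gene in sources}
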