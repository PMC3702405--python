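"""Synthetic study generator: expression profiles, mapping tables, a
miniature knowledge base with planted ground truth, and QC failure modes.

The generator emulates the study conditions the pipeline was built for:
a five-sample normal-bone reference set profiled on the same platform as
the tumor, probe intensities that are positive and right-skewed
(log-normal baselines with multiplicative log-normal noise), several
probes per gene, and a 1:1:1 probe->canine-gene->human-gene mapping chain.
A configurable set of genes is planted differentially expressed in the
tumor, shifted by ``effect_size`` reference standard deviations so the
expected gene-level Z equals the configured effect; one planted drug's
evidence in every store is built concordant with those genes, amid decoy
drugs with random evidence.  :class:`PlantedTruth` records what a perfect
analysis should recover.

What this generator does *not* emulate: probe-level cross-hybridisation,
batch/chip spatial artifacts, correlated gene modules, or realistic
present-call structure — passing recovery tests therefore demonstrates
the pipeline's arithmetic and plumbing, not platform fidelity.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ProbeMatrix, ReferenceStats, compute_reference_stats
from .knowledge_base import (
    BiomarkerRule,
    Drug,
    DrugTargetEntry,
    KnowledgeBase,
    NetworkEdge,
    ResponseSignature,
    SensitivitySignature,
    save_knowledge_base,
)
from .ortholog_map import GeneProbeMap, HomologMap, ProbeGeneMap
from .qc_gate import PathologyQC, PathologyRead, RnaQC, SampleRecord

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticStudy",
    "generate_maps",
    "generate_reference_set",
    "generate_tumor_profile",
    "generate_knowledge_base",
    "generate_sample_record",
    "simulate_study",
    "write_study",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Effects are in reference-sd units, so the expected gene-level Z of a
    planted gene equals ``effect_size`` by construction.
    """

    seed: int = 0
    n_ref_samples: int = 5
    n_genes: int = 200
    min_probes_per_gene: int = 1
    max_probes_per_gene: int = 3
    baseline_meanlog: float = 6.0  # ln intensity units: median intensity ~ e^6
    baseline_sdlog: float = 1.0
    noise_sdlog: float = 0.15  # multiplicative sample noise
    n_planted_up: int = 20
    n_planted_down: int = 20
    effect_size: float = 4.0
    planted_drug_id: str = "d_planted"
    n_decoy_drugs: int = 9
    n_signature_instances: int = 2  # for the planted drug
    qc_fail_stage: str | None = None  # None => QC-clean record


@dataclass
class PlantedTruth:
    """Ground truth: the planted drug, its genes, and the expected methods."""

    drug_id: str
    up_genes: list[str]
    down_genes: list[str]
    expected_methods: list[str]
    evidence: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    cfg: SimulationConfig
    reference: ProbeMatrix
    tumor: ProbeMatrix  # single-sample matrix
    probe_gene: ProbeGeneMap
    homologs: HomologMap
    gene_probe: GeneProbeMap
    kb: KnowledgeBase
    truth: PlantedTruth
    sample_record: SampleRecord


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _human_genes(cfg: SimulationConfig) -> list[str]:
    return [f"hg{i:04d}" for i in range(cfg.n_genes)]


def _planted_sets(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    genes = _human_genes(cfg)
    rng = _rng(cfg, 1)
    picks = rng.choice(cfg.n_genes, size=cfg.n_planted_up + cfg.n_planted_down,
                       replace=False)
    up = sorted(genes[i] for i in picks[: cfg.n_planted_up])
    down = sorted(genes[i] for i in picks[cfg.n_planted_up:])
    return up, down


def generate_maps(cfg: SimulationConfig) -> tuple[ProbeGeneMap, HomologMap, GeneProbeMap]:
    """1:1:1 mapping chain with 1..max probes per gene on each platform."""
    rng = _rng(cfg, 2)
    probe_gene: dict[str, str] = {}
    gene_probe: dict[str, frozenset] = {}
    pairs = []
    for i in range(cfg.n_genes):
        cg, hg = f"cg{i:04d}", f"hg{i:04d}"
        pairs.append((cg, hg))
        k = int(rng.integers(cfg.min_probes_per_gene, cfg.max_probes_per_gene + 1))
        for j in range(k):
            probe_gene[f"cp{i:04d}_{j}"] = cg
        kh = int(rng.integers(cfg.min_probes_per_gene, cfg.max_probes_per_gene + 1))
        gene_probe[hg] = frozenset(f"hp{i:04d}_{j}" for j in range(kh))
    return probe_gene, frozenset(pairs), gene_probe


def _baselines(cfg: SimulationConfig, probe_ids: list[str]) -> np.ndarray:
    rng = _rng(cfg, 3)
    return np.exp(rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, len(probe_ids)))


def _calls(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    return rng.choice(np.array(["P", "M", "A"]), size=shape, p=[0.85, 0.05, 0.10])


def generate_reference_set(cfg: SimulationConfig) -> ProbeMatrix:
    """Reference matrix: i.i.d. log-normal noise around per-probe baselines."""
    if cfg.n_ref_samples < 2:
        raise ValueError("need at least 2 reference samples")
    if cfg.baseline_sdlog <= 0 or cfg.noise_sdlog <= 0:
        raise ValueError("degenerate distribution parameters")
    probe_gene, _, _ = generate_maps(cfg)
    probe_ids = sorted(probe_gene)
    base = _baselines(cfg, probe_ids)
    rng = _rng(cfg, 4)
    noise = rng.normal(0.0, cfg.noise_sdlog, (len(probe_ids), cfg.n_ref_samples))
    inten = base[:, None] * np.exp(noise)
    calls = _calls(rng, inten.shape)
    samples = [f"REF-{i + 1:02d}" for i in range(cfg.n_ref_samples)]
    return ProbeMatrix(probe_ids, samples, inten, calls, platform_tag="synthetic-canine")


def _truth(cfg: SimulationConfig) -> PlantedTruth:
    up, down = _planted_sets(cfg)
    return PlantedTruth(
        drug_id=cfg.planted_drug_id,
        up_genes=up,
        down_genes=down,
        expected_methods=[
            "biomarker_rules", "target_expression", "response_signature",
            "sensitivity_signature", "network_activity",
        ],
        evidence={
            "target_expression": up[:3],
            "biomarker_rules": up[:2],
            "sensitivity_signature": up[: min(10, len(up))],
            "network_activity": up[:1],
        },
    )


def generate_tumor_profile(
    cfg: SimulationConfig, ref_stats: ReferenceStats
) -> tuple[ProbeMatrix, PlantedTruth]:
    """One tumor sample with planted shifts of ``effect_size`` reference sds.

    Unplanted probes are drawn from the reference distribution; each probe
    of a planted gene is shifted by effect x that probe's reference sd
    (clipped at zero intensity).
    """
    truth = _truth(cfg)
    probe_gene, homologs, _ = generate_maps(cfg)
    human_of = dict(homologs)
    probe_ids = sorted(probe_gene)
    base = _baselines(cfg, probe_ids)
    rng = _rng(cfg, 5)
    x = base * np.exp(rng.normal(0.0, cfg.noise_sdlog, len(probe_ids)))
    up, down = set(truth.up_genes), set(truth.down_genes)
    sd = ref_stats.sd.reindex(probe_ids).to_numpy()
    for i, p in enumerate(probe_ids):
        hg = human_of.get(probe_gene[p])
        if hg in up:
            x[i] += cfg.effect_size * sd[i]
        elif hg in down:
            x[i] -= cfg.effect_size * sd[i]
    x = np.maximum(x, 0.0)
    calls = _calls(rng, (len(probe_ids), 1))
    tumor = ProbeMatrix(probe_ids, ["TUMOR-01"], x[:, None], calls,
                        platform_tag="synthetic-canine")
    return tumor, truth


def generate_knowledge_base(cfg: SimulationConfig) -> tuple[KnowledgeBase, PlantedTruth]:
    """Miniature KB: one drug per store concordant with the plant, plus decoys.

    Decoy evidence genes are drawn from the unplanted pool (disjoint from
    the planted set whenever the universe permits).
    """
    truth = _truth(cfg)
    genes = _human_genes(cfg)
    universe = frozenset(genes)
    planted = set(truth.up_genes) | set(truth.down_genes)
    pool = sorted(universe - planted) or genes
    rng = _rng(cfg, 6)

    drugs = {cfg.planted_drug_id: Drug(cfg.planted_drug_id, "Plantedib")}
    decoys = [f"d{i:02d}" for i in range(1, cfg.n_decoy_drugs + 1)]
    for d in decoys:
        drugs[d] = Drug(d, f"Decoyomab-{d[1:]}")

    targets = [
        DrugTargetEntry(cfg.planted_drug_id, g, "inhibits")
        for g in truth.evidence["target_expression"]
    ]
    for d in decoys:
        for g in rng.choice(pool, size=2, replace=False):
            targets.append(DrugTargetEntry(d, str(g), "inhibits"))

    rules = [
        BiomarkerRule(f"r_planted_{k}", g, "greater", 2.0, "indicate", cfg.planted_drug_id)
        for k, g in enumerate(truth.evidence["biomarker_rules"])
    ]
    for k, d in enumerate(decoys[:2]):
        rules.append(
            BiomarkerRule(f"r_decoy_{k}", str(rng.choice(pool)), "greater", 2.0,
                          "indicate", d)
        )

    # Planted response signatures: drug pushes the planted up-genes to the
    # bottom ranks and the planted down-genes to the top — a pure reversal.
    sigs = []
    if planted:
        for k in range(cfg.n_signature_instances):
            middle = [g for g in genes if g not in planted]
            rng.shuffle(middle)
            ranked = list(truth.down_genes) + middle + list(truth.up_genes)
            sigs.append(
                ResponseSignature(cfg.planted_drug_id, f"inst_planted_{k}", tuple(ranked))
            )
    shuffled = list(genes)
    rng.shuffle(shuffled)
    sigs.append(ResponseSignature(decoys[0], "inst_decoy_0", tuple(shuffled)))

    sens = []
    if len(truth.evidence["sensitivity_signature"]) >= 2:
        sens.append(
            SensitivitySignature(
                cfg.planted_drug_id,
                {g: +1 for g in truth.evidence["sensitivity_signature"]},
            )
        )
    for d in decoys[1:3]:
        picks = rng.choice(pool, size=5, replace=False)
        sens.append(SensitivitySignature(d, {str(g): int(s) for g, s in
                                             zip(picks, rng.choice([-1, 1], size=5))}))

    # Network: the planted drug's first target transcriptionally drives the
    # planted DEGs with concordant edge signs; one decoy target drives
    # unplanted (hence mostly non-DEG) genes.
    network = []
    if truth.evidence["network_activity"]:
        hub = truth.evidence["network_activity"][0]
        network += [NetworkEdge(hub, g, +1, True) for g in truth.up_genes[1:7]]
        network += [NetworkEdge(hub, g, -1, True) for g in truth.down_genes[:4]]
    decoy_hub = str(targets[len(truth.evidence["target_expression"])].target_gene)
    for g in rng.choice([g for g in pool if g != decoy_hub], size=5, replace=False):
        network.append(NetworkEdge(decoy_hub, str(g), +1, True))

    kb = KnowledgeBase(
        drugs=drugs, targets=targets, rules=rules, response_signatures=sigs,
        sensitivity_signatures=sens, network=network, gene_universe=universe,
    )
    kb.validate()
    return kb, truth


def generate_sample_record(cfg: SimulationConfig) -> SampleRecord:
    """A QC-clean record, or one failing at ``cfg.qc_fail_stage``."""
    rec = SampleRecord(
        subject_id=f"SIM-{cfg.seed:03d}",
        surgery_date=dt.date(2011, 6, 9),
        receipt_date=dt.date(2011, 6, 13),
        report_date=dt.date(2011, 6, 17),
        rna_vari=RnaQC(yield_ng=100.0, a260_280=2.0, rin=8.0),
        pathology=PathologyQC(reads=[PathologyRead(80, 15, 5), PathologyRead(80, 15, 5)]),
    )
    stage = cfg.qc_fail_stage
    if stage is None:
        return rec
    if stage == "shipping":
        rec.shipping_ok = False
    elif stage == "rna_vari":
        rec.rna_vari = RnaQC(yield_ng=100.0, a260_280=2.0, rin=5.0)
    elif stage == "pathology":
        rec.pathology = PathologyQC(no_tumor_flag=True)
    elif stage == "rna_crl":
        rec.rna_crl = RnaQC(yield_ng=100.0, a260_280=2.0, rin=5.5)
    elif stage == "cdna":
        from .qc_gate import CdnaQC

        rec.cdna = CdnaQC(yield_ug=2.0, a260_280=2.0)
    elif stage == "array":
        from .expression import ArrayQCMetrics

        rec.array = ArrayQCMetrics(120.0, 45.0, 2.0, True)
    else:
        raise ValueError(f"unknown QC failure stage {stage!r}")
    return rec


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate every input of one end-to-end run, deterministically from the seed."""
    probe_gene, homologs, gene_probe = generate_maps(cfg)
    reference = generate_reference_set(cfg)
    stats = compute_reference_stats(reference)
    tumor, truth = generate_tumor_profile(cfg, stats)
    kb, _ = generate_knowledge_base(cfg)
    record = generate_sample_record(cfg)
    return SyntheticStudy(cfg, reference, tumor, probe_gene, homologs, gene_probe,
                          kb, truth, record)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write all generated inputs as the pipeline's on-disk formats."""
    from .expression import write_pivot_table
    from .qc_gate import sample_record_to_dict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pivot_table(study.reference, outdir / "reference.tsv")
    write_pivot_table(study.tumor, outdir / "tumor.tsv")
    pd.DataFrame(sorted(study.probe_gene.items()),
                 columns=["probe_id", "canine_gene"]).to_csv(
        outdir / "probe_gene.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(study.homologs),
                 columns=["canine_gene", "human_gene"]).to_csv(
        outdir / "homologs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, p) for g, ps in sorted(study.gene_probe.items()) for p in sorted(ps)],
        columns=["human_gene", "human_probe"]).to_csv(
        outdir / "gene_probe.tsv", sep="\t", index=False)
    save_knowledge_base(study.kb, outdir / "kb")
    (outdir / "truth.json").write_text(json.dumps(asdict(study.truth), indent=1))
    (outdir / "sample_record.json").write_text(
        json.dumps(sample_record_to_dict(study.sample_record), indent=1))
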