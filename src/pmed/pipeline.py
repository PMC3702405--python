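"""End-to-end run: QC gate -> Z-score -> mapping -> five predictors -> report.

:func:`analyze_sample` is the in-memory pipeline; :func:`run_pipeline`
wraps it for file-driven runs from a YAML/JSON config naming the tumor
pivot table, the reference table, the mapping TSVs, the knowledge-base
directory and (optionally) the sample QC record and holiday list.  If the
QC gate fails, the report carries the decision and no predictions.  All
stochastic stages take the config seed, so two runs with the same config
render byte-identical JSON.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ensemble import rank_drugs, summate
from .expression import ProbeMatrix, compute_reference_stats, read_pivot_table, zscore_sample
from .knowledge_base import KnowledgeBase, load_knowledge_base
from .ortholog_map import (
    HomologMap,
    ProbeGeneMap,
    aggregate_to_genes,
    load_homolog_map,
    load_probe_gene_map,
    to_human_genes,
)
from .predictors import predict_all
from .qc_gate import (
    BusinessCalendar,
    SampleRecord,
    gate_sample,
    sample_record_from_dict,
    turnaround_days,
)
from .report import PMedReport

__all__ = ["PipelineConfig", "analyze_sample", "run_pipeline"]


@dataclass
class PipelineConfig:
    """File-driven pipeline configuration (all paths relative to ``root``)."""

    tumor_table: str
    reference_table: str
    probe_gene_map: str
    homolog_map: str
    kb_dir: str
    tumor_sample_id: str | None = None  # default: the single sample in tumor_table
    sample_record: str | None = None  # JSON file; omit to skip the QC gate
    holidays: list[str] = field(default_factory=list)
    seed: int = 0
    deg_threshold: float = 2.0
    deg_cap: int = 500
    target_threshold: float = 3.0
    network_alpha: float = 0.05
    n_perm: int = 1000
    log2_transform: bool = False
    root: str = "."

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("root", str(path.parent))
        return cls(**raw)


def analyze_sample(
    tumor: ProbeMatrix,
    reference: ProbeMatrix,
    probe_gene: ProbeGeneMap,
    homologs: HomologMap,
    kb: KnowledgeBase,
    tumor_sample_id: str | None = None,
    sample_record: SampleRecord | None = None,
    calendar: BusinessCalendar | None = None,
    seed: int = 0,
    deg_threshold: float = 2.0,
    deg_cap: int = 500,
    target_threshold: float = 3.0,
    network_alpha: float = 0.05,
    n_perm: int = 1000,
    log2_transform: bool = False,
) -> PMedReport:
    """Run the full analysis for one tumor sample and assemble the report."""
    if tumor_sample_id is None:
        if tumor.n_samples != 1:
            raise ValueError("tumor_sample_id required when the table has several samples")
        tumor_sample_id = tumor.sample_ids[0]
    subject = sample_record.subject_id if sample_record is not None else tumor_sample_id

    metadata = {
        "pmed_version": __version__,
        "seed": seed,
        "thresholds": {
            "deg_z": deg_threshold,
            "deg_cap": deg_cap,
            "target_z": target_threshold,
            "network_alpha": network_alpha,
        },
        "n_perm": n_perm,
        "log2_transform": log2_transform,
        "n_reference_samples": reference.n_samples,
    }
    metadata["config_hash"] = hashlib.sha256(
        json.dumps(metadata, sort_keys=True).encode()
    ).hexdigest()[:16]

    qc = None
    if sample_record is not None:
        qc = gate_sample(sample_record)
        if sample_record.receipt_date and sample_record.report_date:
            metadata["turnaround_business_days"] = turnaround_days(
                sample_record, calendar or BusinessCalendar()
            )
        if qc.status == "fail":
            return PMedReport(subject_id=subject, metadata=metadata, qc=qc)

    try:
        stats = compute_reference_stats(reference, log2_transform=log2_transform)
        z_probe = zscore_sample(tumor.column(tumor_sample_id), stats,
                                log2_transform=log2_transform)
        z_canine = aggregate_to_genes(z_probe, probe_gene)
        z_human = to_human_genes(z_canine, homologs)
    except Exception as exc:
        raise RuntimeError(f"expression/mapping stage failed: {exc}") from exc

    try:
        preds = predict_all(
            z_human, kb, seed=seed,
            deg_threshold=deg_threshold, deg_cap=deg_cap,
            target_threshold=target_threshold, network_alpha=network_alpha,
            n_perm=n_perm,
        )
        ranked, contra = rank_drugs(summate(preds))
    except Exception as exc:
        raise RuntimeError(f"prediction stage failed: {exc}") from exc

    return PMedReport(
        subject_id=subject,
        metadata=metadata,
        qc=qc,
        ranked=ranked,
        contraindicated=contra,
        predictions=sorted(preds, key=lambda p: (p.method.value, p.drug_id)),
        dropped_features={"human_gene": z_human.dropped_features},
    )


def run_pipeline(config: PipelineConfig | str | Path) -> PMedReport:
    """Load all inputs named by *config* and run :func:`analyze_sample`."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    root = Path(config.root)

    tumor = read_pivot_table(root / config.tumor_table)
    reference = read_pivot_table(root / config.reference_table)
    probe_gene = load_probe_gene_map(root / config.probe_gene_map)
    homologs = load_homolog_map(root / config.homolog_map)
    kb = load_knowledge_base(root / config.kb_dir)
    record = None
    if config.sample_record:
        with open(root / config.sample_record) as fh:
            record = sample_record_from_dict(json.load(fh))
    calendar = BusinessCalendar(
        frozenset(dt.date.fromisoformat(h) for h in config.holidays)
    )

    return analyze_sample(
        tumor, reference, probe_gene, homologs, kb,
        tumor_sample_id=config.tumor_sample_id,
        sample_record=record, calendar=calendar, seed=config.seed,
        deg_threshold=config.deg_threshold, deg_cap=config.deg_cap,
        target_threshold=config.target_threshold,
        network_alpha=config.network_alpha, n_perm=config.n_perm,
        log2_transform=config.log2_transform,
    )
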