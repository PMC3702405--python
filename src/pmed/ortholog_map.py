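"""Cross-species feature mapping: canine probes -> canine genes -> human genes.

Probe-level Z-scores are collapsed to canine genes by the arithmetic mean of
each gene's probes, then translated to human homologs under a strict
one-to-one rule: a canine gene is translated only when it participates in
exactly one homolog pair AND that pair's human gene likewise participates in
exactly one pair.  Everything else is dropped with reason "ambiguous
homology" — ambiguity is treated as data to audit, not to resolve.  An
optional final step replicates each human gene's Z to its human array probe
sets, for evidence stores keyed by probe id; downstream scoring defaults to
the human-gene level to avoid vote inflation from multi-probe genes.

All mapping tables are plain two-column TSV snapshots; no live database
access.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pandas as pd

from .expression import Level, ZProfile

__all__ = [
    "ProbeGeneMap",
    "HomologMap",
    "GeneProbeMap",
    "load_probe_gene_map",
    "load_homolog_map",
    "load_gene_probe_map",
    "aggregate_to_genes",
    "to_human_genes",
    "to_human_probes",
]

ProbeGeneMap = dict[str, str]  # probe_id -> canine_gene_id
HomologMap = frozenset  # of (canine_gene_id, human_gene_id) pairs
GeneProbeMap = dict[str, frozenset]  # human_gene_id -> set of human_probe_id


def load_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns probe_id<TAB>canine_gene")
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: probe {dupes.iloc[0]!r} maps to more than one gene")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_homolog_map(path: str | Path) -> HomologMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns canine_gene<TAB>human_gene")
    return frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_gene_probe_map(path: str | Path) -> GeneProbeMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns human_gene<TAB>human_probe")
    out: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    for g, p in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if p in seen and seen[p] != g:
            raise ValueError(f"{path}: probe {p!r} assigned to both {seen[p]!r} and {g!r}")
        seen[p] = g
        out.setdefault(g, set()).add(p)
    return {g: frozenset(ps) for g, ps in out.items()}


def _require_level(z: ZProfile, level: Level) -> None:
    if z.level is not Level(level):
        raise ValueError(f"expected a {Level(level).value}-level profile, got {z.level.value}")


def aggregate_to_genes(z: ZProfile, probe_gene: ProbeGeneMap) -> ZProfile:
    """Collapse a probe-level profile to canine genes by per-gene arithmetic mean.

    Probes without a mapping are dropped with a reason; drop reasons from the
    input are carried forward.
    """
    _require_level(z, Level.probe)
    sums: dict[str, float] = {}
    counts: Counter[str] = Counter()
    dropped = dict(z.dropped_features)
    for probe, value in z.values.items():
        gene = probe_gene.get(probe)
        if gene is None:
            dropped[probe] = "no probe-to-gene mapping"
            continue
        sums[gene] = sums.get(gene, 0.0) + value
        counts[gene] += 1
    values = {g: sums[g] / counts[g] for g in sums}
    return ZProfile(z.sample_id, Level.canine_gene, values, dropped)


def to_human_genes(z: ZProfile, homologs: HomologMap) -> ZProfile:
    """Translate canine genes to human homologs under the strict 1:1 rule.

    A gene is retained only if its homolog pair is unique in both directions;
    Z values are never altered by translation.
    """
    _require_level(z, Level.canine_gene)
    canine_degree = Counter(c for c, _ in homologs)
    human_degree = Counter(h for _, h in homologs)
    one_to_one = {
        c: h for c, h in homologs if canine_degree[c] == 1 and human_degree[h] == 1
    }
    values: dict[str, float] = {}
    dropped = dict(z.dropped_features)
    for gene, value in z.values.items():
        if gene in one_to_one:
            values[one_to_one[gene]] = value
        elif canine_degree[gene] == 0:
            dropped[gene] = "no human homolog"
        else:
            dropped[gene] = "ambiguous homology"
    return ZProfile(z.sample_id, Level.human_gene, values, dropped)


def to_human_probes(z: ZProfile, gene_probe: GeneProbeMap) -> ZProfile:
    """Replicate each human gene's Z to all of its human probe sets."""
    _require_level(z, Level.human_gene)
    values: dict[str, float] = {}
    dropped = dict(z.dropped_features)
    for gene, value in z.values.items():
        probes = gene_probe.get(gene)
        if not probes:
            dropped[gene] = "no human probe set"
            continue
        for p in probes:
            values[p] = value
    return ZProfile(z.sample_id, Level.human_probe, values, dropped)
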