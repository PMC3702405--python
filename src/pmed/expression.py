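"""Probe-level expression input, reference statistics and Z-scoring.

The pipeline's raw input is a MAS5-style tab-delimited pivot table: one row
per probe set, and per sample a signal column, a detection-call column
(P/M/A) and an optional detection p-value column.  A tumor sample is
expressed in Z units against a small normal-tissue reference set: for each
probe set the reference mean and sample standard deviation (n-1 denominator)
are compiled across the reference arrays, and the tumor intensity is mapped
to ``Z = (intensity - mean) / sd``.  Probes with zero reference variance
have no defined Z and are dropped with an auditable reason rather than
patched with a pseudo-variance.

Intensities are Z-scored on the scale received; ``log2_transform=True`` on
:func:`compute_reference_stats` / :func:`zscore_sample` applies log2(x+1)
first for users who prefer variance-stabilised statistics (default off).
Present calls are carried through but never filtered on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "ProbeMatrix",
    "ReferenceStats",
    "ZProfile",
    "ArrayQCMetrics",
    "PivotTableError",
    "read_pivot_table",
    "write_pivot_table",
    "compute_reference_stats",
    "zscore_sample",
    "array_qc",
]


class Level(str, enum.Enum):
    """Feature level of a Z-profile along the cross-species mapping chain."""

    probe = "probe"
    canine_gene = "canine_gene"
    human_gene = "human_gene"
    human_probe = "human_probe"


class PivotTableError(ValueError):
    pass


@dataclass
class ProbeMatrix:
    """Probe x sample intensity table with present calls."""

    probe_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray  # (n_probes, n_samples), float, >= 0
    present_calls: np.ndarray  # (n_probes, n_samples), '<U1' in {P, M, A}
    platform_tag: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.present_calls = np.asarray(self.present_calls, dtype="<U1")
        shape = (len(self.probe_ids), len(self.sample_ids))
        if self.intensities.shape != shape or self.present_calls.shape != shape:
            raise ValueError(
                f"inconsistent dimensions: {self.intensities.shape} vs {shape}"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> pd.Series:
        """Intensities of one sample, indexed by probe id."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.intensities[:, j], index=self.probe_ids, name=sample_id)


@dataclass
class ReferenceStats:
    """Per-probe mean and sample sd across a normal reference set."""

    mean: pd.Series
    sd: pd.Series
    n_ref: int


@dataclass
class ZProfile:
    """Per-feature Z-scores for one sample at a declared mapping level."""

    sample_id: str
    level: Level
    values: dict[str, float]
    dropped_features: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.level = Level(self.level)
        overlap = self.values.keys() & self.dropped_features.keys()
        if overlap:
            raise ValueError(f"features both valued and dropped: {sorted(overlap)[:5]}")
        bad = [f for f, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite Z for {bad[:5]}")


@dataclass
class ArrayQCMetrics:
    """Post-hybridisation chip-level quality metrics."""

    background: float | None = None
    percent_present: float | None = None
    scale_factor: float | None = None
    spike_order_ok: bool | None = None  # 3' signal bioB < bioC < bioD < cre


# ---------------------------------------------------------------------------
# Pivot-table I/O

_SIGNAL = " Signal"
_CALL = " Detection"
_PVAL = " Detection p-value"


def read_pivot_table(path: str | Path, platform_tag: str = "") -> ProbeMatrix:
    """Read a tab-delimited pivot table into a :class:`ProbeMatrix`.

    Expected header: a probe-id column first, then per sample
    ``<sample> Signal`` and ``<sample> Detection`` (optionally
    ``<sample> Detection p-value``); unknown extra columns are ignored.
    Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    probe_col = df.columns[0]
    samples = [c[: -len(_SIGNAL)] for c in df.columns if c.endswith(_SIGNAL)]
    if not samples:
        raise PivotTableError(f"{path}: no '<sample>{_SIGNAL}' columns found")
    for s in samples:
        if s + _CALL not in df.columns:
            raise PivotTableError(f"{path}: missing detection-call column for sample {s!r}")

    probe_ids = df[probe_col].tolist()
    dupes = df[probe_col][df[probe_col].duplicated()]
    if len(dupes):
        raise PivotTableError(f"{path}: duplicate probe id {dupes.iloc[0]!r}")

    inten = np.empty((len(df), len(samples)), dtype=float)
    calls = np.empty((len(df), len(samples)), dtype="<U1")
    for j, s in enumerate(samples):
        col = pd.to_numeric(df[s + _SIGNAL], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise PivotTableError(
                f"{path}: non-numeric intensity {df[s + _SIGNAL].iloc[i]!r} "
                f"at row {i + 2}, column {s + _SIGNAL!r}"
            )
        inten[:, j] = col.to_numpy()
        calls[:, j] = df[s + _CALL].str.strip().str.upper().str[:1].to_numpy()

    return ProbeMatrix(probe_ids, samples, inten, calls, platform_tag=platform_tag)


def write_pivot_table(m: ProbeMatrix, path: str | Path) -> None:
    """Write the tab-delimited pivot-table dialect read by :func:`read_pivot_table`."""
    out: dict[str, object] = {"probe_set_id": m.probe_ids}
    for j, s in enumerate(m.sample_ids):
        out[s + _SIGNAL] = [repr(float(v)) for v in m.intensities[:, j]]
        out[s + _CALL] = m.present_calls[:, j]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference statistics and Z-scoring


def compute_reference_stats(ref: ProbeMatrix, log2_transform: bool = False) -> ReferenceStats:
    """Per-probe mean and sample sd (n-1) across the reference samples."""
    if ref.n_samples < 2:
        raise ValueError(f"need >= 2 reference samples, got {ref.n_samples}")
    x = ref.intensities
    if log2_transform:
        x = np.log2(x + 1.0)
    mean = pd.Series(x.mean(axis=1), index=ref.probe_ids)
    sd = pd.Series(x.std(axis=1, ddof=1), index=ref.probe_ids)
    return ReferenceStats(mean=mean, sd=sd, n_ref=ref.n_samples)


def zscore_sample(
    tumor: pd.Series, stats: ReferenceStats, log2_transform: bool = False
) -> ZProfile:
    """Z-score one tumor sample against reference statistics.

    *tumor* is a probe-indexed intensity series (see
    :meth:`ProbeMatrix.column`).  Probes absent from *stats* or with zero
    reference sd are dropped with a reason; everything else gets
    ``Z = (x - mean) / sd``.
    """
    overlap = [p for p in tumor.index if p in stats.mean.index]
    if not overlap:
        raise ValueError("no probe overlap between tumor sample and reference stats")
    values: dict[str, float] = {}
    dropped: dict[str, str] = {}
    x = tumor.astype(float)
    if log2_transform:
        x = np.log2(x + 1.0)
    for p in tumor.index:
        if p not in stats.mean.index:
            dropped[p] = "absent from reference statistics"
            continue
        sd = stats.sd[p]
        if sd == 0:
            dropped[p] = "zero reference variance"
            continue
        values[p] = float((x[p] - stats.mean[p]) / sd)
    return ZProfile(sample_id=str(tumor.name), level=Level.probe,
                    values=values, dropped_features=dropped)


def array_qc(m: ArrayQCMetrics) -> tuple[bool, list[str]]:
    """Chip-level pass/fail: background < 100, percent present > 30,
    scale factor < 100, spike-in 3' order bioB < bioC < bioD < cre.

    A missing metric fails its criterion.  Returns (passed, failed-criteria).
    """
    failed: list[str] = []
    if m.background is None or not m.background < 100:
        failed.append("background")
    if m.percent_present is None or not m.percent_present > 30:
        failed.append("percent_present")
    if m.scale_factor is None or not m.scale_factor < 100:
        failed.append("scale_factor")
    if not m.spike_order_ok:
        failed.append("spike_order")
    return (not failed, failed)
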