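"""Simplified kinetic modification calling.

Per-position inter-pulse durations are compared to an in-silico reference by
a one-sided Welch's t-test (methylation slows the polymerase, elevating IPD);
the p-value is Phred-scaled into a modification QV and thresholded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io_formats import ModificationRecord, SequenceRecord

_P_FLOOR = 1e-300

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class IpdObservations:
    """IPD samples at one position/strand plus reference moments."""

    contig: str
    position: int
    strand: str
    sample_ipds: tuple[float, ...]
    ref_mean: float
    ref_sd: float
    ref_n: float

    def __post_init__(self) -> None:
        if len(self.sample_ipds) < 1:
            raise ValueError("at least one IPD observation required")
        if self.ref_sd < 0:
            raise ValueError("reference sd must be >= 0")


@dataclass(frozen=True)
class CallFilter:
    """QV / type / coverage filter applied to candidate calls."""

    min_qv: float = 30.0
    allowed_types: frozenset[str] = frozenset({"m6A", "m4C"})
    min_coverage: int = 0

    def __post_init__(self) -> None:
        if self.min_qv < 0:
            raise ValueError("min_qv must be >= 0")

    def accepts(self, record: ModificationRecord) -> bool:
        return (
            record.score >= self.min_qv
            and record.mod_type in self.allowed_types
            and record.coverage >= self.min_coverage
        )


def welch_test(obs: IpdObservations) -> tuple[float, float, float]:
    """One-sided Welch's t-test of sample mean > reference mean.

    Returns (t, Welch-Satterthwaite df, upper-tail p clamped to [1e-300, 1]).
    """
    x = np.asarray(obs.sample_ipds, dtype=float)
    n = len(x)
    mean = float(x.mean())
    s2 = float(x.var(ddof=1)) if n >= 2 else 0.0
    a = s2 / n
    b = (obs.ref_sd ** 2) / obs.ref_n
    if a == 0.0 and b == 0.0:
        if mean == obs.ref_mean:
            return 0.0, float("inf"), 1.0
        raise ValueError(
            "degenerate observation: zero variance on both sides with a "
            "mean shift (need n >= 2 with spread, or ref_sd > 0)"
        )
    se = math.sqrt(a + b)
    t = (mean - obs.ref_mean) / se
    # Welch-Satterthwaite; a zero-variance side contributes no df penalty
    denom = 0.0
    if a > 0.0:
        if n < 2:
            raise ValueError("sample variance undefined for n < 2")
        denom += a * a / (n - 1)
    if b > 0.0:
        denom += b * b / max(obs.ref_n - 1, 1.0)
    df = (a + b) ** 2 / denom if denom > 0 else float("inf")
    p = float(stats.t.sf(t, df)) if math.isfinite(df) else float(stats.norm.sf(t))
    return t, df, min(max(p, _P_FLOOR), 1.0)


def pvalue_to_qv(p: float) -> float:
    """Phred scale: QV = -10 log10(p). Rounded only when reported."""
    if p <= 0:
        raise ValueError("p-value must be > 0")
    return -10.0 * math.log10(p)


def qv_to_pvalue(qv: float) -> float:
    """Inverse Phred scale: p = 10^(-qv/10); qv_to_pvalue(30) == 0.001."""
    if qv < 0:
        raise ValueError("QV must be >= 0")
    return 10.0 ** (-qv / 10.0)


def _base_under_call(genome: SequenceRecord, position: int, strand: str) -> str:
    base = genome.sequence[position]
    return base if strand == "+" else _COMPLEMENT.get(base, "N")


def _context(genome: SequenceRecord, position: int, flank: int = 20) -> str:
    lo, hi = max(0, position - flank), min(len(genome), position + flank + 1)
    return genome.sequence[lo:hi]


def detect_modifications(
    observations: Iterable[IpdObservations],
    genome: SequenceRecord,
    call_filter: Optional[CallFilter] = None,
) -> list[ModificationRecord]:
    """Call modified positions from IPD observations and filter them.

    The modification type follows the genomic base under the call (A -> m6A,
    C -> m4C, otherwise modified_base); the reported score is the unrounded
    QV so the threshold never suffers rounding artifacts.
    """
    call_filter = call_filter or CallFilter()
    records = []
    for obs in observations:
        if not 0 <= obs.position < len(genome):
            raise ValueError(
                f"position {obs.position} outside genome {genome.id!r}"
            )
        _t, _df, p = welch_test(obs)
        qv = pvalue_to_qv(p)
        base = _base_under_call(genome, obs.position, obs.strand)
        mod_type = {"A": "m6A", "C": "m4C"}.get(base, "modified_base")
        mean = float(np.mean(obs.sample_ipds))
        record = ModificationRecord(
            contig=obs.contig,
            position=obs.position,
            strand=obs.strand,
            mod_type=mod_type,
            score=qv,
            ipd_ratio=mean / obs.ref_mean if obs.ref_mean > 0 else 0.0,
            coverage=len(obs.sample_ipds),
            context=_context(genome, obs.position),
        )
        if call_filter.accepts(record):
            records.append(record)
    return records


def filter_calls(
    records: Iterable[ModificationRecord],
    call_filter: Optional[CallFilter] = None,
) -> list[ModificationRecord]:
    """Keep calls with score >= min_qv, allowed type and sufficient coverage."""
    call_filter = call_filter or CallFilter()
    return [r for r in records if call_filter.accepts(r)]


def read_ipd_csv(path: Union[str, Path]) -> list[IpdObservations]:
    """Read IPD observations: contig,pos0,strand,ipds(;-separated),refMean,refSd,refN."""
    observations = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            observations.append(
                IpdObservations(
                    contig=row["contig"],
                    position=int(row["pos0"]),
                    strand=row["strand"],
                    sample_ipds=tuple(float(v) for v in row["ipds"].split(";")),
                    ref_mean=float(row["refMean"]),
                    ref_sd=float(row["refSd"]),
                    ref_n=float(row["refN"]),
                )
            )
    return observations
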