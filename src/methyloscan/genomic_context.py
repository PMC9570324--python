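"""Classify genome positions relative to ORFs and test promoter enrichment.

A position is a putative promoter site when it lies strictly less than
`promoter_window + 1` bp (default 1-99 bp) upstream of a start codon,
strand-aware; otherwise gene body when inside an ORF; otherwise intergenic.
Promoter takes precedence over gene body.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .io_formats import AnnotationRecord
from .motif_model import MotifOccurrence

PROMOTER = "promoter"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class ContextLabel:
    value: str
    nearest_feature_id: Optional[str] = None
    distance_to_start: Optional[int] = None  # negative = upstream


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows (unmethylated, reference), columns (promoter, gene body)."""

    unmeth_promoter: int
    unmeth_gene_body: int
    ref_promoter: int
    ref_gene_body: int

    def __post_init__(self) -> None:
        cells = self.as_list()
        if any(c < 0 for row in cells for c in row):
            raise ValueError("contingency counts must be non-negative")
        if sum(c for row in cells for c in row) == 0:
            raise ValueError("all-zero contingency table")

    def as_list(self) -> list[list[int]]:
        return [
            [self.unmeth_promoter, self.unmeth_gene_body],
            [self.ref_promoter, self.ref_gene_body],
        ]


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    alternative: str


class ContextIndex:
    """Per-contig interval index answering promoter/gene-body queries."""

    def __init__(self, annotations: Iterable[AnnotationRecord],
                 promoter_window: int = 99) -> None:
        self.promoter_window = promoter_window
        self._by_contig: dict[str, list[AnnotationRecord]] = {}
        for ann in annotations:
            self._by_contig.setdefault(ann.contig, []).append(ann)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for contig, anns in self._by_contig.items():
            anns.sort(key=lambda a: (a.start, a.end, a.feature_id))
            self._starts[contig] = [a.start for a in anns]
            self._max_len[contig] = max(a.end - a.start for a in anns)

    def _candidates(self, contig: str, pos: int) -> Iterable[AnnotationRecord]:
        anns = self._by_contig.get(contig, [])
        if not anns:
            return []
        starts = self._starts[contig]
        reach = self._max_len[contig] + self.promoter_window
        lo = bisect_right(starts, pos - reach)
        hi = bisect_right(starts, pos + self.promoter_window)
        return anns[lo:hi]

    def classify(self, contig: str, pos: int) -> ContextLabel:
        """Label one position; promoter > gene_body > intergenic precedence."""
        if pos < 0:
            raise ValueError(f"position {pos} outside contig {contig!r}")
        best_promoter: Optional[tuple[int, str]] = None  # (upstream distance, id)
        best_body: Optional[tuple[int, str, int]] = None  # (|dist to start|, id, signed)
        for ann in self._candidates(contig, pos):
            if ann.strand == "+":
                upstream = ann.start - pos  # 1..window means promoter
                signed_to_start = pos - ann.start
            else:
                upstream = pos - (ann.end - 1)
                signed_to_start = (ann.end - 1) - pos
            if 1 <= upstream <= self.promoter_window:
                cand = (upstream, ann.feature_id)
                if best_promoter is None or cand < best_promoter:
                    best_promoter = cand
            elif ann.start <= pos < ann.end:
                cand = (abs(signed_to_start), ann.feature_id, signed_to_start)
                if best_body is None or cand < best_body:
                    best_body = cand
        if best_promoter is not None:
            dist, fid = best_promoter
            return ContextLabel(PROMOTER, fid, -dist)
        if best_body is not None:
            _absd, fid, signed = best_body
            return ContextLabel(GENE_BODY, fid, signed)
        return ContextLabel(INTERGENIC)


def classify_position(contig: str, pos: int,
                      annotations: Iterable[AnnotationRecord],
                      promoter_window: int = 99) -> ContextLabel:
    return ContextIndex(annotations, promoter_window).classify(contig, pos)


def tabulate_contexts(
    occurrences: Sequence[MotifOccurrence],
    annotations: Iterable[AnnotationRecord],
    promoter_window: int = 99,
    index: Optional[ContextIndex] = None,
) -> dict[str, int]:
    """Category counts over occurrences; always a partition of the input."""
    index = index or ContextIndex(annotations, promoter_window)
    counts = Counter(
        index.classify(occ.contig, occ.methyl_pos).value for occ in occurrences
    )
    return {
        PROMOTER: counts.get(PROMOTER, 0),
        GENE_BODY: counts.get(GENE_BODY, 0),
        INTERGENIC: counts.get(INTERGENIC, 0),
    }


def fisher_exact(table: ContingencyTable,
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test (point-probability two-sided rule).

    Returns (p_value, odds_ratio) where the odds ratio is the sample
    (a*d)/(b*c), with infinity when b*c == 0 and a*d > 0, and 1 when both
    products vanish.
    """
    a, b = table.unmeth_promoter, table.unmeth_gene_body
    c, d = table.ref_promoter, table.ref_gene_body
    if a * d > 0 and b * c == 0:
        odds = math.inf
    elif b * c == 0:
        odds = 1.0
    else:
        odds = (a * d) / (b * c)
    result = stats.fisher_exact(table.as_list(), alternative=alternative)
    return float(result.pvalue), odds


def promoter_enrichment(
    unmethylated: Sequence[MotifOccurrence],
    all_occurrences: Sequence[MotifOccurrence],
    annotations: Iterable[AnnotationRecord],
    mode: str = "vs_all",
    promoter_window: int = 99,
    index: Optional[ContextIndex] = None,
) -> EnrichmentResult:
    """Two-sided Fisher test of promoter occupancy of unmethylated sites.

    The table uses promoter vs gene-body counts only (intergenic excluded).
    The reference set is all sites (default) or the methylated complement
    (mode="vs_methylated").
    """
    if not unmethylated:
        raise ValueError("empty unmethylated set")
    if mode not in ("vs_all", "vs_methylated"):
        raise ValueError(f"unknown mode {mode!r}")
    index = index or ContextIndex(annotations, promoter_window)
    if mode == "vs_methylated":
        unmeth_keys = {
            (o.contig, o.methyl_pos, o.strand) for o in unmethylated
        }
        reference = [
            o for o in all_occurrences
            if (o.contig, o.methyl_pos, o.strand) not in unmeth_keys
        ]
    else:
        reference = list(all_occurrences)
    u_counts = tabulate_contexts(unmethylated, (), index=index)
    r_counts = tabulate_contexts(reference, (), index=index)
    table = ContingencyTable(
        unmeth_promoter=u_counts[PROMOTER],
        unmeth_gene_body=u_counts[GENE_BODY],
        ref_promoter=r_counts[PROMOTER],
        ref_gene_body=r_counts[GENE_BODY],
    )
    p_value, odds = fisher_exact(table, "two-sided")
    return EnrichmentResult(table=table, odds_ratio=odds, p_value=p_value,
                            alternative="two-sided")
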