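"""Join modification calls to motif sites and summarize the methylome.

Produces per-motif summary rows (fraction / nDetected / nGenome / mean
score, IPD ratio, coverage / objective score), the complementary list of
unmethylated sites, and a greedy de-novo motif search over call contexts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .io_formats import ModificationRecord, SequenceRecord
from .motif_model import (
    MOD_TYPE_BASE,
    MotifOccurrence,
    MotifSpec,
    is_partner,
    reverse_complement,
    scan_motif,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding (the table convention), not banker's."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SiteState:
    """One motif site and whether a (filtered) call marks it methylated."""

    occurrence: MotifOccurrence
    methylated: bool
    call: Optional[ModificationRecord] = None

    def __post_init__(self) -> None:
        if self.methylated != (self.call is not None):
            raise ValueError("methylated must be true iff a call is attached")


@dataclass(frozen=True)
class MotifSummary:
    """One summary row; fraction kept unrounded, reported to 3 decimals."""

    motif: MotifSpec
    n_detected: int
    n_genome: int
    mean_score: Optional[float]
    mean_ipd_ratio: Optional[float]
    mean_coverage: Optional[float]
    objective_score: Optional[int]

    @property
    def fraction(self) -> float:
        return self.n_detected / self.n_genome

    @property
    def reported_fraction(self) -> float:
        return round_half_up(self.fraction, 3)


def _call_base(call: ModificationRecord, genome: Optional[SequenceRecord]) -> Optional[str]:
    if genome is not None and call.contig == genome.id:
        base = genome.sequence[call.position]
        return base if call.strand == "+" else _COMPLEMENT.get(base, "N")
    if call.context:
        return call.context[len(call.context) // 2]
    return None


def _compatible(call: ModificationRecord, motif: MotifSpec,
                genome: Optional[SequenceRecord]) -> bool:
    if call.mod_type == motif.mod_type:
        return True
    if call.mod_type == "modified_base":
        # subtype unresolved: accept when the underlying base matches
        base = _call_base(call, genome)
        return base is None or base == MOD_TYPE_BASE[motif.mod_type]
    return False


def assign_calls(
    occurrences: Sequence[MotifOccurrence],
    calls: Iterable[ModificationRecord],
    genome: Optional[SequenceRecord] = None,
) -> tuple[list[SiteState], list[ModificationRecord]]:
    """Mark each motif site methylated iff a type-compatible call sits on it.

    Calls are keyed by (contig, position, strand); duplicates keep the
    highest score with a warning.  Calls matching no occurrence are returned
    separately as off-motif calls.
    """
    by_key: dict[tuple[str, int, str], ModificationRecord] = {}
    for call in calls:
        key = (call.contig, call.position, call.strand)
        prev = by_key.get(key)
        if prev is not None:
            logger.warning("duplicate call at %s:%d%s, keeping highest score",
                           *key)
            if call.score <= prev.score:
                continue
        by_key[key] = call

    states = []
    used_keys = set()
    for occ in occurrences:
        key = (occ.contig, occ.methyl_pos, occ.strand)
        call = by_key.get(key)
        if call is not None and _compatible(call, occ.motif, genome):
            states.append(SiteState(occurrence=occ, methylated=True, call=call))
            used_keys.add(key)
        else:
            states.append(SiteState(occurrence=occ, methylated=False))
    off_motif = [c for k, c in by_key.items() if k not in used_keys]
    return states, off_motif


def summarize_motif(states: Sequence[SiteState]) -> MotifSummary:
    """Collapse the site states of one motif into a summary row.

    objective score = round(fraction x sum of detected scores), a heuristic
    stand-in for the sequencing pipeline's unpublished formula.
    """
    if not states:
        raise ValueError("cannot summarize a motif with no genomic sites")
    motifs = {st.occurrence.motif for st in states}
    if len(motifs) != 1:
        raise ValueError("states mix several motifs")
    motif = motifs.pop()
    n_genome = len(states)
    detected = [st for st in states if st.methylated]
    n_detected = len(detected)
    if n_detected == 0:
        return MotifSummary(motif, 0, n_genome, None, None, None, None)
    scores = [st.call.score for st in detected]
    fraction = n_detected / n_genome
    return MotifSummary(
        motif=motif,
        n_detected=n_detected,
        n_genome=n_genome,
        mean_score=sum(scores) / n_detected,
        mean_ipd_ratio=sum(st.call.ipd_ratio for st in detected) / n_detected,
        mean_coverage=sum(st.call.coverage for st in detected) / n_detected,
        objective_score=int(round(fraction * sum(scores))),
    )


def summary_from_counts(motif: MotifSpec, n_detected: int, n_genome: int) -> MotifSummary:
    """Summary row from bare counts (means unavailable)."""
    if not 0 <= n_detected <= n_genome or n_genome == 0:
        raise ValueError("need 0 <= nDetected <= nGenome, nGenome > 0")
    return MotifSummary(motif, n_detected, n_genome, None, None, None, None)


def find_unmethylated(states: Iterable[SiteState]) -> list[MotifOccurrence]:
    """The sites without a modification mark, sorted by position."""
    unmet = [st.occurrence for st in states if not st.methylated]
    unmet.sort(key=lambda o: (o.contig, o.methyl_pos, o.strand))
    return unmet


# ---------------------------------------------------------------------------
# De-novo motif discovery
# ---------------------------------------------------------------------------

_MAX_BIPARTITE_WORD = 5


def _context_window(genome: SequenceRecord, pos: int, strand: str,
                    flank: int) -> Optional[str]:
    """Sequence read 5'->3' on the call's strand, methylated base centered."""
    n = len(genome)
    if genome.circular:
        idx = [(pos + d) % n for d in range(-flank, flank + 1)]
        window = "".join(genome.sequence[i] for i in idx)
    else:
        if pos - flank < 0 or pos + flank + 1 > n:
            return None
        window = genome.sequence[pos - flank: pos + flank + 1]
    if strand == "-":
        window = reverse_complement(window)
    return window


def _candidate_patterns(window: str, flank: int, max_contiguous: int,
                        max_gap: int) -> Iterable[tuple[str, int]]:
    """(pattern, methyl offset) candidates anchored at the window center."""
    # contiguous words covering the anchor
    for k in range(2, max_contiguous + 1):
        for off in range(k):  # anchor sits at index `off` of the word
            start = flank - off
            word = window[start: start + k]
            if len(word) == k and "N" not in word:
                yield word, off
    # bipartite word1 - N{gap} - word2, anchor inside either word
    for l1 in range(1, _MAX_BIPARTITE_WORD + 1):
        for l2 in range(1, _MAX_BIPARTITE_WORD + 1):
            for gap in range(1, max_gap + 1):
                total = l1 + gap + l2
                # anchor in word1
                for off in range(l1):
                    start = flank - off
                    chunk = window[start: start + total]
                    if len(chunk) == total:
                        w1, w2 = chunk[:l1], chunk[l1 + gap:]
                        if "N" not in w1 + w2:
                            yield w1 + "N" * gap + w2, off
                # anchor in word2
                for off2 in range(l2):
                    start = flank - (l1 + gap + off2)
                    chunk = window[start: start + total]
                    if len(chunk) == total and start >= 0:
                        w1, w2 = chunk[:l1], chunk[l1 + gap:]
                        if "N" not in w1 + w2:
                            yield w1 + "N" * gap + w2, l1 + gap + off2


def _evaluate(pattern: str, offset: int, mod_type: str,
              genome: SequenceRecord,
              calls: Sequence[ModificationRecord]) -> Optional[tuple[MotifSpec, float, float, list[SiteState]]]:
    try:
        spec = MotifSpec(pattern, offset, mod_type)
    except ValueError:
        return None
    occs = scan_motif(genome, spec)
    if not occs:
        return None
    states, _off = assign_calls(occs, calls, genome)
    detected = [st for st in states if st.methylated]
    if not detected:
        return None
    fraction = len(detected) / len(states)
    objective = fraction * sum(st.call.score for st in detected)
    return spec, fraction, objective, states


def discover_motifs(
    calls: Sequence[ModificationRecord],
    genome: SequenceRecord,
    min_fraction: float = 0.5,
    max_contiguous_len: int = 8,
    max_gap: int = 9,
    flank: int = 20,
    shortlist_size: int = 60,
    min_support: int = 3,
) -> list[MotifSpec]:
    """Greedy de-novo motif search over the contexts of filtered calls.

    Each round counts candidate patterns (contiguous words and bipartite
    word-N{g}-word forms anchored at the methylated base) over the remaining
    calls, evaluates a support-ranked shortlist genome-wide, and accepts the
    candidate with the highest objective score whose methylated fraction
    reaches *min_fraction*; its calls are then removed and, for
    non-palindromic winners, the reverse-complement partner is tried next.
    Ties break toward shorter, then lexicographically smaller patterns.
    """
    remaining = list(calls)
    found: list[MotifSpec] = []
    while remaining:
        support: Counter[tuple[str, int, str]] = Counter()
        for call in remaining:
            window = _context_window(genome, call.position, call.strand, flank)
            if window is None:
                continue
            seen = set()
            for pattern, offset in _candidate_patterns(
                window, flank, max_contiguous_len, max_gap
            ):
                base = pattern[offset]
                mod_type = {"A": "m6A", "C": "m4C"}.get(base)
                if mod_type is None:
                    continue
                if call.mod_type not in ("modified_base", mod_type):
                    continue
                key = (pattern, offset, mod_type)
                if key not in seen:
                    seen.add(key)
                    support[key] += 1

        ranked = [
            (cnt, key) for key, cnt in support.items() if cnt >= min_support
        ]
        ranked.sort(key=lambda item: (-item[0], len(item[1][0]), item[1][0]))
        best = None  # (objective, len, pattern, spec, states)
        for _cnt, (pattern, offset, mod_type) in ranked[:shortlist_size]:
            result = _evaluate(pattern, offset, mod_type, genome, remaining)
            if result is None:
                continue
            spec, fraction, objective, states = result
            if fraction < min_fraction:
                continue
            key = (-objective, len(pattern), pattern)
            if best is None or key < best[0]:
                best = (key, spec, states)
        if best is None:
            break

        _key, spec, states = best
        remaining = _remove_explained(remaining, states)
        rc = reverse_complement(spec.iupac)
        if rc != spec.iupac:
            partner = _find_partner(spec, genome, remaining, min_fraction)
            if partner is not None:
                spec = MotifSpec(spec.iupac, spec.methyl_offset, spec.mod_type,
                                 partner_iupac=partner.iupac)
                _p_occs = scan_motif(genome, partner)
                p_states, _ = assign_calls(_p_occs, remaining, genome)
                remaining = _remove_explained(remaining, p_states)
                found.append(spec)
                found.append(partner)
                continue
        found.append(spec)
    return found


def _remove_explained(calls: Sequence[ModificationRecord],
                      states: Sequence[SiteState]) -> list[ModificationRecord]:
    explained = {
        (st.call.contig, st.call.position, st.call.strand)
        for st in states if st.methylated
    }
    return [c for c in calls if (c.contig, c.position, c.strand) not in explained]


def _find_partner(spec: MotifSpec, genome: SequenceRecord,
                  calls: Sequence[ModificationRecord],
                  min_fraction: float) -> Optional[MotifSpec]:
    """Best-supported methyl offset for the reverse-complement pattern."""
    rc = reverse_complement(spec.iupac)
    best = None
    for mod_type, base in MOD_TYPE_BASE.items():
        for offset, code in enumerate(rc):
            if code != base:
                continue
            result = _evaluate(rc, offset, mod_type, genome, calls)
            if result is None:
                continue
            cand, fraction, objective, _states = result
            if fraction < min_fraction:
                continue
            if best is None or objective > best[0]:
                best = (objective, cand)
    if best is None:
        return None
    winner = best[1]
    assert is_partner(spec, winner)
    return MotifSpec(winner.iupac, winner.methyl_offset, winner.mod_type,
                     partner_iupac=spec.iupac)
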