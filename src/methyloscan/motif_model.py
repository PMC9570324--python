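"""IUPAC motif representation and strand-aware genome scanning.

A motif is an IUPAC string plus the 0-based offset of the methylatable base
within it.  Scanning enumerates per-strand sites: a palindromic motif such as
GATC therefore yields two sites per duplex locus, matching the convention of
strand-specific modification calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .io_formats import SequenceRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

MOD_TYPE_BASE = {"m6A": "A", "m4C": "C"}


def reverse_complement(seq: str) -> str:
    """Reverse-complement a (possibly degenerate) IUPAC string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"unknown IUPAC letter {exc.args[0]!r}") from None


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every window base lies in the degeneracy set of the pattern code.

    Genome letters outside {A,C,G,T} (e.g. N) never match any pattern code:
    a modification call cannot sit on an ambiguous base.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, w in zip(pattern.upper(), window.upper()):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"unknown IUPAC letter {p!r}") from None
        if w not in allowed:
            return False
    return True


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC motif with the 0-based offset of its methylated base."""

    iupac: str
    methyl_offset: int
    mod_type: str  # m6A or m4C
    partner_iupac: Optional[str] = None

    def __post_init__(self) -> None:
        iupac = self.iupac.upper()
        object.__setattr__(self, "iupac", iupac)
        if len(iupac) < 2:
            raise ValueError("motif length must be >= 2")
        unknown = set(iupac) - set(IUPAC_SETS)
        if unknown:
            raise ValueError(f"unknown IUPAC letters {sorted(unknown)}")
        if not 0 <= self.methyl_offset < len(iupac):
            raise ValueError("methyl_offset out of range")
        if self.mod_type not in MOD_TYPE_BASE:
            raise ValueError(f"mod_type must be m6A or m4C, got {self.mod_type!r}")
        base = MOD_TYPE_BASE[self.mod_type]
        if base not in IUPAC_SETS[iupac[self.methyl_offset]]:
            raise ValueError(
                f"base {iupac[self.methyl_offset]!r} at offset {self.methyl_offset} "
                f"is not compatible with {self.mod_type}"
            )

    @property
    def methyl_base(self) -> str:
        return MOD_TYPE_BASE[self.mod_type]

    @classmethod
    def parse(cls, text: str) -> "MotifSpec":
        """Parse the CLI syntax IUPAC:methylOffset:modType, e.g. GATC:1:m6A."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected IUPAC:offset:modType, got {text!r}")
        return cls(parts[0], int(parts[1]), parts[2])


@dataclass(frozen=True, order=True)
class MotifOccurrence:
    """One strand-aware match of a motif, in + strand coordinates."""

    contig: str = field(compare=False)
    methyl_pos: int
    strand: str
    match_start: int = field(compare=False)
    motif: MotifSpec = field(compare=False)


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    # Character classes list concrete bases only, so genome N matches nothing.
    parts = []
    for code in pattern:
        bases = sorted(IUPAC_SETS[code])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def _scan_one_strand(seq: str, pattern: str, circular: bool) -> Iterator[int]:
    """Yield 0-based match starts of an IUPAC pattern on a + strand sequence."""
    n, L = len(seq), len(pattern)
    if L > n:
        return
    search_space = seq + seq[: L - 1] if circular else seq
    rx = _iupac_regex(pattern)
    for m in rx.finditer(search_space):
        if m.start() < n:  # origin-spanning windows counted once
            yield m.start()


def scan_motif(genome: SequenceRecord, motif: MotifSpec) -> list[MotifOccurrence]:
    """Enumerate all per-strand occurrences of a motif on a genome.

    A + occurrence starting at s places the methylatable base at
    s + methyl_offset; a - occurrence (the motif matches the reverse
    complement of the window) places it at s + L - 1 - methyl_offset.
    Circular genomes are scanned across the origin without double counting.
    Output is sorted by (methyl_pos, strand).
    """
    seq = genome.sequence
    n, L = len(seq), len(motif.iupac)
    occs: list[MotifOccurrence] = []
    for s in _scan_one_strand(seq, motif.iupac, genome.circular):
        occs.append(
            MotifOccurrence(
                contig=genome.id,
                strand="+",
                match_start=s,
                methyl_pos=(s + motif.methyl_offset) % n,
                motif=motif,
            )
        )
    rc = reverse_complement(motif.iupac)
    for s in _scan_one_strand(seq, rc, genome.circular):
        occs.append(
            MotifOccurrence(
                contig=genome.id,
                strand="-",
                match_start=s,
                methyl_pos=(s + L - 1 - motif.methyl_offset) % n,
                motif=motif,
            )
        )
    occs.sort(key=lambda o: (o.methyl_pos, o.strand))
    return occs


def is_partner(a: MotifSpec, b: MotifSpec) -> bool:
    """Partner motifs mark the two strands of one duplex recognition site."""
    return reverse_complement(a.iupac) == b.iupac


def scan_motifs(
    genome: SequenceRecord, motifs: Sequence[MotifSpec]
) -> dict[MotifSpec, list[MotifOccurrence]]:
    return {m: scan_motif(genome, m) for m in motifs}
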