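"""In-silico methylation-sensitive restriction digestion and amplicon logic.

MboI cuts only fully unmethylated GATC duplexes, DpnI only fully methylated
ones, Bsp143I cuts regardless of methylation state; hemimethylated sites are
refractory to both MboI and DpnI.  An amplicon is detected iff no cut falls
strictly between the primers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

ENZYMES = ("none", "MboI", "DpnI", "Bsp143I")


@dataclass(frozen=True)
class GatcSiteState:
    """Duplex methylation state of one GATC site (position of the G)."""

    position: int
    plus_methylated: bool
    minus_methylated: bool

    @property
    def fully_methylated(self) -> bool:
        return self.plus_methylated and self.minus_methylated

    @property
    def fully_unmethylated(self) -> bool:
        return not (self.plus_methylated or self.minus_methylated)


@dataclass(frozen=True)
class DigestOutcome:
    enzyme: str
    cut_positions: tuple[int, ...]
    amplicon_present: bool


def digest(sites: Iterable[GatcSiteState], enzyme: str) -> list[int]:
    """Sorted cut positions for one enzyme over a set of GATC duplex states."""
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {ENZYMES}")
    if enzyme == "none":
        return []
    if enzyme == "Bsp143I":
        cut = lambda s: True
    elif enzyme == "MboI":
        cut = lambda s: s.fully_unmethylated
    else:  # DpnI
        cut = lambda s: s.fully_methylated
    return sorted(s.position for s in sites if cut(s))


def predict_amplicon(forward_primer_end: int, reverse_primer_start: int,
                     cuts: Sequence[int]) -> bool:
    """Amplicon present iff no cut lies strictly between the primers."""
    if forward_primer_end >= reverse_primer_start:
        raise ValueError("forward primer must end before the reverse primer starts")
    return not any(forward_primer_end < c < reverse_primer_start for c in cuts)


def msre_panel(sites: Sequence[GatcSiteState], forward_primer_end: int,
               reverse_primer_start: int) -> dict[str, DigestOutcome]:
    """Amplicon truth table across the four-enzyme panel."""
    panel = {}
    for enzyme in ENZYMES:
        cuts = digest(sites, enzyme)
        panel[enzyme] = DigestOutcome(
            enzyme=enzyme,
            cut_positions=tuple(cuts),
            amplicon_present=predict_amplicon(
                forward_primer_end, reverse_primer_start, cuts
            ),
        )
    return panel
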