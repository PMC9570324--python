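"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open; the 1-based conventions of
GFF are converted here and nowhere else.  Modification scores are Phred QVs
taken as reported, never recomputed on read.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ALLOWED_LETTERS = frozenset("ACGTN")
MOD_TYPES = frozenset({"m6A", "m4C", "modified_base"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A genome sequence; circularity controls origin-spanning motif scans."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - _ALLOWED_LETTERS
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise FormatError(
                f"sequence {self.id!r}: illegal letter {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """A genome feature in 0-based half-open coordinates."""

    feature_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: undefined strand")


@dataclass(frozen=True)
class ModificationRecord:
    """One per-strand, per-base modification call."""

    contig: str
    position: int  # 0-based
    strand: str
    mod_type: str
    score: float  # Phred QV, as reported
    ipd_ratio: float
    coverage: int
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"unknown modification type {self.mod_type!r}")
        if self.score < 0 or self.ipd_ratio < 0 or self.coverage < 1:
            raise ValueError(
                f"invalid call at {self.contig}:{self.position}: "
                f"score={self.score}, ipdRatio={self.ipd_ratio}, "
                f"coverage={self.coverage}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read FASTA; a ``circular=true`` token in the header marks circularity."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = any(
            tok.lower() == "circular=true" for tok in rec.description.split()
        )
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description="circular=true" if r.circular else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 annotations
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_annotations(
    path: Union[str, Path],
    keep_types: Iterable[str] = ("CDS", "gene"),
) -> list[AnnotationRecord]:
    """Read GFF3 features, converting to 0-based half-open coordinates.

    Features whose type is not in *keep_types* are dropped; kept features with
    strand "." are rejected with a warning.  featureId comes from the ID
    attribute, else ``contig:start-end``.
    """
    keep = set(keep_types)
    records = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            contig, _source, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if ftype not in keep:
                continue
            start, end = int(start1) - 1, int(end1)
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start > end")
            if strand not in ("+", "-"):
                logger.warning("%s:%d: kept feature with undefined strand, rejected",
                               path, lineno)
                n_rejected += 1
                continue
            feature_id = _parse_gff_attributes(attrs).get(
                "ID", f"{contig}:{start}-{end}"
            )
            records.append(
                AnnotationRecord(
                    feature_id=feature_id, contig=contig, start=start, end=end,
                    strand=strand, feature_type=ftype,
                )
            )
    return records


def write_gff3_annotations(
    records: Iterable[AnnotationRecord], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{r.contig}\tmethyloscan\t{r.feature_type}\t{r.start + 1}\t{r.end}"
                f"\t.\t{r.strand}\t.\tID={r.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# Modification calls (PacBio modifications.gff dialect + CSV twin)
# ---------------------------------------------------------------------------

_CSV_HEADER = ["contig", "pos0", "strand", "type", "score", "ipdRatio", "coverage"]


def read_modifications(path: Union[str, Path]) -> list[ModificationRecord]:
    """Read per-base modification calls from GFF dialect or the CSV twin.

    Dispatches on extension (.csv) and falls back to content sniffing.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_modifications_csv(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("contig,"):
        return _read_modifications_csv(path)
    return read_modifications_gff(path)


def read_modifications_gff(path: Union[str, Path]) -> list[ModificationRecord]:
    """Read the PacBio modifications.gff dialect.

    Column 4 is the 1-based position of the modified base (start == end),
    column 6 the Phred QV; coverage/context/IPDRatio live in the attributes.
    Records missing IPDRatio or coverage are rejected with a warning.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, mod_type, start1, _end1, score, strand, _phase, attr_text = fields
            if mod_type not in MOD_TYPES:
                logger.warning("%s:%d: unknown call type %r, rejected",
                               path, lineno, mod_type)
                continue
            attrs = _parse_gff_attributes(attr_text)
            if "coverage" not in attrs or "IPDRatio" not in attrs:
                logger.warning("%s:%d: missing coverage/IPDRatio attribute, rejected",
                               path, lineno)
                continue
            records.append(
                ModificationRecord(
                    contig=contig,
                    position=int(start1) - 1,
                    strand=strand,
                    mod_type=mod_type,
                    score=float(score),
                    ipd_ratio=float(attrs["IPDRatio"]),
                    coverage=int(attrs["coverage"]),
                    context=attrs.get("context"),
                )
            )
    if not records:
        raise FormatError(f"{path}: no parsable modification records")
    return records


def _read_modifications_csv(path: Union[str, Path]) -> list[ModificationRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing CSV columns {sorted(missing)}")
        for row in reader:
            if row["type"] not in MOD_TYPES:
                logger.warning("%s: unknown call type %r, rejected", path, row["type"])
                continue
            records.append(
                ModificationRecord(
                    contig=row["contig"],
                    position=int(row["pos0"]),
                    strand=row["strand"],
                    mod_type=row["type"],
                    score=float(row["score"]),
                    ipd_ratio=float(row["ipdRatio"]),
                    coverage=int(row["coverage"]),
                    context=row.get("context") or None,
                )
            )
    if not records:
        raise FormatError(f"{path}: no parsable modification records")
    return records


def write_modifications_gff(
    records: Iterable[ModificationRecord], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = [f"coverage={r.coverage}"]
            if r.context:
                attrs.append(f"context={r.context}")
            attrs.append(f"IPDRatio={r.ipd_ratio:.3f}")
            fh.write(
                f"{r.contig}\t.\t{r.mod_type}\t{r.position + 1}\t{r.position + 1}"
                f"\t{r.score:g}\t{r.strand}\t.\t{';'.join(attrs)}\n"
            )


def write_modifications_csv(
    records: Iterable[ModificationRecord], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER + ["context"])
        for r in records:
            writer.writerow(
                [r.contig, r.position, r.strand, r.mod_type, f"{r.score:g}",
                 f"{r.ipd_ratio:g}", r.coverage, r.context or ""]
            )


# ---------------------------------------------------------------------------
# Result writers: summary CSV, BED6, newick
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "Motif", "Fraction", "nDetected", "nGenome",
    "Mean Score", "Mean Ipd Ratio", "Mean Coverage", "Objective Score",
]


def write_summary_csv(summaries: Sequence, path: Union[str, Path]) -> None:
    """Write motif summaries with the canonical 8-column header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for s in summaries:
            writer.writerow(
                [
                    s.motif.iupac,
                    f"{s.reported_fraction:.3f}",
                    s.n_detected,
                    s.n_genome,
                    "" if s.mean_score is None else f"{s.mean_score:.1f}",
                    "" if s.mean_ipd_ratio is None else f"{s.mean_ipd_ratio:.2f}",
                    "" if s.mean_coverage is None else f"{s.mean_coverage:.1f}",
                    "" if s.objective_score is None else s.objective_score,
                ]
            )


def write_bed6(states: Iterable, path: Union[str, Path]) -> None:
    """Write site states as BED6; unscored (uncalled) sites get score 0."""
    with open(path, "w") as fh:
        for st in states:
            occ = st.occurrence
            score = 0 if st.call is None else min(int(round(st.call.score)), 1000)
            fh.write(
                f"{occ.contig}\t{occ.methyl_pos}\t{occ.methyl_pos + 1}"
                f"\t{occ.motif.iupac}\t{score}\t{occ.strand}\n"
            )


def write_newick(tree, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_outputs(
    summaries: Sequence,
    states: Iterable,
    tree,
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write the standard result bundle; any component may be None."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if summaries is not None:
        p = out_dir / "motif_summary.csv"
        write_summary_csv(summaries, p)
        written["summary"] = p
    if states is not None:
        p = out_dir / "sites.bed"
        write_bed6(states, p)
        written["bed"] = p
    if tree is not None:
        p = out_dir / "tree.nwk"
        write_newick(tree, p)
        written["tree"] = p
    return written
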