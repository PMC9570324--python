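"""Synthetic genomes, annotations and methylomes with full ground truth.

The generator emulates the statistical structure the analysis assumes: a
bacterial genome with natural motif occurrences, tiled ORFs with intergenic
gaps, near-complete motif methylation (fraction f) with Phred-scaled QVs,
IPD ratios and coverages, and a controllable excess (odds weight theta) of
unmethylated sites inside promoter windows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .genomic_context import ContextIndex
from .io_formats import (
    AnnotationRecord,
    ModificationRecord,
    SequenceRecord,
    write_fasta,
    write_gff3_annotations,
    write_modifications_gff,
)
from .motif_model import MotifOccurrence, MotifSpec, scan_motif

_SUB_QV_RANGE = (5.0, 29.5)  # sub-threshold calls at unmethylated sites


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 200_000
    gc_content: float = 0.44
    circular: bool = True
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (600, 1200)
    intergenic_gap_range: tuple[int, int] = (100, 400)
    motifs: tuple[tuple[MotifSpec, float], ...] = (
        (MotifSpec("GATC", 1, "m6A"), 0.998),
    )
    promoter_unmeth_weight: float = 1.0  # theta
    score_dist: tuple[float, float] = (95.6, 15.0)
    ipd_dist: tuple[float, float] = (5.52, 1.0)
    coverage_dist: tuple[float, float] = (56.9, 10.0)
    sub_threshold_call_prob: float = 0.5
    promoter_window: int = 99
    seed: int = 0
    contig_id: str = "sim1"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.promoter_unmeth_weight < 0:
            raise ValueError("theta must be >= 0")
        for _motif, f in self.motifs:
            if not 0.0 < f <= 1.0:
                raise ValueError("methylation fraction must lie in (0, 1]")


def paper_like_config(seed: int = 0, genome_length: int = 2_000_000) -> SimConfig:
    """Preset mirroring the published Dam methylome scale (f=0.998,
    score ~95.6, IPD ~5.52, coverage ~56.9)."""
    return SimConfig(
        genome_length=genome_length,
        n_genes=max(1, genome_length // 1300),
        seed=seed,
    )


@dataclass
class GroundTruthSite:
    occurrence: MotifOccurrence
    methylated: bool
    context: str  # promoter / gene_body / intergenic


@dataclass
class GroundTruth:
    motifs: list[MotifSpec]
    sites: dict[str, list[GroundTruthSite]]  # keyed by motif IUPAC

    def unmethylated_positions(self, iupac: str) -> list[tuple[int, str]]:
        return [
            (s.occurrence.methyl_pos, s.occurrence.strand)
            for s in self.sites[iupac]
            if not s.methylated
        ]


def _rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage generators derived from the single seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n)]


def generate_genome(config: SimConfig) -> SequenceRecord:
    """I.i.d. bases at the configured GC content, deterministic under seed."""
    rng = _rngs(config, 3)[0]
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=config.genome_length, p=p)
    return SequenceRecord(
        id=config.contig_id, sequence="".join(bases), circular=config.circular
    )


def generate_annotations(config: SimConfig,
                         genome: SequenceRecord) -> list[AnnotationRecord]:
    """Tile non-overlapping ORFs separated by intergenic gaps.

    The first gene starts beyond the promoter window so every gene has a
    well-defined upstream region.
    """
    rng = _rngs(config, 3)[1]
    records = []
    pos = config.promoter_window + 1
    lo_g, hi_g = config.gene_length_range
    lo_i, hi_i = config.intergenic_gap_range
    for k in range(config.n_genes):
        gap = int(rng.integers(lo_i, hi_i + 1)) if k > 0 else 0
        length = int(rng.integers(lo_g, hi_g + 1))
        start = pos + gap
        end = start + length
        if end > len(genome):
            raise ValueError(
                f"gene layout infeasible: gene {k} would end at {end} "
                f"> genome length {len(genome)}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            AnnotationRecord(
                feature_id=f"gene{k + 1:05d}", contig=genome.id,
                start=start, end=end, strand=strand, feature_type="CDS",
            )
        )
        pos = end
    return records


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Efraimidis-Spirakis keys: take the k largest u^(1/w)."""
    if k == 0:
        return np.array([], dtype=int)
    u = rng.random(len(weights))
    with np.errstate(divide="ignore"):
        keys = np.where(weights > 0, u ** (1.0 / np.maximum(weights, 1e-300)), -1.0)
    return np.argpartition(keys, -k)[-k:]


def generate_methylome(
    config: SimConfig,
    genome: SequenceRecord,
    annotations: Sequence[AnnotationRecord],
    context_index: Optional[ContextIndex] = None,
) -> tuple[list[ModificationRecord], GroundTruth]:
    """Draw per-site methylation states and emit modification calls.

    For each motif the u ~ round((1-f) * nGenome) unmethylated sites are
    sampled without replacement with weight theta for promoter-context sites
    and 1 otherwise.  Methylated sites emit a call with QV floored at 30;
    unmethylated sites emit a sub-threshold call with probability
    *sub_threshold_call_prob*, else nothing.
    """
    rng = _rngs(config, 3)[2]
    index = context_index or ContextIndex(annotations, config.promoter_window)
    records: list[ModificationRecord] = []
    truth = GroundTruth(motifs=[m for m, _f in config.motifs], sites={})
    score_mu, score_sd = config.score_dist
    ipd_mu, ipd_sd = config.ipd_dist
    cov_mu, cov_sd = config.coverage_dist

    for motif, f in config.motifs:
        occs = scan_motif(genome, motif)
        if not occs:
            raise ValueError(f"motif {motif.iupac} does not occur in the genome")
        n = len(occs)
        u = round((1.0 - f) * n)
        if u > n:
            raise ValueError("unmethylated count exceeds site count")
        contexts = [index.classify(o.contig, o.methyl_pos).value for o in occs]
        weights = np.where(
            np.array(contexts) == "promoter", config.promoter_unmeth_weight, 1.0
        )
        unmeth_idx = set(
            _weighted_sample_without_replacement(rng, weights, u).tolist()
        )
        site_truth = []
        for i, occ in enumerate(occs):
            methylated = i not in unmeth_idx
            site_truth.append(
                GroundTruthSite(occurrence=occ, methylated=methylated,
                                context=contexts[i])
            )
            if methylated:
                qv = float(rng.normal(score_mu, score_sd))
                if qv < 30.0:
                    qv = 30.0 + float(rng.random())  # floor with jitter
                ipd = max(1.01, float(rng.normal(ipd_mu, ipd_sd)))
                cov = max(1, int(round(rng.normal(cov_mu, cov_sd))))
            elif rng.random() < config.sub_threshold_call_prob:
                qv = float(rng.uniform(*_SUB_QV_RANGE))
                ipd = max(1.01, float(rng.normal(1.8, 0.4)))
                cov = max(1, int(round(rng.normal(cov_mu, cov_sd))))
            else:
                continue
            records.append(
                ModificationRecord(
                    contig=occ.contig, position=occ.methyl_pos, strand=occ.strand,
                    mod_type=motif.mod_type, score=qv, ipd_ratio=ipd,
                    coverage=cov,
                )
            )
        truth.sites[motif.iupac] = site_truth
    records.sort(key=lambda r: (r.contig, r.position, r.strand))
    return records, truth


def make_fixture(config: SimConfig, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write genome.fasta, annotations.gff3, modifications.gff and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    annotations = generate_annotations(config, genome)
    calls, truth = generate_methylome(config, genome, annotations)

    paths = {
        "genome": out_dir / "genome.fasta",
        "annotations": out_dir / "annotations.gff3",
        "modifications": out_dir / "modifications.gff",
        "truth": out_dir / "truth.json",
    }
    write_fasta([genome], paths["genome"])
    write_gff3_annotations(annotations, paths["annotations"])
    write_modifications_gff(calls, paths["modifications"])
    truth_json = {
        "motifs": [
            {"iupac": m.iupac, "methylOffset": m.methyl_offset,
             "modType": m.mod_type}
            for m in truth.motifs
        ],
        "sites": {
            iupac: [
                {"pos": s.occurrence.methyl_pos, "strand": s.occurrence.strand,
                 "methylated": s.methylated, "context": s.context}
                for s in sites
            ]
            for iupac, sites in truth.sites.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return paths
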