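from dataclasses import replace

import pytest

from methyloscan.genomic_context import ContextIndex
from methyloscan.kinetics import filter_calls
from methyloscan.methylome_summary import assign_calls
from methyloscan.motif_model import MotifSpec, scan_motif
from methyloscan.synthetic_data import (
    SimConfig,
    generate_annotations,
    generate_genome,
    generate_methylome,
)

GATC = MotifSpec("GATC", 1, "m6A")


@pytest.fixture(scope="session")
def dam_sim():
    """A small Dam-like methylome (200 kb, f=0.998) with ground truth."""
    config = SimConfig(seed=1)
    genome = generate_genome(config)
    annotations = generate_annotations(config, genome)
    calls, truth = generate_methylome(config, genome, annotations)
    occurrences = scan_motif(genome, GATC)
    states, off_motif = assign_calls(occurrences, filter_calls(calls), genome)
    return {
        "config": config,
        "genome": genome,
        "annotations": annotations,
        "calls": calls,
        "truth": truth,
        "occurrences": occurrences,
        "states": states,
        "off_motif": off_motif,
    }


@pytest.fixture(scope="session")
def enrichment_base():
    """Shared 500 kb genome/annotation for enrichment simulations.

    Per-seed methylomes are drawn on top of this via generate_methylome with
    a replaced seed, so power/calibration loops stay cheap.
    """
    base = SimConfig(seed=42, genome_length=500_000, n_genes=380)
    genome = generate_genome(base)
    annotations = generate_annotations(base, genome)
    occurrences = scan_motif(genome, GATC)
    index = ContextIndex(annotations)
    f_for_77 = 1.0 - 77 / len(occurrences)

    def draw(seed: int, theta: float):
        config = replace(
            base,
            seed=seed,
            promoter_unmeth_weight=theta,
            motifs=((GATC, f_for_77),),
        )
        return generate_methylome(config, genome, annotations,
                                  context_index=index)

    return {
        "config": base,
        "genome": genome,
        "annotations": annotations,
        "occurrences": occurrences,
        "index": index,
        "draw": draw,
    }
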