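"""Shared fixtures: small deterministic simulations built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hicscaf import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """2 chromosomes x 1 Mbp, 40 kbp contigs, 50k distance-decay pairs."""
    genome = sd.make_genome(n_chrom=2, chrom_length=1_000_000, seed=101)
    contigs, truth, asm_graph = sd.fragment(genome, contig_size=40_000)
    pairs = sd.simulate_hic(truth, n_pairs=50_000, decay_alpha=1.0, seed=102)
    return {
        "genome": genome,
        "contigs": contigs,
        "truth": truth,
        "asm_graph": asm_graph,
        "pairs": pairs,
        "contig_lengths": {c.id: c.length for c in contigs},
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
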