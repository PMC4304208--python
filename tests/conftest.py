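"""Shared fixtures: deterministic random sequences and a small simulated run."""

import numpy as np
import pytest

from polystr import (
    RunConfig,
    SimConfig,
    make_pedigree,
    run_pipeline,
    simulate,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)


@pytest.fixture(scope="session")
def small_sim():
    """Noise-free 6-gene, 18-locus two-trio dataset."""
    config = SimConfig(n_genes=6, loci_per_gene=3, seed=7,
                       snp_rate=0.0, indel_rate=0.0, n_mask_rate=0.0)
    reference, genomes = simulate(config)
    return config, reference, genomes


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full pipeline result over the small noise-free dataset."""
    _, reference, genomes = small_sim
    result = run_pipeline(
        reference.sequences, reference.transcripts, genomes,
        make_pedigree(), RunConfig(excluded_chromosomes=()))
    return reference, genomes, result
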