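"""Shared fixtures: one small synthetic dataset generated once per session."""

from __future__ import annotations

import pytest

from teloepi import read_assembly
from teloepi.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact scenario: two 12-kb chromosomes, 160-bp telomeric arrays,
    modest coverage; fast enough to regenerate freely."""
    return SimulationConfig(
        seed=11,
        n_contigs=2,
        contig_length=12_000,
        telomere_copies=20,
        read_depth=60,
        read_length_mean=3_000,
        n_motif_sites=12,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """(config, truth, directory) for the generated small dataset."""
    outdir = tmp_path_factory.mktemp("sim")
    truth = simulate_all(small_config, outdir)
    return small_config, truth, outdir


@pytest.fixture(scope="session")
def small_contigs(small_dataset):
    _, _, outdir = small_dataset
    return read_assembly(outdir / "genome.fasta")
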