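"""Shared fixtures: synthetic genomes generated once per session."""

from __future__ import annotations

import pytest

from minimt import SimulationConfig, generate_genome
from minimt import fixtures as fx


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic genome (Pa partition), seed 1."""
    return generate_genome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def ancestral_sim():
    """Synthetic genome on the reconstructed ancestral arrangement, seed 1."""
    cfg = SimulationConfig(seed=1,
                           gene_partition=dict(fx.ancestral_catalog().entries))
    return generate_genome(cfg, species="ancestor")


@pytest.fixture(scope="session")
def pa_catalog():
    return fx.pa_catalog()


@pytest.fixture(scope="session")
def ps_catalog():
    return fx.ps_catalog()
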