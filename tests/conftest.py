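"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pytest

from minichrom import SimConfig, simulate_dataset
from minichrom.workflow import junction_survey


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale simulated study: ~360 kb, 48 breakage sites."""
    cfg = SimConfig(seed=11, n_contigs=6, mean_contig_length=60_000, n_cbs=48)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_survey(small_sim):
    """Junction survey of the small study (all scaffolds, incl. EMCs)."""
    return junction_survey(small_sim.mic, small_sim.mac.scaffolds_24hpm)


def _junction_config(seed: int, flank_model: str) -> SimConfig:
    """10,000 breakage junctions on a lean genome (no IESs or genes)."""
    return SimConfig(
        seed=seed,
        n_contigs=5,
        mean_contig_length=880_000,
        n_cbs=10_000,
        ies_per_section_mean=0.0,
        emc_gene_rates={},
        mds_genes_per_section=0.0,
        flank_model=flank_model,
    )


@pytest.fixture(scope="session")
def junction_sim_10k():
    """Measured junctions for 10,000 sites with independent 5'/3' flank losses."""
    data = simulate_dataset(_junction_config(101, "independent"))
    survey = junction_survey(data.mic, data.mac.scaffolds_24hpm)
    return data, survey


@pytest.fixture(scope="session")
def gap_sim_10k():
    """Measured junctions for 10,000 sites with total-gap-distributed losses."""
    data = simulate_dataset(_junction_config(102, "total_gap"))
    survey = junction_survey(data.mic, data.mac.scaffolds_24hpm)
    return data, survey


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
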