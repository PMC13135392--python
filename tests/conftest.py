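import numpy as np
import pytest

from regshift.synthetic import (SimulationConfig, ap1_motif, generate_genome,
                                generate_contribution_tracks)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=42, n_chrom=2, chrom_length=20_000,
                            n_cells_per_group=50)


@pytest.fixture(scope="session")
def planted_world(small_config):
    """Genome + contribution tracks with 40 planted AP-1 seqlets, 10 differential."""
    genome, truth = generate_genome(small_config, [ap1_motif()], 40)
    tracks, peaks, truth = generate_contribution_tracks(
        genome, truth, small_config, differential_fraction=0.25, delta=2.0)
    return {"genome": genome, "truth": truth, "tracks": tracks, "peaks": peaks}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
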