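import numpy as np
import pytest

from egrnkit import SimConfig, simulate_multiome


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale dataset used by most unit tests: 2 programs, 120+120 nuclei."""
    return SimConfig(
        n_rna_nuclei=120,
        n_atac_nuclei=120,
        n_genes=60,
        n_peaks=240,
        n_tf_programs=2,
        targets_per_tf=4,
        enhancers_per_target=2,
        n_clusters=4,
        decoy_motifs=10,
        chrom_length=60_000_000,
        window_half_width=100_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_multiome(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
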