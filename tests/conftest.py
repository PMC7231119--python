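import numpy as np
import pytest

from bulkseg import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact experiment: one 2 Mb chromosome, causal locus at 1 Mb."""
    return SimConfig(
        n_chromosomes=1, chrom_length_bp=2_000_000, marker_density=50,
        causal_chrom="chr1", causal_pos=1_000_000,
        population_size=300, bulk_size=30, mean_depth=30,
        base_error_rate=0.001, seed=42,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
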