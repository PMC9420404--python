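import numpy as np
import pytest

from poolscan.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by read-only tests."""
    cfg = SimConfig(
        n_scaffolds=3,
        scaffold_length=500_000,
        seed=42,
        sweep_regions=[("scaf1", 100_000, 200_000)],
        balancing_regions=[("scaf2", 300_000, 400_000)],
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
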