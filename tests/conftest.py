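import numpy as np
import pytest

from clichunter import ContactMap, SimulationConfig, simulate_contact_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_map(rng):
    """Small symmetric positive random contact map (no structure)."""
    raw = rng.uniform(0.1, 1.0, size=(30, 30))
    return ContactMap("chr1", 40_000, (raw + raw.T) / 2)


@pytest.fixture
def decay_map():
    """Seeded 50-bin power-law map without plaid structure."""
    cfg = SimulationConfig(
        n_bins=50, compartment_contrast=1.0, noise_dispersion=0.3, seed=7
    )
    return simulate_contact_map(cfg)


@pytest.fixture
def plaid_map_noiseless():
    """Two-compartment plaid with decay and no noise (deterministic)."""
    cfg = SimulationConfig(
        n_bins=40,
        compartment_block_len=10,
        compartment_contrast=2.0,
        noise_dispersion=0.0,
        seed=0,
    )
    return simulate_contact_map(cfg)
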