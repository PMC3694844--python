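import pytest

from methylpair.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small paired study with spiked sites, shared across tests."""
    config = SimulationConfig(
        n_subjects=12,
        n_probes=3000,
        n_true_dms=300,
        delta_range=(0.02, 0.11),
        n_genes=400,
        seed=42,
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def null_study():
    """A no-spike, single-batch study for calibration checks."""
    config = SimulationConfig(
        n_subjects=12,
        n_probes=3000,
        n_true_dms=0,
        n_batches=1,
        batch_shift_sd=0.0,
        n_genes=400,
        seed=7,
    )
    return simulate_study(config)
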