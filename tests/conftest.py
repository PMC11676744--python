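import numpy as np
import pytest

from cyclopure import (
    ERMS_DESIGN,
    IR_DESIGN,
    ErmsSimConfig,
    IrSimConfig,
    MixtureDesign,
    simulate_erms_dataset,
    simulate_ir_dataset,
)


@pytest.fixture
def noiseless_erms_config():
    return ErmsSimConfig(noise_sd_rel=0.0, seed=0)


@pytest.fixture
def voltage_grid(noiseless_erms_config):
    return np.array(noiseless_erms_config.voltage_grid)


@pytest.fixture
def small_ir_config():
    """A reduced IR simulation (coarse grid, few raw spectra) for fast tests."""
    return IrSimConfig(
        wavenumber_grid=tuple(np.linspace(675.0, 4000.0, 400)),
        raw_spectra_per_replicate=10,
        seed=0,
    )


@pytest.fixture
def default_ir_dataset(small_ir_config):
    return simulate_ir_dataset(small_ir_config, IR_DESIGN)


@pytest.fixture
def noiseless_erms_samples(noiseless_erms_config):
    return simulate_erms_dataset(noiseless_erms_config, ERMS_DESIGN)


@pytest.fixture
def low_range_design():
    """The 6-level x 3-replicate design of the low-ratio calibration, with
    the two pure standards that supply the reference curves."""
    return MixtureDesign(ratios=(0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 1.0), replicates=3)
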