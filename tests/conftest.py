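import numpy as np
import pytest

from trunksyn import SyntheticSpec, TimeSeriesTable, make_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """A fast, small-but-complete synthetic study (2 sides, 3 DoFs)."""
    return SyntheticSpec(k_true=3, n_leg_musc=6, n_trunk_musc=6, n_pt=41,
                         n_cycles=2, activation_noise_sd=0.0,
                         moment_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return make_dataset(tiny_spec)


@pytest.fixture(scope="session")
def noisy_dataset():
    return make_dataset(SyntheticSpec(k_true=3, n_leg_musc=6,
                                      n_trunk_musc=6, n_pt=41, n_cycles=3,
                                      seed=11))


@pytest.fixture
def ramp_table() -> TimeSeriesTable:
    t = np.linspace(0.0, 1.0, 11)
    data = np.column_stack([2.0 * t + 1.0, np.ones_like(t)])
    return TimeSeriesTable(t, data, ["ramp", "const"])
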