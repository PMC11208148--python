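import pytest

import diazosym as dz
from diazosym.pipeline import cell_rates, partition_table


@pytest.fixture(scope="session")
def labeling():
    return dz.LabelingConfig()


@pytest.fixture(scope="session")
def fixed_run():
    """Noise-free fixed-geometry simulation at documented defaults."""
    return dz.generate(dz.SimConfig(fixed_geometry=True, noise="none", seed=1))


@pytest.fixture(scope="session")
def fixed_partition(fixed_run, labeling):
    return partition_table(fixed_run.roi, labeling)


@pytest.fixture(scope="session")
def noisy_run():
    """Stochastic run: sampled geometry, Poisson ion-count noise."""
    return dz.generate(dz.SimConfig(n_symbioses=200, noise="poisson", seed=7))


@pytest.fixture(scope="session")
def noisy_cell_rates(noisy_run, labeling):
    return cell_rates(noisy_run.roi, labeling)
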