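import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pigdamage import ModelSpec, SimulationConfig, reml_fit, simulate_dataset


def small_config(**kw) -> SimulationConfig:
    """A two-line population small enough for dense oracles."""
    base = dict(n_lines=2, n_farms=4, sires_per_generation=4,
                dams_per_generation=12, generations=3, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_ds():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_fit(small_ds):
    vc, fit = reml_fit(small_ds.phenotypes, ModelSpec(traits=["ear"]),
                       small_ds.pedigree)
    return vc, fit


@pytest.fixture(scope="session")
def medium_ds():
    """One mid-sized population for validation-level tests."""
    return simulate_dataset(small_config(
        sires_per_generation=10, dams_per_generation=70, seed=23))
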