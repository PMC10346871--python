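import numpy as np
import pytest

from covidsa import SynthSpec, WrapperFitness, generate_synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """8-feature, 3-class instance small enough for exhaustive mask search."""
    ds, truth = generate_synthetic(
        SynthSpec(n_classes=3, n_per_class=30, n_informative=3,
                  n_redundant=2, n_noise=3, seed=42)
    )
    return ds, truth


@pytest.fixture()
def small_fitness(small_dataset):
    ds, _ = small_dataset
    return WrapperFitness(ds)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
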