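import numpy as np
import pytest

from ppsi import DataMatrix, FitConfig, GeneratorParams, fit, simulate_dataset


@pytest.fixture(scope="session")
def easy_params():
    """A well-separated 2-subtype, 2nd-order generator setting."""
    return GeneratorParams(
        n_polynomials=10,
        n_subtypes=2,
        dimensions=2,
        record_count=300,
        noise_min=0.2,
        noise_max=0.4,
        subtype_class_imbalance_index=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def easy_dataset(easy_params):
    data, truth = simulate_dataset(easy_params)
    return data, truth


@pytest.fixture(scope="session")
def fitted_model(easy_dataset):
    data, _ = easy_dataset
    return fit(data, FitConfig(D=2, S=2, seed=0, iterations=1200))


@pytest.fixture()
def tiny_data():
    rng = np.random.default_rng(0)
    return DataMatrix(
        X=rng.normal(size=(8, 3)),
        feature_names=["a", "b", "c"],
        zscored=True,
    )
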