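import numpy as np
import pytest

import setsig as sg
from setsig.synthetic import SyntheticSpec, generate_collection, generate_datasets


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        p=300, n_samples=80, n_sets=30, n_informative_sets=5,
        set_size_range=(5, 15), rho=0.6, delta=1.5, n_datasets=2,
        batch_shift_sd=0.3, missing_frac=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    """Two small labelled cohorts plus their mapped collection and truth."""
    rng = np.random.default_rng(small_spec.seed)
    coll, informative = generate_collection(small_spec, rng)
    datasets, truth = generate_datasets(small_spec, coll, informative)
    mapped, _ = sg.map_collection(coll, datasets[0], min_set_size=2)
    return datasets, mapped, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
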