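import numpy as np
import pytest

import coloboot as cb


@pytest.fixture(scope="session")
def study_dataset():
    """Default-sized synthetic study (56 farms x 6), prepared for modelling."""
    cfg = cb.SimulationConfig(seed=1)
    ds, _ = cb.prepare(cb.generate_dataset(cfg))
    return ds


@pytest.fixture(scope="session")
def small_dataset():
    """Small study for fast model tests (20 farms x 4)."""
    cfg = cb.SimulationConfig(
        n_farms=20, samples_per_farm=4,
        true_effects={"teat_dry_wiped:Yes": 2.0}, seed=7,
    )
    ds, _ = cb.prepare(cb.generate_dataset(cfg))
    return ds


def random_instance(rng, n_max=60, p=3):
    """One random small mixed-model instance: intercept + (p-1) covariates,
    3-8 farms, true farm effects and noise."""
    n = int(rng.integers(12, n_max + 1))
    G = int(rng.integers(3, 9))
    farm = rng.integers(0, G, size=n)
    # guarantee >= 2 distinct farms
    farm[0], farm[1] = 0, 1
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    beta = rng.normal(size=p)
    u = rng.normal(0, 1.0, size=G)
    y = X @ beta + u[farm] + rng.normal(0, 1.0, size=n)
    return y, X, farm
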