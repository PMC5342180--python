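import warnings

import numpy as np
import pandas as pd
import pytest

from pugmark import AlgorithmConfig, PopulationSpec, generate_population
from pugmark.synthetic import TEMPLATE
from pugmark.morphometry import LandmarkSet, calibrate, derive_points


@pytest.fixture(scope="session")
def small_population():
    """8 individuals, separated regime; shared across tests (read-only)."""
    spec = PopulationSpec(n_individuals=8, seed=101, prints_per_trail=(4, 6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sets, table = generate_population(spec)
    return spec, sets, table


@pytest.fixture(scope="session")
def null_population():
    """Exchangeable animals: no individual signal, no dimorphism."""
    spec = PopulationSpec(
        n_individuals=8,
        sigma_individual=0.0,
        male_scale=1.0,
        shape_shift=0.0,
        seed=202,
        prints_per_trail=(5, 7),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sets, table = generate_population(spec)
    return spec, sets, table


@pytest.fixture(scope="session")
def default_config():
    return AlgorithmConfig()


@pytest.fixture(scope="session")
def small_matrices(small_population, default_config):
    """Pairwise distance/verdict matrices for the small population."""
    from pugmark import pairwise_matrix

    _, _, table = small_population
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pairwise_matrix(table, default_config)


@pytest.fixture(scope="session")
def small_truth(small_population):
    _, _, table = small_population
    return table.drop_duplicates("trail_id").set_index("trail_id")["animal_id"]


@pytest.fixture
def template_landmarks():
    """A calibrated, derived landmark set at the exact template geometry."""
    ls = LandmarkSet(
        footprint_id="fp1",
        trail_id="t1",
        landmarks=TEMPLATE.copy(),
        scale_points=np.array([(0.0, 0.0), (10.0, 0.0)]),
        scale_separation_mm=10.0,
        calibrated=True,
    )
    return derive_points(ls)


def jitter_landmarks(rng, scale=2.0):
    """A random valid 25-point configuration near the template."""
    return TEMPLATE + rng.standard_normal(TEMPLATE.shape) * scale
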