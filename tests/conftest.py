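"""Shared synthetic populations (session-scoped: generation is the slow part)."""

import numpy as np
import pytest

from ctnet.interactions import chromosome_pairs, matrices_from_records
from ctnet.morphometry import MeasurementTable
from ctnet.nullmodels import NullConfig, simulate_random_population
from ctnet.synthetic import PopulationSpec, default_spec, plant_and_grow_population

#: the standard planted-network benchmark: five elevated pairs over background
BENCH_PLANTED = [(1, 17), (4, 12), (11, 16), (1, 18), (12, 17)]


def bench_spec(n_nuclei: int, seed: int) -> PopulationSpec:
    probs = {p: 0.1 for p in chromosome_pairs()}
    for p in BENCH_PLANTED:
        probs[p] = 0.6
    return PopulationSpec(
        n_nuclei=n_nuclei,
        condition="benchmark",
        pair_probabilities=probs,
        homolog_probability=0.05,
        seed=seed,
    )


@pytest.fixture(scope="session")
def g1_population():
    """Default fibroblast-G1 condition, 50 nuclei."""
    return plant_and_grow_population(default_spec("WI38", "G1", n_nuclei=50, seed=11))


@pytest.fixture(scope="session")
def g1_tables(g1_population):
    return [MeasurementTable.measure(r) for r in g1_population]


@pytest.fixture(scope="session")
def g1_matrices(g1_population, g1_tables):
    from ctnet.interactions import call_interactions

    return [call_interactions(t) for t in g1_tables]


@pytest.fixture(scope="session")
def random_twin(g1_population):
    """Random-placement twin of the G1 population (same nuclei and volumes)."""
    return simulate_random_population(NullConfig(g1_population, seed=9))


@pytest.fixture(scope="session")
def random_twin_matrices(random_twin):
    return matrices_from_records(random_twin)


@pytest.fixture(scope="session")
def sparse_population():
    """Sparse-interaction population where radial placement dominates (n=100)."""
    spec = default_spec(
        "WI38", "G1", n_nuclei=100, seed=7,
        pair_probabilities={p: 0.1 for p in chromosome_pairs()},
    )
    return plant_and_grow_population(spec)


@pytest.fixture(scope="session")
def sparse_tables(sparse_population):
    return [MeasurementTable.measure(r) for r in sparse_population]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
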