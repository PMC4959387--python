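import numpy as np
import pytest

from nnimpute import DataMatrix, PopulationSpec, compute_truth, generate_population

POP_SIZE = 250_000  # scaled-down stand-in for the benchmark population
POP_SEED = 11
NOISE_SEED = 97


@pytest.fixture(scope="session")
def population():
    """One shared synthetic population for every statistical test."""
    return generate_population(PopulationSpec(noise_seed=NOISE_SEED), POP_SIZE, POP_SEED)


@pytest.fixture(scope="session")
def truth(population):
    return compute_truth(population)


@pytest.fixture
def toy_table():
    """Three complete donors and one recipient with B missing.

    Donors (A, B): (1, 10), (2, 20), (10, 50); recipient A = 1.5.
    With Euclidean distance on A the donor order is rows 0, 1, 2.
    """
    values = np.array(
        [[1.0, 10.0], [2.0, 20.0], [10.0, 50.0], [1.5, np.nan]]
    )
    mask = ~np.isnan(values)
    return DataMatrix(values, mask, ["A", "B"])


def make_random_table(rng, n_rows, n_cols):
    """Complete random table used by brute-force oracle checks."""
    values = rng.normal(0, 1, size=(n_rows, n_cols)) * rng.uniform(
        0.5, 20, size=n_cols
    )
    return DataMatrix(values, np.ones_like(values, dtype=bool), [f"c{i}" for i in range(n_cols)])
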