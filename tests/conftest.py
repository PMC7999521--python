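import numpy as np
import pandas as pd
import pytest

from enterotyper import (
    AbundanceTable,
    default_config,
    generate_cohort,
    jsd_matrix,
    normalize_relative,
)


@pytest.fixture
def toy_counts() -> AbundanceTable:
    df = pd.DataFrame(
        [[10, 5, 0], [2, 2, 6], [0, 1, 9]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return AbundanceTable(df, "counts")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=105, 3 components), shared per session."""
    return generate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def default_cohort_distance(default_cohort):
    table, _, _ = default_cohort
    return jsd_matrix(normalize_relative(table))


def random_probability_vectors(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Strictly positive probability vectors (rows)."""
    v = rng.gamma(1.0, 1.0, size=(n, k)) + 1e-12
    return v / v.sum(axis=1, keepdims=True)
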