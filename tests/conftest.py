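import numpy as np
import pandas as pd
import pytest

from coda_age import CountTable
from coda_age.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """12 samples x 20 OTUs, two groups, with metadata and taxonomy."""
    table, truth = make_fixture("tiny")
    return table, truth


@pytest.fixture(scope="session")
def tiny_table(tiny):
    return tiny[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_table():
    """Deterministic 4x5 count table with zeros, no metadata."""
    counts = pd.DataFrame(
        [
            [0, 5, 5, 10, 0],
            [1, 2, 3, 4, 5],
            [10, 0, 0, 0, 10],
            [3, 3, 3, 3, 3],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"o{i}" for i in range(5)],
    )
    return CountTable(counts)


def make_counts(rng, n_samples, n_otus, depth=1000):
    """Random multinomial count table around a shared log-normal base."""
    base = rng.lognormal(0, 2.0, size=n_otus)
    p = base / base.sum()
    counts = rng.multinomial(depth, p, size=n_samples)
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"o{j}" for j in range(n_otus)],
        )
    )
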