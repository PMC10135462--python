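import numpy as np
import pandas as pd
import pytest

from cerna_forge import generate_cohort
from cerna_forge.io_prep import make_sample_table


@pytest.fixture(scope="session")
def small_bundle():
    """A compact cohort with planted modules, DE features and triplets."""
    return generate_cohort(
        10, 10, 300, 4, 30, 40, 1.5, 0.5, 2, 0.8, seed=11, n_triplets=6
    )


@pytest.fixture(scope="session")
def de_bundle():
    """Cohort tuned for differential-expression checks (single batch)."""
    return generate_cohort(
        8, 8, 120, 0, 0, 20, 1.5, 0.5, 1, 0.0, seed=3, n_triplets=0, with_tables=False
    )


@pytest.fixture()
def two_group_table():
    def make(n_control, n_case, batches=None):
        ids = [f"c{i}" for i in range(n_control)] + [f"p{i}" for i in range(n_case)]
        groups = ["control"] * n_control + ["case"] * n_case
        return make_sample_table(ids, groups, batches)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_expression(rng, n_genes, n_samples, prefix="G"):
    vals = rng.normal(7.0, 1.0, size=(n_genes, n_samples))
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
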