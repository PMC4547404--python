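import numpy as np
import pandas as pd
import pytest

from hubprior.io_formats import ExpressionMatrix, SampleGroups
from hubprior.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic study (300 genes, 20+20 samples, 6 planted hubs)."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced fixture for fast file-based tests."""
    return generate_fixture(
        FixtureSpec(
            n_genes=120,
            n_samples_per_group=10,
            n_planted_hubs=3,
            planted_min_degree=8,
            seed=7,
        )
    )


def expr_from_array(arr, gene_ids=None, sample_ids=None):
    arr = np.asarray(arr, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def two_groups(sample_ids, n_disease):
    return SampleGroups(
        {
            s: ("disease" if i < n_disease else "control")
            for i, s in enumerate(sample_ids)
        }
    )
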