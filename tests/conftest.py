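import numpy as np
import pytest

import chromshap as cs
from chromshap.regression import MLPParams


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene cohort for structural tests (not recovery)."""
    return cs.generate_cohort(cs.SynConfig(n_genes=400, seed=7))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return cs.make_splits(small_cohort.features.gene_ids, small_cohort.degron, seed=42)[0]


@pytest.fixture(scope="session")
def small_model(small_cohort, small_split):
    return cs.PolIIModel.from_cohort(small_cohort, small_split)


@pytest.fixture(scope="session")
def quick_mlp_params():
    """A light training recipe for tests that only need a working network."""
    return MLPParams(hidden_layer_sizes=(32,), max_epochs=200, patience=50, tol=1e-6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
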