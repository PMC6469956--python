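import numpy as np
import pandas as pd
import pytest

from mgscope.datamodel import FeatureTable, GeneCountMatrix
from mgscope.synth import SyntheticSpec, generate_bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_bundle():
    """One small, fully-populated synthetic study shared across tests."""
    spec = SyntheticSpec(
        rng_seed=11, n_control=10, n_case=10, n_species=6,
        genes_per_species=(15, 40), depth=5e4,
    )
    return generate_bundle(spec)


@pytest.fixture()
def tiny_gcm():
    counts = pd.DataFrame(
        [[10, 0], [20, 5]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    lengths = pd.Series({"g1": 100, "g2": 200})
    return GeneCountMatrix(counts=counts, lengths=lengths)


def random_feature_table(rng, n_features=8, n_samples=5, kind="copy_number"):
    vals = rng.random((n_features, n_samples)) + 0.01
    return FeatureTable(
        values=pd.DataFrame(
            vals,
            index=[f"f{i}" for i in range(n_features)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        kind=kind,
    )
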