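import numpy as np
import pytest

from hybridscreen import ModelSpec, fixtures, split_stratified, train
from hybridscreen.fixtures import FixtureSpec, records_from_table


@pytest.fixture(scope="session")
def aligned4():
    """Four aligned halobenzyl analogues + manifest of expected hybrids."""
    return fixtures.make_aligned_set(k=4)


@pytest.fixture(scope="session")
def small_dataset():
    """Separable planted-motif dataset, 80 actives / 80 decoys."""
    df = fixtures.make_activity_dataset(FixtureSpec(seed=7, n_active=80, n_inactive=80))
    return records_from_table(df)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_stratified(small_dataset, test_fraction=0.2, seed=7)


@pytest.fixture(scope="session")
def small_clf(small_split):
    """MLP trained once per session on the small separable dataset."""
    train_recs, _ = small_split
    return train(train_recs, ModelSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
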