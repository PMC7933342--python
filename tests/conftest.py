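import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

import mitomorph as mm


@pytest.fixture(scope="session")
def table2d_acc():
    """Object table at the reference study scale: 300 objects per class."""
    return mm.sample_object_table(mm.SynthSpec2D(n_per_class=300, seed=1))


@pytest.fixture(scope="session")
def model2d_acc(table2d_acc):
    """The full 2D protocol: stratified 80/20 split, 500 trees, 25 reps."""
    train, test = mm.split_train_test(table2d_acc, 0.8, seed=2)
    model = mm.train_random_forest(train, n_trees=500, n_repetitions=25, seed=3)
    return model, train, test


@pytest.fixture(scope="session")
def table2d_small():
    """A cheap 2D object table for analytics and quantification tests."""
    return mm.sample_object_table(mm.SynthSpec2D(n_per_class=30, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
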