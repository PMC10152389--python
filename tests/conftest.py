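import numpy as np
import pytest

from mononet import MonoNetClassifier, make_signatures, sample_cells, split_data
from mononet.training import SplitSpec


@pytest.fixture(scope="session")
def cytof_sig():
    return make_signatures(8, 13, seed=0)


@pytest.fixture(scope="session")
def cytof_small(cytof_sig):
    """A 3000-cell sample — enough structure for interpretation tests, fast."""
    X, y = sample_cells(cytof_sig, 3000, seed=1)
    return X, y


@pytest.fixture(scope="session")
def trained_small(cytof_small):
    """Case-study architecture trained on the small synthetic sample."""
    X, y = cytof_small
    tr, va, te = split_data(X.to_numpy(), y.to_numpy(), SplitSpec(seed=0))
    model = MonoNetClassifier(random_state=0, epochs=80, patience=10)
    model.fit(*tr, validation_data=va)
    return model, (tr, va, te)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
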