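import numpy as np
import pandas as pd
import pytest

from cbqsar import load_cb1_reference


@pytest.fixture(scope="session")
def cb1():
    """Bundled CB1 synthetic-cannabinoid reference dataset."""
    return load_cb1_reference()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def frame(values, columns=None, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    columns = columns or [f"x{j}" for j in range(values.shape[1])]
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=pd.Index(ids, name="compound_id"),
                        columns=columns)


@pytest.fixture
def make_frame():
    return frame
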