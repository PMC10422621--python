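import numpy as np
import pandas as pd
import pytest

from necroscan import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_cloud(x, y, z, return_number=None, n_returns=None, ground=None,
               height=None, epoch_label=""):
    n = len(x)
    df = pd.DataFrame({
        "x": np.asarray(x, float),
        "y": np.asarray(y, float),
        "z": np.asarray(z, float),
        "return_number": np.ones(n, int) if return_number is None else np.asarray(return_number),
        "n_returns": np.ones(n, int) if n_returns is None else np.asarray(n_returns),
    })
    if ground is not None:
        df["ground"] = np.asarray(ground, bool)
    if height is not None:
        df["height"] = np.asarray(height, float)
    return PointCloud(df, epoch_label=epoch_label)


@pytest.fixture
def random_cloud(rng):
    """1000 returns scattered over 100 x 100 m with normalized heights."""
    n = 1000
    return make_cloud(
        x=rng.uniform(0, 100, n),
        y=rng.uniform(0, 100, n),
        z=rng.uniform(0, 20, n),
        return_number=rng.integers(1, 3, n),
        n_returns=np.full(n, 2),
        height=rng.choice([0.0, 0.8, 5.0, 15.0], n),
    )
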