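import numpy as np
import pandas as pd
import pytest

from sxdamage.reflections import UnitCell, point_group_ops


@pytest.fixture(scope="session")
def cell():
    return UnitCell(78.8)


@pytest.fixture(scope="session")
def group23():
    return point_group_ops("23")


@pytest.fixture(scope="session")
def group1():
    return point_group_ops("1")


def make_observations(rows):
    """Build an observation table from (h, k, l, I, sigma, frame, id) tuples."""
    arr = list(zip(*rows))
    return pd.DataFrame(
        {
            "h": np.asarray(arr[0], dtype=np.int64),
            "k": np.asarray(arr[1], dtype=np.int64),
            "l": np.asarray(arr[2], dtype=np.int64),
            "intensity": np.asarray(arr[3], dtype=float),
            "sigma": np.asarray(arr[4], dtype=float),
            "frame": np.asarray(arr[5], dtype=np.int64),
            "crystal_id": pd.Series(arr[6], dtype=object),
        }
    )


@pytest.fixture(scope="session")
def small_truth(cell, group23):
    """Coarse ground truth (d_min 4 A) shared by simulation-heavy tests."""
    from sxdamage.simulate import generate_truth

    return generate_truth(cell, group23, d_min=4.0, d_max=30.0, seed=7)
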