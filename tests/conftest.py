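import numpy as np
import pandas as pd
import pytest

from mycospec.spectra_io import META_COLUMNS, SpectraSet
from mycospec.synthetic_data import synth_dataset


def make_meta(n: int, **overrides) -> pd.DataFrame:
    """Minimal valid metadata table for n spectra."""
    base = {
        "sample_id": [f"s{i}" for i in range(n)],
        "strain": ["Mc1"] * n,
        "pi_level": [1.0] * n,
        "ca_level": [1] * n,
        "bio_rep": [1] * n,
        "tech_rep": list(range(1, n + 1)),
        "laser_power_mw": [500.0] * n,
        "block": ["raman"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)[META_COLUMNS]


def make_set(matrix, grid=None, meta=None, chemistry=None) -> SpectraSet:
    """SpectraSet from a raw matrix with a descending grid and dummy meta."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if grid is None:
        grid = np.arange(float(p), 0.0, -1.0)
    return SpectraSet(np.asarray(grid, float), matrix, meta if meta is not None else make_meta(n), chemistry).validate()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 1): raman, ftir, chemistry."""
    return synth_dataset(seed=1)


@pytest.fixture(scope="session")
def raman_set(default_dataset):
    return default_dataset[0]


@pytest.fixture(scope="session")
def ftir_set(default_dataset):
    return default_dataset[1]


@pytest.fixture(scope="session")
def chemistry(default_dataset):
    return default_dataset[2]
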