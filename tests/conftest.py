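import numpy as np
import pandas as pd
import pytest

from patchlink import GeneratorConfig, generate_dataset
from patchlink.datatypes import EPHYS_FEATURES


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (17 ND / 9 T1D donors), seed 1."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, small cohort for pipeline-level tests."""
    cfg = GeneratorConfig(
        seed=7,
        n_donors_nd=6,
        n_donors_t1d=6,
        cells_per_donor={"ND": 30, "T1D": 40},
        n_genes=600,
    )
    return generate_dataset(cfg)


def separable_toy(n_per_class: int = 250, seed: int = 0):
    """Linearly separable electrophysiology toy: alpha cells have
    cell_size in [2, 4], beta in [8, 10]; every other feature is noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n, len(EPHYS_FEATURES))),
        columns=list(EPHYS_FEATURES),
        index=[f"cell{i}" for i in range(n)],
    )
    X.iloc[:n_per_class, X.columns.get_loc("cell_size")] = rng.uniform(
        2.0, 4.0, n_per_class
    )
    X.iloc[n_per_class:, X.columns.get_loc("cell_size")] = rng.uniform(
        8.0, 10.0, n_per_class
    )
    y = np.array(["alpha"] * n_per_class + ["beta"] * n_per_class, dtype=object)
    perm = rng.permutation(n)
    return X.iloc[perm], y[perm]


@pytest.fixture()
def toy_classifier_data():
    return separable_toy()
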