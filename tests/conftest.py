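import numpy as np
import pandas as pd
import pytest

from morphocompare import DesignSpec, EffectSpec
from morphocompare.datasets import LABEL_COLUMNS


@pytest.fixture
def small_design():
    """A compact but complete crossed design for fast tests."""
    return DesignSpec(n_species=1, n_populations=2, n_individuals=8,
                      n_measurers=2, n_repeats=2, seed=42)


@pytest.fixture
def quiet_effects():
    """No measurement error at all: repeats and measurers agree exactly."""
    return EffectSpec(measurer_bias=0.0, repeat_noise=0.0)


def make_labels(n, species="sp1", site="site1", measurer="M1", repeat=1):
    return pd.DataFrame({
        "species": species, "site": site,
        "individual": [f"i{j:02d}" for j in range(n)],
        "measurer": measurer, "repeat": repeat,
    }, columns=LABEL_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
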