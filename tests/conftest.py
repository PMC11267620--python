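import numpy as np
import pandas as pd
import pytest

from mirhd.de import CountMatrix
from mirhd.energy import EnergyModel


@pytest.fixture
def model():
    return EnergyModel()


@pytest.fixture
def strict_model():
    """A model in which every substitution strictly loses bonds (wobble and
    A–C weakened below the canonical pairs), so ratio 100 pins down the exact
    reverse complement."""
    return EnergyModel(bonds_per_pair={"AU": 2.0, "CG": 3.0, "GU": 1.0, "AC": 0.5})


@pytest.fixture
def small_matrix():
    """4 miRNAs × (3+3) samples of hand-set raw counts."""
    counts = pd.DataFrame(
        np.array(
            [
                [10, 12, 11, 40, 44, 42],
                [100, 110, 105, 25, 27, 26],
                [50, 55, 52, 50, 53, 51],
                [5, 6, 5, 5, 6, 5],
            ]
        ),
        index=[f"mir-{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(
        ["control"] * 3 + ["disease"] * 3, index=counts.columns
    )
    return CountMatrix(counts, groups)
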