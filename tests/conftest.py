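import numpy as np
import pandas as pd
import pytest

from phylomilk.core import CovariateTable, TraitMatrix, read_newick_string


@pytest.fixture
def three_tip_tree():
    return read_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return read_newick_string("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")


@pytest.fixture
def star_tree():
    return read_newick_string("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def small_traits():
    g = pd.DataFrame(
        {
            "fat": [4.5, 3.8, 25.0, 12.0, 6.1],
            "protein": [3.2, 2.9, 10.5, 7.6, 4.0],
            "sugar": [6.8, 7.1, 0.9, 3.5, 5.2],
        },
        index=["A", "B", "C", "D", "E"],
    )
    return TraitMatrix.from_g100g(g)


@pytest.fixture
def small_covariates():
    df = pd.DataFrame(
        {
            "arid": [0, 0, 1, 0, 1],
            "aquatic": [0, 0, 3, 1, 0],
            "diet": ["herbivore", "omnivore", "carnivore", "herbivore", "omnivore"],
            "female_mass": [1.0, 10.0, 100.0, 5.0, 50.0],
            "rep_output": [0.1, 0.2, 0.05, 0.3, 0.15],
            "lactation_length": [0.4, 0.5, 0.3, 0.6, 0.45],
            "precociality": [1, 2, 0, 3, 1],
        },
        index=["A", "B", "C", "D", "E"],
    )
    return CovariateTable(df, centered=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
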