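import warnings

import numpy as np
import pandas as pd
import pytest

from qasd_mediate import SyntheticTruth, FoodIntakeTable
from qasd_mediate.synthetic import gen_cohort, make_taxonomy


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-participant cohort with the default planted structure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_cohort(SyntheticTruth(n=80, seed=11))


@pytest.fixture(scope="session")
def taxonomy():
    return make_taxonomy()


@pytest.fixture
def tiny_intake():
    """Five participants, six items, three food groups (one beverage)."""
    tax = pd.DataFrame({
        "group42": ["veg", "veg", "grain", "grain", "drink", "drink"],
        "group22": ["plant", "plant", "plant", "plant", "bev", "bev"],
        "is_beverage": [False, False, False, False, True, True],
        "is_liquid": [False, False, False, False, True, True],
    }, index=["carrot", "pea", "bread", "rice", "cola", "juice"])
    grams = pd.DataFrame(
        [
            [100.0, 100.0, 100.0, 100.0, 0.0, 0.0],
            [400.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [50.0, 50.0, 200.0, 0.0, 300.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 250.0, 250.0],
            [120.0, 30.0, 60.0, 90.0, 100.0, 0.0],
        ],
        index=[f"p{i}" for i in range(1, 6)],
        columns=tax.index,
    )
    return FoodIntakeTable(grams, tax)
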