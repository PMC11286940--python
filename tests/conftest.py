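import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from isodiet import core_io
from isodiet.synthetic import DietScenario, generate_stomachs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def diet_tables():
    """One seeded study cycle of synthetic stomach/prey tables."""
    return generate_stomachs(DietScenario(seed=42))


@pytest.fixture(scope="session")
def filtered(diet_tables):
    stomachs, prey = diet_tables
    return core_io.filter_stomachs(stomachs, prey)


@pytest.fixture(scope="session")
def stratified(filtered):
    return core_io.stratify(filtered.stomachs)


@pytest.fixture()
def tiny_prey():
    """Two stomachs: A{X: 2 items, 10 g}, B{Y: 2 items, 30 g}."""
    return pd.DataFrame(
        {
            "stomach_id": ["A", "B"],
            "taxon_name": ["Xfish", "Yfish"],
            "taxon_rank": ["species", "species"],
            "family": ["X", "Y"],
            "count": [2, 2],
            "wet_weight_g": [10.0, 30.0],
            "life_stage": ["adult", "adult"],
            "is_bait": [False, False],
            "is_chum": [False, False],
            "source_group": ["oceanic_nekton", "oceanic_nekton"],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240401)
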