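import numpy as np
import pandas as pd
import pytest

from tcqe import metabolomics as mb
from tcqe import synthetic as syn


@pytest.fixture
def compounds():
    return pd.DataFrame(
        {
            "id": ["C1", "C2", "C3", "HSYA"],
            "name": ["a", "b", "c", "hydroxysafflor yellow A"],
            "ob": [30.0, 29.9, 55.0, 5.0],
            "dl": [0.18, 0.9, 0.5, 0.01],
        }
    )


@pytest.fixture
def small_feature_table():
    """6+6 biological samples, 5 QCs, 30 features, no drift."""
    table, truth = syn.gen_feature_table(
        syn.MetaboSimSpec(
            n_features=30,
            n_per_group=6,
            planted_effects=[(0, 4.0), (1, 4.0), (2, 0.25)],
            seed=11,
        )
    )
    return table, truth


@pytest.fixture
def bio_subtable(small_feature_table):
    table, truth = small_feature_table
    bio = table.biological_columns
    return mb.FeatureTable(table.intensities[bio], table.samples.loc[bio]), truth
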