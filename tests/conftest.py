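import numpy as np
import pandas as pd
import pytest

import bdcfgp as b


@pytest.fixture(scope="session")
def study_table() -> b.ResponseTable:
    """Synthetic response table with the study's class distribution (654 rows)."""
    return b.generate_dataset(b.GeneratorSpec(seed=20240603))


@pytest.fixture(scope="session")
def fgp_frame(study_table) -> pd.DataFrame:
    return b.fgp_transform(study_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_weight_matrix(rng) -> np.ndarray:
    """500 random 25-item responses, uniform weights 0-4."""
    return rng.integers(0, 5, size=(500, 25))
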