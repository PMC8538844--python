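import numpy as np
import pandas as pd
import pytest

from tmmkit.io_formats import ExpressionMatrix, GeneSetCollection
from tmmkit.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expr():
    """5 genes x 4 samples, two cohorts, no ties."""
    values = pd.DataFrame(
        [
            [1.0, 5.0, 2.5, 7.0],
            [2.0, 4.0, 3.5, 1.0],
            [3.0, 3.0, 9.0, 2.0],
            [4.0, 2.0, 0.5, 5.0],
            [5.0, 1.0, 6.0, 3.0],
        ],
        index=["G1", "G2", "G3", "G4", "G5"],
        columns=["S1", "S2", "S3", "S4"],
    )
    cohorts = {"S1": "A", "S2": "A", "S3": "B", "S4": "B"}
    return ExpressionMatrix(values, cohorts)


@pytest.fixture
def toy_sets():
    return GeneSetCollection(
        {"UP": ["G1", "G2"], "DOWN": ["G4", "G5"]},
        {"UP": "", "DOWN": ""},
    )


@pytest.fixture(scope="session")
def high_effect_cohort():
    """Shared n=400, effect=3 cohort used by several recovery tests."""
    return generate_cohort(
        CohortConfig(n_samples=400, effect=3.0, noise_sd=0.5, seed=2024)
    )
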