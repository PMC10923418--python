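import numpy as np
import pandas as pd
import pytest

from eggfr import EggParams, FRParams, ModelSpec
from eggfr.lifetime import ExperimentDataset


@pytest.fixture(scope="session")
def cachamai_c5():
    """Generating configuration for the short-lived species profile."""
    return (
        ModelSpec.from_name("C5"),
        FRParams(b=0.073, a=0.003, H=0.005),
        EggParams(e0=56.0, h0=8.0, g=0.972, r=0.677, u=19.0),
    )


@pytest.fixture(scope="session")
def lapachosus_d5():
    """Generating configuration for the experience-driven species profile."""
    return (
        ModelSpec.from_name("D5"),
        FRParams(b=0.109, a=0.001, H=0.004),
        EggParams(e0=57.0, h0=11.0, g=1.330, r=0.935, u=15.0),
    )


def make_dataset(rows) -> ExperimentDataset:
    return ExperimentDataset(pd.DataFrame(rows))


@pytest.fixture
def tiny_dataset():
    """Two females, three/two days, small counts."""
    return make_dataset(
        [
            {"female_id": "F1", "day": 1, "n_offered": 10, "n_parasitized": 2},
            {"female_id": "F1", "day": 2, "n_offered": 9, "n_parasitized": 1},
            {"female_id": "F1", "day": 3, "n_offered": 11, "n_parasitized": 0},
            {"female_id": "F2", "day": 1, "n_offered": 8, "n_parasitized": 3},
            {"female_id": "F2", "day": 2, "n_offered": 10, "n_parasitized": 2},
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
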