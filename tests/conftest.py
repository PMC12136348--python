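import warnings

import numpy as np
import pytest

from saccadapt import (
    ExperimentDesign,
    FieldGrid,
    NegativeGainWarning,
    TABLE1_PARAMS,
    TEST_GRID,
)


@pytest.fixture(autouse=True)
def _silence_negative_gain_warnings():
    # deep learning dips legitimately push gains through zero in the
    # reference parameter regime; individual tests assert the warning itself
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeGainWarning)
        yield


@pytest.fixture(scope="session")
def grid() -> FieldGrid:
    return TEST_GRID


@pytest.fixture(scope="session")
def coarse_grid() -> FieldGrid:
    """Small, fast grid for unit tests that only need qualitative geometry."""
    return FieldGrid(half_extent=20.0, step=0.5)


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign.standard()


@pytest.fixture(scope="session")
def table1():
    return TABLE1_PARAMS


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
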