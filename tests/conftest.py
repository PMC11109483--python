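import warnings

import numpy as np
import pandas as pd
import pytest

from ubichain.io import IntensityMatrix, SampleDesign
from ubichain.pipeline import RunConfig, run_all
from ubichain.simulate import SimConfig


@pytest.fixture
def small_matrix():
    """3 proteins x 4 samples, one masked cell, linear scale."""
    values = np.array(
        [
            [100.0, 200.0, 150.0, 120.0],
            [50.0, np.nan, 80.0, 60.0],
            [1000.0, 900.0, 1100.0, 950.0],
        ]
    )
    missing = np.isnan(values)
    return IntensityMatrix(["A", "B", "C"], ["S1", "S2", "S3", "S4"], values, missing)


@pytest.fixture
def two_group_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "bait": ["bead_control", "bead_control", "K48_Ub3", "K48_Ub3"],
                "replicate": [1, 2, 1, 2],
                "dataset": ["CAA"] * 4,
            }
        )
    )


@pytest.fixture(scope="session")
def default_study():
    """One full two-dataset run on the default synthetic study (seed 1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_all(RunConfig(sim=SimConfig(seed=1), seed=1))
    return report
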