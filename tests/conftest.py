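import numpy as np
import pandas as pd
import pytest

from fibrostrat.io_formats import ClinicalTable, ExpressionMatrix
from fibrostrat.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix.from_arrays(
        ["GA", "GB", "GC"],
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 5.0, 5.0, 5.0],
                [0.5, 1.5, 2.5, 0.5],
            ]
        ),
    )


@pytest.fixture
def small_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "group": ["control", "disease", "disease", "disease"],
                "fev1_pct": [95.0, 70.0, 60.0, 50.0],
                "fvc_pct": [92.0, 65.0, 58.0, 45.0],
                "dlco_pct": [96.0, 60.0, np.nan, 35.0],
                "age": [60, 62, 64, 66],
                "sex": ["male", "female", "male", "male"],
                "smoking": ["never", "former", "former", "current"],
            }
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(), seed=7)
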