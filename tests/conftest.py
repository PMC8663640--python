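import numpy as np
import pandas as pd
import pytest

from ldptab import ClinicalTableSpec, gen_clinical_table


@pytest.fixture(scope="session")
def clinical_1000():
    """Deterministic n=1000 clinical table + schema (the standard test fixture)."""
    return gen_clinical_table(ClinicalTableSpec(n=1000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def mixed_table():
    """Tiny hand-written mixed table for schema tests."""
    return pd.DataFrame(
        {
            "hr": [60.0, 80.0, 100.0, 120.0],
            "flag": [0, 1, 1, 0],
            "gcs": [3, 1, 2, 3],
        }
    )
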