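import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from scngraph import CohortConfig, generate_cohort, residualize


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest synthetic cohort reused across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=25, n_controls=20, seed=42))


@pytest.fixture(scope="session")
def small_residuals(small_cohort) -> pd.DataFrame:
    return residualize(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
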