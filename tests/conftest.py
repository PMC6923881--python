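import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from protpred.data_io import ExpressionMatrix
from protpred.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 features, one missing entry."""
    values = np.array([[1.0, 4.0], [2.0, np.nan], [3.0, 6.0]])
    return ExpressionMatrix(["s1", "s2", "s3"], ["g1", "g2"], values,
                            layer="transcript")


@pytest.fixture(scope="session")
def small_cohort():
    """Complete (no missing) mixed cohort for fast harness tests."""
    spec = CohortSpec(n_samples=60, n_transcripts=40, n_proteins=10,
                      missing_rate=0.0, transcript_missing_rate=0.0, seed=11)
    return generate_cohort(spec)
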