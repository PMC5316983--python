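import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adaptseq.design import default_design

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def design3():
    """Printed amplicon design with i7 indices for three samples."""
    return default_design(["s1", "s2", "s3"], index_seed=11)


@pytest.fixture
def small_count_table():
    from adaptseq.counts import CountTable

    data = pd.DataFrame(
        {"a": [10, 40, 50], "b": [30, 90, 180]},
        index=["ACG" * 11 + "AA", "CGT" * 11 + "TT", "GTA" * 11 + "CC"],
    )
    samples = pd.DataFrame(
        {
            "cohort": ["cancer", "healthy"],
            "patient_id": ["p1", "p2"],
            "replicate": [1, 1],
        },
        index=["a", "b"],
    )
    return CountTable(data=data, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
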