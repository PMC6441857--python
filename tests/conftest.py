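import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import kpsize as kp

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def table_from_captures(captures: np.ndarray, sources: tuple[str, ...]) -> kp.AggregateCaptureTable:
    """Reduce a (N, J) binary capture matrix to its aggregate profile table."""
    obs = captures[captures.any(axis=1)]
    records = [
        kp.CaptureRecord(f"i{i}", tuple(int(x) for x in row)) for i, row in enumerate(obs)
    ]
    return kp.aggregate_histories(records, sources)


@pytest.fixture
def homogeneous_table():
    """3-source table from a homogeneous population: N=1000, p=0.3 per source."""
    rng = np.random.default_rng(1)
    captures = (rng.random((1000, 3)) < 0.3).astype(int)
    return table_from_captures(captures, ("a", "b", "c")), 1000


@pytest.fixture
def flat_rds_frame():
    """RDS sample of 500 unlinked respondents (all seeds), equal degrees."""
    rng = np.random.default_rng(2)
    n = 500
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "degree": 3,
            "recruiter_id": pd.NA,
            "wave": 0,
            "tested": (rng.random(n) < 0.4).astype(int),
        }
    )
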