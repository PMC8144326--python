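import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_pair_panel(records):
    """Build a minimal graded two-wave panel from (subject, state1, state2)
    tuples; ``state2=None`` marks a subject lost to follow-up."""
    rows = []
    for sid, s1, s2 in records:
        rows.append(
            {
                "subject_id": str(sid),
                "wave": 2011,
                "age_group": "65-74",
                "male": 0,
                "urban": 0,
                "widowed": 0,
                "dead": int(s1 == 0),
                "state": s1,
            }
        )
        if s2 is not None:
            rows.append(
                {
                    "subject_id": str(sid),
                    "wave": 2014,
                    "age_group": "65-74",
                    "male": 0,
                    "urban": 0,
                    "widowed": 0,
                    "dead": int(s2 == 0),
                    "state": s2,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def pair_panel_factory():
    return make_pair_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
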