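import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220831)


@pytest.fixture
def toy_cohort_csv(tmp_path):
    """A tiny well-formed cohort file: 2 cases + 2 controls, male 60-69."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "subject_id,group,sex,age,grt_left,grt_right,grip_left,grip_right\n"
        "c1,control,male,62,24,25,36.0,37.5\n"
        "c2,control,male,68,22,21,33.5,34.0\n"
        "d1,dcm,male,65,14,12,15.0,16.5\n"
        "d2,dcm,male,61,16,15,18.0,17.5\n"
    )
    return path
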