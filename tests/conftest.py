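import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from statincf.effects import PooledEffect
from statincf.survey_io import OFFSET_ATTR, PERIOD_1991, PERIOD_2011

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_participants(
    n=200,
    period=PERIOD_2011,
    seed=0,
    prevalence=0.2,
    tc_mean=5.5,
    tc_sd=1.0,
    missing=0.0,
):
    """Small hand-rolled participant table in the canonical schema."""
    rng = np.random.default_rng(seed)
    tc = rng.normal(tc_mean, tc_sd, n).clip(1.0)
    tc[rng.random(n) < missing] = np.nan
    df = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "age": rng.integers(18, 90, n),
            "sex": rng.choice(["male", "female"], n),
            "period": period,
            "qimd": rng.integers(1, 6, n).astype(float)
            if period == PERIOD_2011
            else np.nan,
            "social_class": None
            if period == PERIOD_2011
            else rng.choice(["I", "II", "IIIN", "IIIM", "IV", "V", "Other"], n),
            "weight": 1.0
            if period == PERIOD_1991
            else rng.lognormal(0, 0.2, n),
            "psu": rng.choice([f"p{j}" for j in range(20)], n),
            "stratum": rng.choice([f"s{j}" for j in range(4)], n),
            "statin_user": rng.random(n) < prevalence,
            "tc_mmol": tc,
            "measured_post_2010_04": period == PERIOD_2011,
        }
    )
    df.attrs[OFFSET_ATTR] = False
    return df


@pytest.fixture
def participants_2011():
    return make_participants()


@pytest.fixture
def pooled():
    return PooledEffect(e_w=0.257, se=0.012)


@pytest.fixture
def participant_csv(tmp_path):
    """A well-formed 3-row participant file on disk."""
    path = tmp_path / "participants.csv"
    path.write_text(
        "id,age,sex,period,qimd,social_class,weight,psu,stratum,"
        "statin_user,tc_mmol,measured_post_2010_04\n"
        "a,45,male,2011-12,2,,1.1,p1,s1,1,5.27,1\n"
        "b,60,female,2011-12,5,,0.9,p2,s1,0,6.10,1\n"
        "c,30,female,1991-92,,IIIN,1.0,p3,s2,0,5.00,0\n"
    )
    return path
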