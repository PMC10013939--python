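import numpy as np
import pytest
from hypothesis import settings
from hypothesis import strategies as st

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from hbsr.model import (
    AlcoholFreq,
    Education,
    Exercise,
    Group,
    Marital,
    Respondent,
    Salting,
    Sex,
    Smoking,
)
from hbsr.scoring import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


def make_respondent(rid="r1", **overrides):
    """A complete low-risk respondent; override any field."""
    base = dict(
        id=rid,
        group=Group.PATIENT,
        age=40,
        sex=Sex.MALE,
        education=Education.HIGHER,
        marital=Marital.MARRIED_COHABITING,
        smoking=Smoking.NEVER,
        bmi=22.0,
        exercise=Exercise.GE4_PER_WEEK,
        veg_days=7,
        salting=Salting.NEVER,
        alcohol_freq=AlcoholFreq.NONE,
        alcohol_units_7d=0.0,
    )
    base.update(overrides)
    return Respondent(**base)


def max_risk_respondent(rid="worst"):
    return make_respondent(
        rid,
        smoking=Smoking.DAILY,
        bmi=32.0,
        exercise=Exercise.RARE_OR_NONE,
        veg_days=2,
        salting=Salting.BEFORE_TASTING,
        alcohol_freq=AlcoholFreq.GE2_PER_WEEK,
        alcohol_units_7d=30.0,
    )


# hypothesis strategy for arbitrary (possibly incomplete) respondents
def respondents(complete=False):
    opt = (lambda s: s) if complete else (lambda s: st.none() | s)
    return st.builds(
        Respondent,
        id=st.uuids().map(str),
        group=st.sampled_from(Group),
        age=st.integers(18, 54),
        sex=st.sampled_from(Sex),
        education=st.sampled_from(Education),
        marital=st.sampled_from(Marital),
        smoking=opt(st.sampled_from(Smoking)),
        bmi=opt(st.floats(10.5, 79.5, allow_nan=False)),
        exercise=opt(st.sampled_from(Exercise)),
        veg_days=opt(st.integers(0, 7)),
        salting=opt(st.sampled_from(Salting)),
        alcohol_freq=opt(st.sampled_from(AlcoholFreq)),
        alcohol_units_7d=opt(st.floats(0, 60, allow_nan=False)),
    )


def random_complete_respondent(rng: np.random.Generator, rid: str) -> Respondent:
    """Numpy-driven complete respondent for large seeded property sweeps."""

    def pick(etype):
        members = list(etype)
        return members[int(rng.integers(len(members)))]

    return Respondent(
        id=rid,
        group=pick(Group),
        age=int(rng.integers(18, 55)),
        sex=pick(Sex),
        education=pick(Education),
        marital=pick(Marital),
        smoking=pick(Smoking),
        bmi=float(rng.uniform(16, 45)),
        exercise=pick(Exercise),
        veg_days=int(rng.integers(0, 8)),
        salting=pick(Salting),
        alcohol_freq=pick(AlcoholFreq),
        alcohol_units_7d=float(rng.uniform(0, 40)),
    )
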