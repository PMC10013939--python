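"""The Health Behavior Stroke Risk (HBSR) score.

Five behavioral factors -- smoking, BMI, exercise, diet (meal salting +
vegetable frequency) and alcohol (use frequency + 7-day amount) -- are each
graded low / moderate / high risk, worth 0 / 1 / 2 points, and summed to a
total of 0-10; 10 is the worst attainable behavior.  Totals of 6-10 define
the high-risk band, 0-5 the low band.

The answer-to-grade mapping is fully configurable (:class:`ScoringConfig`);
the packaged default grades each single-answer factor by its published
high-risk definition (daily smoking, BMI >= 30, exercising less than twice
a week) with intermediate answers as moderate, and grades the two composite
factors by counting adverse sub-answers (both adverse -> high, one ->
moderate, none -> low).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .model import (
    AlcoholFreq,
    BmiClass,
    Cohort,
    Exercise,
    Respondent,
    Salting,
    Smoking,
    bmi_class,
)

FACTORS = ("smoking", "bmi", "exercise", "diet", "alcohol")

SCORE_MIN = 0
SCORE_MAX = 10


class RiskLevel(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def points(self) -> int:
        return {"low": 0, "moderate": 1, "high": 2}[self.value]


class Band(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


class MissingPolicy(str, enum.Enum):
    REQUIRE_COMPLETE = "require_complete"
    TREAT_MISSING_AS_LOW = "treat_missing_as_low"


@dataclass(frozen=True)
class ScoringConfig:
    """Answer -> risk-grade mapping tables and thresholds for the HBSR score."""

    smoking_grades: Mapping[Smoking, RiskLevel]
    bmi_grades: Mapping[BmiClass, RiskLevel]
    exercise_grades: Mapping[Exercise, RiskLevel]
    adverse_salting: frozenset[Salting]
    veg_days_threshold: int  # adverse when veg_days < threshold
    adverse_alcohol_freq: frozenset[AlcoholFreq]
    alcohol_unit_limits: Mapping[str, float]  # per Sex token, units/7 days
    alcohol_strict_inequality: bool  # True: > limit; False: >= limit
    high_band_cutoff: int = 6
    missing_policy: MissingPolicy = MissingPolicy.REQUIRE_COMPLETE

    def __post_init__(self) -> None:
        for grades, etype in (
            (self.smoking_grades, Smoking),
            (self.bmi_grades, BmiClass),
            (self.exercise_grades, Exercise),
        ):
            missing = set(etype) - set(grades)
            if missing:
                raise ValueError(f"grade mapping lacks categories {missing}")
        if not 1 <= self.high_band_cutoff <= 10:
            raise ValueError("high-band cut-off must lie in 1..10")
        if not {"male", "female"} <= set(self.alcohol_unit_limits):
            raise ValueError("alcohol unit limits needed for both sexes")


def default_config() -> ScoringConfig:
    """The packaged default mapping (see docs/methods.md for rationale)."""
    return ScoringConfig(
        smoking_grades={
            Smoking.DAILY: RiskLevel.HIGH,
            Smoking.OCCASIONAL: RiskLevel.MODERATE,
            Smoking.EX_SMOKER: RiskLevel.MODERATE,
            Smoking.NEVER: RiskLevel.LOW,
        },
        bmi_grades={
            BmiClass.GE30: RiskLevel.HIGH,
            BmiClass.B25_29_9: RiskLevel.MODERATE,
            BmiClass.LT25: RiskLevel.LOW,
        },
        exercise_grades={
            Exercise.GE4_PER_WEEK: RiskLevel.LOW,
            Exercise.W2_3_PER_WEEK: RiskLevel.LOW,
            Exercise.ONCE_PER_WEEK: RiskLevel.MODERATE,
            Exercise.M2_3_PER_MONTH: RiskLevel.MODERATE,
            Exercise.RARE_OR_NONE: RiskLevel.HIGH,
        },
        adverse_salting=frozenset({Salting.BEFORE_TASTING}),
        veg_days_threshold=6,
        adverse_alcohol_freq=frozenset(
            {AlcoholFreq.GE2_PER_WEEK, AlcoholFreq.ONCE_PER_WEEK}
        ),
        alcohol_unit_limits={"female": 8.0, "male": 16.0},
        alcohol_strict_inequality=True,
    )


# --- config (de)serialization ------------------------------------------------

def config_to_dict(cfg: ScoringConfig) -> dict:
    return {
        "smoking_grades": {k.value: v.value for k, v in cfg.smoking_grades.items()},
        "bmi_grades": {k.value: v.value for k, v in cfg.bmi_grades.items()},
        "exercise_grades": {k.value: v.value for k, v in cfg.exercise_grades.items()},
        "adverse_salting": sorted(s.value for s in cfg.adverse_salting),
        "veg_days_threshold": cfg.veg_days_threshold,
        "adverse_alcohol_freq": sorted(a.value for a in cfg.adverse_alcohol_freq),
        "alcohol_unit_limits": dict(cfg.alcohol_unit_limits),
        "alcohol_strict_inequality": cfg.alcohol_strict_inequality,
        "high_band_cutoff": cfg.high_band_cutoff,
        "missing_policy": cfg.missing_policy.value,
    }


def config_from_dict(d: Mapping) -> ScoringConfig:
    return ScoringConfig(
        smoking_grades={Smoking(k): RiskLevel(v) for k, v in d["smoking_grades"].items()},
        bmi_grades={BmiClass(k): RiskLevel(v) for k, v in d["bmi_grades"].items()},
        exercise_grades={Exercise(k): RiskLevel(v) for k, v in d["exercise_grades"].items()},
        adverse_salting=frozenset(Salting(s) for s in d["adverse_salting"]),
        veg_days_threshold=int(d["veg_days_threshold"]),
        adverse_alcohol_freq=frozenset(AlcoholFreq(a) for a in d["adverse_alcohol_freq"]),
        alcohol_unit_limits={k: float(v) for k, v in d["alcohol_unit_limits"].items()},
        alcohol_strict_inequality=bool(d["alcohol_strict_inequality"]),
        high_band_cutoff=int(d.get("high_band_cutoff", 6)),
        missing_policy=MissingPolicy(d.get("missing_policy", "require_complete")),
    )


def load_config(path: str | Path) -> ScoringConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: ScoringConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# --- grading ------------------------------------------------------------------

@dataclass(frozen=True)
class HBSRResult:
    """Per-factor points, total 0-10 and low/high band for one respondent."""

    factor_points: Mapping[str, Optional[int]]
    total: Optional[int]
    band: Optional[Band]
    n_missing_factors: int


def _diet_adverse(r: Respondent, cfg: ScoringConfig) -> Optional[tuple[bool, bool]]:
    if r.salting is None or r.veg_days is None:
        return None
    return (r.salting in cfg.adverse_salting, r.veg_days < cfg.veg_days_threshold)


def _alcohol_adverse(r: Respondent, cfg: ScoringConfig) -> Optional[tuple[bool, bool]]:
    if r.alcohol_freq is None or r.alcohol_units_7d is None:
        return None
    limit = cfg.alcohol_unit_limits[r.sex.value]
    if cfg.alcohol_strict_inequality:
        excess = r.alcohol_units_7d > limit
    else:
        excess = r.alcohol_units_7d >= limit
    return (r.alcohol_freq in cfg.adverse_alcohol_freq, excess)


_COMPOSITE_GRADE = {0: RiskLevel.LOW, 1: RiskLevel.MODERATE, 2: RiskLevel.HIGH}


def grade_factor(
    factor: str, r: Respondent, cfg: Optional[ScoringConfig] = None
) -> Optional[RiskLevel]:
    """Grade one of the five factors for a respondent; ``None`` when any
    required answer is missing.

    The composite factors count adverse sub-answers: diet combines the
    salting habit with vegetable frequency, alcohol combines use frequency
    with the sex-specific 7-day amount; two adverse sub-answers grade high,
    one moderate, none low.
    """
    cfg = cfg or default_config()
    if factor == "smoking":
        return None if r.smoking is None else cfg.smoking_grades[r.smoking]
    if factor == "bmi":
        bc = bmi_class(r.bmi)
        return None if bc is None else cfg.bmi_grades[bc]
    if factor == "exercise":
        return None if r.exercise is None else cfg.exercise_grades[r.exercise]
    if factor == "diet":
        adverse = _diet_adverse(r, cfg)
        return None if adverse is None else _COMPOSITE_GRADE[sum(adverse)]
    if factor == "alcohol":
        adverse = _alcohol_adverse(r, cfg)
        return None if adverse is None else _COMPOSITE_GRADE[sum(adverse)]
    raise KeyError(f"unknown factor {factor!r}; expected one of {FACTORS}")


def compute_hbsr(r: Respondent, cfg: Optional[ScoringConfig] = None) -> HBSRResult:
    """Score a respondent: per-factor points, total 0-10 and low/high band.

    Under the default ``require_complete`` policy a respondent missing any
    factor gets a missing total and band (complete-case); under
    ``treat_missing_as_low`` missing factors contribute 0 points.
    """
    cfg = cfg or default_config()
    points: dict[str, Optional[int]] = {}
    n_missing = 0
    for factor in FACTORS:
        grade = grade_factor(factor, r, cfg)
        if grade is None:
            points[factor] = None
            n_missing += 1
        else:
            points[factor] = grade.points
    if n_missing and cfg.missing_policy is MissingPolicy.REQUIRE_COMPLETE:
        return HBSRResult(points, None, None, n_missing)
    total = sum(p for p in points.values() if p is not None)
    band = Band.HIGH if total >= cfg.high_band_cutoff else Band.LOW
    return HBSRResult(points, total, band, n_missing)


def score_cohort(cohort: Cohort, cfg: Optional[ScoringConfig] = None) -> list[HBSRResult]:
    cfg = cfg or default_config()
    return [compute_hbsr(r, cfg) for r in cohort]


def score_distribution(
    cohort: Cohort, cfg: Optional[ScoringConfig] = None
) -> tuple[np.ndarray, int]:
    """Counts of complete totals indexed 0..10 plus the missing-score count."""
    counts = np.zeros(SCORE_MAX + 1, dtype=int)
    n_missing = 0
    for res in score_cohort(cohort, cfg):
        if res.total is None:
            n_missing += 1
        else:
            counts[res.total] += 1
    return counts, n_missing
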