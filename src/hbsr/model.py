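"""Questionnaire data model for the case-control health-behavior cohorts.

A cohort is an ordered collection of respondents, each carrying the
demographic covariates (group, age, sex, education, marital status) and the
behavioral answers used by the Health Behavior Stroke Risk (HBSR) score:
smoking status, BMI, exercise frequency, vegetable-consumption days per
week, meal-salting habit, alcohol-use frequency and standard drink units
consumed in the last 7 days.  Any behavioral answer may be missing
(``None``); analyses downstream are complete-case per variable.

Cohorts are read from and written to plain CSV with a fixed column schema
and enum tokens (see ``hbsr/data/data_dictionary.json``).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

log = logging.getLogger(__name__)

AGE_MIN = 18
AGE_MAX = 54


class CohortError(ValueError):
    """Raised when a cohort file violates a hard invariant in strict mode."""


class Group(str, enum.Enum):
    PATIENT = "patient"
    CONTROL = "control"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Education(str, enum.Enum):
    BASIC = "basic"
    SECONDARY = "secondary"
    HIGHER = "higher"


class Marital(str, enum.Enum):
    MARRIED_COHABITING = "married_cohabiting"
    SINGLE = "single"
    DIVORCED_WIDOWED = "divorced_widowed"


class Smoking(str, enum.Enum):
    DAILY = "daily"
    OCCASIONAL = "occasional"
    EX_SMOKER = "ex_smoker"  # quit at least one year ago
    NEVER = "never"


class Exercise(str, enum.Enum):
    GE4_PER_WEEK = "ge4_per_week"
    W2_3_PER_WEEK = "w2_3_per_week"
    ONCE_PER_WEEK = "once_per_week"
    M2_3_PER_MONTH = "m2_3_per_month"
    RARE_OR_NONE = "rare_or_none"


class Salting(str, enum.Enum):
    BEFORE_TASTING = "before_tasting"
    WHEN_NEEDED = "when_needed"
    NEVER = "never"


class AlcoholFreq(str, enum.Enum):
    GE2_PER_WEEK = "ge2_per_week"
    ONCE_PER_WEEK = "once_per_week"
    M2_3_PER_MONTH = "m2_3_per_month"
    FEW_PER_YEAR = "few_per_year"
    NONE = "none"


class BmiClass(str, enum.Enum):
    LT25 = "lt25"
    B25_29_9 = "b25_29_9"
    GE30 = "ge30"


class AgeBand(str, enum.Enum):
    B18_44 = "b18_44"
    B45_54 = "b45_54"


def age_band(age: int) -> AgeBand:
    """Assign the two-band age stratification (18-44 vs 45-54, inclusive)."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside supported range {AGE_MIN}-{AGE_MAX}")
    return AgeBand.B18_44 if age <= 44 else AgeBand.B45_54


def bmi_class(bmi: Optional[float]) -> Optional[BmiClass]:
    """Classify BMI into <25 / 25-29.9 / >=30 (kg/m^2); ``None`` passes through.

    Boundaries are closed on the left: 25.0 falls in the middle class and
    30.0 counts as obese.
    """
    if bmi is None:
        return None
    if bmi < 25.0:
        return BmiClass.LT25
    if bmi < 30.0:
        return BmiClass.B25_29_9
    return BmiClass.GE30


@dataclass(frozen=True)
class Respondent:
    """One questionnaire record; behavioral answers may each be missing."""

    id: str
    group: Group
    age: int
    sex: Sex
    education: Education
    marital: Marital
    smoking: Optional[Smoking] = None
    bmi: Optional[float] = None
    exercise: Optional[Exercise] = None
    veg_days: Optional[int] = None  # days/week with vegetables, 0..7
    salting: Optional[Salting] = None
    alcohol_freq: Optional[AlcoholFreq] = None
    alcohol_units_7d: Optional[float] = None  # standard drink units, >=0

    _ENUM_FIELDS = {
        "group": Group,
        "sex": Sex,
        "education": Education,
        "marital": Marital,
        "smoking": Smoking,
        "exercise": Exercise,
        "salting": Salting,
        "alcohol_freq": AlcoholFreq,
    }

    def __post_init__(self) -> None:
        for name, etype in self._ENUM_FIELDS.items():
            v = getattr(self, name)
            if v is not None and not isinstance(v, etype):
                object.__setattr__(self, name, etype(v))  # accept plain tokens
        if not AGE_MIN <= self.age <= AGE_MAX:
            raise ValueError(f"age {self.age} outside {AGE_MIN}-{AGE_MAX}")
        if self.bmi is not None and not 10.0 < self.bmi < 80.0:
            raise ValueError(f"implausible BMI {self.bmi}")
        if self.veg_days is not None and self.veg_days not in range(8):
            raise ValueError(f"veg_days {self.veg_days} outside 0-7")
        if self.alcohol_units_7d is not None and self.alcohol_units_7d < 0:
            raise ValueError(f"negative alcohol units {self.alcohol_units_7d}")

    @property
    def band(self) -> AgeBand:
        return age_band(self.age)

    @property
    def bmi_class(self) -> Optional[BmiClass]:
        return bmi_class(self.bmi)


@dataclass
class Cohort:
    """Ordered collection of respondents with unique ids."""

    respondents: list[Respondent] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.respondents]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate respondent ids within cohort")

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self) -> Iterator[Respondent]:
        return iter(self.respondents)

    def subset(self, pred) -> "Cohort":
        return Cohort([r for r in self.respondents if pred(r)], self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with enum tokens as strings and missing as NaN/None."""
        rows = []
        for r in self.respondents:
            row = {}
            for f in fields(Respondent):
                v = getattr(r, f.name)
                row[f.name] = v.value if isinstance(v, enum.Enum) else v
            rows.append(row)
        cols = [f.name for f in fields(Respondent)]
        return pd.DataFrame(rows, columns=cols)


# --- CSV I/O ----------------------------------------------------------------

_ENUM_COLS: Mapping[str, type] = {
    "group": Group,
    "sex": Sex,
    "education": Education,
    "marital": Marital,
    "smoking": Smoking,
    "exercise": Exercise,
    "salting": Salting,
    "alcohol_freq": AlcoholFreq,
}
_REQUIRED = ("id", "group", "age", "sex", "education", "marital")
_OPTIONAL_BEHAVIOR = (
    "smoking",
    "bmi",
    "exercise",
    "veg_days",
    "salting",
    "alcohol_freq",
    "alcohol_units_7d",
)


def _parse_row(raw: Mapping[str, object], strict: bool) -> Optional[Respondent]:
    def cell(name: str):
        v = raw.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if isinstance(v, str) and v.strip() == "":
            return None
        return v

    kwargs: dict = {}
    for name in _REQUIRED:
        v = cell(name)
        if v is None:
            raise CohortError(f"missing required column value {name!r}")
        kwargs[name] = v
    kwargs["id"] = str(kwargs["id"])
    kwargs["age"] = int(kwargs["age"])
    for name in _OPTIONAL_BEHAVIOR:
        kwargs[name] = cell(name)

    for name, etype in _ENUM_COLS.items():
        if kwargs.get(name) is not None:
            try:
                kwargs[name] = etype(str(kwargs[name]))
            except ValueError:
                raise CohortError(
                    f"unknown {name} token {kwargs[name]!r}"
                ) from None

    # BMI may arrive directly or as height/weight; direct BMI wins.
    height_cm = cell("height_cm")
    weight_kg = cell("weight_kg")
    derived = None
    if height_cm is not None and weight_kg is not None:
        h = float(height_cm) / 100.0
        if h > 0:
            derived = float(weight_kg) / (h * h)
    if kwargs["bmi"] is None:
        kwargs["bmi"] = derived
    elif derived is not None and abs(float(kwargs["bmi"]) - derived) > 0.5:
        log.warning(
            "row %s: reported BMI %.1f differs from height/weight-derived %.1f",
            kwargs["id"], float(kwargs["bmi"]), derived,
        )
    if kwargs["bmi"] is not None:
        kwargs["bmi"] = float(kwargs["bmi"])

    # Binary vegetable category maps onto sentinel day counts (>=6 -> 6, <6 -> 0).
    if kwargs["veg_days"] is not None:
        tok = str(kwargs["veg_days"])
        if tok == "ge6_days":
            kwargs["veg_days"] = 6
        elif tok == "lt6_days":
            kwargs["veg_days"] = 0
        else:
            kwargs["veg_days"] = int(float(tok))
    if kwargs["alcohol_units_7d"] is not None:
        kwargs["alcohol_units_7d"] = float(kwargs["alcohol_units_7d"])

    r = Respondent(**kwargs)
    if (
        r.alcohol_freq is AlcoholFreq.NONE
        and r.alcohol_units_7d is not None
        and r.alcohol_units_7d > 0
    ):
        log.warning(
            "row %s: alcohol_freq=none but %.1f units reported in last 7 days",
            r.id, r.alcohol_units_7d,
        )
    return r


def read_cohort(path: str | Path, strict: bool = False) -> Cohort:
    """Read and validate a cohort CSV.

    Rows violating hard invariants (age outside 18-54, implausible BMI,
    out-of-range answers, unknown enum tokens) raise :class:`CohortError`
    in strict mode and are dropped with a logged warning otherwise.  Blank
    cells become missing values.  Duplicate ids raise in strict mode; in
    non-strict mode later duplicates are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort file lacks required columns {missing_cols}")

    respondents: list[Respondent] = []
    seen: set[str] = set()
    for i, raw in enumerate(df.to_dict("records")):
        try:
            r = _parse_row(raw, strict)
        except (CohortError, ValueError) as exc:
            if strict:
                raise CohortError(f"{path.name} row {i + 2}: {exc}") from exc
            log.warning("%s row %d dropped: %s", path.name, i + 2, exc)
            continue
        if r.id in seen:
            if strict:
                raise CohortError(f"{path.name}: duplicate id {r.id!r}")
            log.warning("%s: dropping duplicate id %r", path.name, r.id)
            continue
        seen.add(r.id)
        respondents.append(r)
    return Cohort(respondents, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the same CSV dialect the reader accepts."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False)


# --- Derived binary high-risk indicators ------------------------------------

INDICATOR_NAMES = (
    "daily_smoking",
    "obesity",
    "low_exercise",
    "salting",
    "low_vegetables",
    "alcohol_weekly",
    "alcohol_excess",
)

_LOW_EXERCISE = frozenset(
    {Exercise.ONCE_PER_WEEK, Exercise.M2_3_PER_MONTH, Exercise.RARE_OR_NONE}
)
_WEEKLY_ALCOHOL = frozenset({AlcoholFreq.GE2_PER_WEEK, AlcoholFreq.ONCE_PER_WEEK})


def high_risk_indicators(r: Respondent, cfg=None) -> dict[str, Optional[bool]]:
    """The seven binary high-risk flags, each ``None`` when its answer is missing.

    Flags: daily smoking; BMI >= 30; exercising less than twice a week;
    salting ready-made meals before tasting; vegetables on fewer than 6
    days/week; drinking alcohol at least weekly; and exceeding the
    sex-specific 7-day unit limit (default: more than 8 units for women,
    16 for men, strict inequality; both limit and comparison live in the
    scoring config).
    """
    from .scoring import ScoringConfig, default_config  # local: avoid cycle

    if cfg is None:
        cfg = default_config()
    out: dict[str, Optional[bool]] = {}
    out["daily_smoking"] = None if r.smoking is None else r.smoking is Smoking.DAILY
    bc = r.bmi_class
    out["obesity"] = None if bc is None else bc is BmiClass.GE30
    out["low_exercise"] = None if r.exercise is None else r.exercise in _LOW_EXERCISE
    out["salting"] = (
        None if r.salting is None else r.salting in cfg.adverse_salting
    )
    out["low_vegetables"] = (
        None if r.veg_days is None else r.veg_days < cfg.veg_days_threshold
    )
    out["alcohol_weekly"] = (
        None if r.alcohol_freq is None else r.alcohol_freq in cfg.adverse_alcohol_freq
    )
    if r.alcohol_units_7d is None:
        out["alcohol_excess"] = None
    else:
        limit = cfg.alcohol_unit_limits[r.sex.value]
        if cfg.alcohol_strict_inequality:
            out["alcohol_excess"] = r.alcohol_units_7d > limit
        else:
            out["alcohol_excess"] = r.alcohol_units_7d >= limit
    return out
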