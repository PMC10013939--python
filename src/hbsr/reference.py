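"""Published case-control prevalence counts used as calibration defaults.

The packaged file ``data/published_counts.csv`` transcribes the study's
baseline prevalence table: per-category respondent counts for seven
behavioral variables, stratified by group (342 stroke patients vs 1789
population-survey controls) and age band (18-44 vs 45-54).  Denominators
are complete-case: the sum of a variable's category counts within a
stratum, which falls short of the stratum size by that variable's missing
answers.  These counts calibrate the synthetic-cohort generator and anchor
the regression tests on printed percentages.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .model import AgeBand, Group

#: printed stratum sizes (questionnaire respondents per group x age band)
STRATUM_N: dict[tuple[str, str], int] = {
    ("patient", "b18_44"): 135,
    ("control", "b18_44"): 1263,
    ("patient", "b45_54"): 206,
    ("control", "b45_54"): 526,
}

#: behavioral variables in generation order, with their category tokens
VARIABLES: dict[str, tuple[str, ...]] = {
    "smoking": ("daily", "occasional", "ex_smoker", "never"),
    "bmi": ("lt25", "b25_29_9", "ge30"),
    "exercise": (
        "ge4_per_week",
        "w2_3_per_week",
        "once_per_week",
        "m2_3_per_month",
        "rare_or_none",
    ),
    "vegetables": ("ge6_days", "lt6_days"),
    "salting": ("before_tasting", "when_needed", "never"),
    "alcohol_freq": (
        "ge2_per_week",
        "once_per_week",
        "m2_3_per_month",
        "few_per_year",
        "none",
    ),
    "alcohol_7d": ("excess", "no_excess"),
}


@lru_cache(maxsize=1)
def published_counts() -> pd.DataFrame:
    """Tidy counts: variable, category, group, band, count."""
    with resources.files("hbsr.data").joinpath("published_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def stratum_counts(variable: str, group: str | Group, band: str | AgeBand) -> pd.Series:
    """Category counts for one variable in one group x band stratum, in
    canonical category order."""
    group = Group(group).value
    band = AgeBand(band).value
    df = published_counts()
    sub = df[(df.variable == variable) & (df.group == group) & (df.band == band)]
    if sub.empty:
        raise KeyError(f"no published counts for {variable} / {group} / {band}")
    s = sub.set_index("category")["count"]
    return s.reindex(list(VARIABLES[variable]))


def complete_case_denominator(variable: str, group: str | Group, band: str | AgeBand) -> int:
    return int(stratum_counts(variable, group, band).sum())


def pooled_counts(variable: str, group: str | Group) -> pd.Series:
    """Category counts pooled over both age bands for one group."""
    a = stratum_counts(variable, group, AgeBand.B18_44)
    b = stratum_counts(variable, group, AgeBand.B45_54)
    return a + b
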