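"""Seedable synthetic patient/control cohort generator.

Emulates the study's two cohorts without individual-level data: behavioral
category marginals per group x age band default to the published prevalence
table (count / complete-case denominator), covariate mixes default to the
published demographics (62% vs 41% male; median ages 47 [IQR 39-51] vs 37
[IQR 28-46]; 20% vs 34% higher education; 15% vs 22% single), and
missingness is injected completely at random at each variable's implied
published rate.

Inter-behavior dependence uses a Gaussian copula: a latent multivariate
normal draw per respondent is thresholded at each variable's marginal
quantiles, so marginals are preserved exactly in expectation for any valid
latent correlation matrix (identity by default -- the joint distribution is
unpublished).

Randomness comes from one root seed split into documented per-purpose
streams (``numpy.random.SeedSequence.spawn``), so adding a stream at the
end of the list leaves earlier draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import stats as sps

from .model import AgeBand, Cohort, Group, Respondent, age_band
from .reference import STRATUM_N, VARIABLES, stratum_counts

_GROUPS = ("patient", "control")
_BANDS = ("b18_44", "b45_54")
_BEHAVIOR_VARS = tuple(VARIABLES)  # canonical order; latent dims follow it

#: per-group stream order; append only (keeps earlier draws stable)
_STREAMS = (
    "age",
    "sex",
    "education",
    "marital",
    "latent",
    "miss_smoking",
    "miss_bmi",
    "miss_exercise",
    "miss_vegetables",
    "miss_salting",
    "miss_alcohol_freq",
    "miss_alcohol_7d",
    "bmi_value",
    "veg_value",
    "alcohol_units",
)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class MarginalSpec:
    """Category probabilities and missingness per group x band per variable."""

    probs: Mapping[tuple[str, str], Mapping[str, np.ndarray]]
    missingness: Mapping[tuple[str, str], Mapping[str, float]]

    def validate(self) -> None:
        for key, table in self.probs.items():
            for var, p in table.items():
                p = np.asarray(p, dtype=float)
                if len(p) != len(VARIABLES[var]):
                    raise SpecError(f"{key}/{var}: wrong number of categories")
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise SpecError(f"{key}/{var}: probabilities must sum to 1")
        for key, table in self.missingness.items():
            for var, rate in table.items():
                if not 0.0 <= rate < 1.0:
                    raise SpecError(f"{key}/{var}: missingness rate outside [0,1)")


@dataclass(frozen=True)
class CovariateSpec:
    """Group sizes and demographic mixes.

    ``age_bands`` gives, per group, (lo, hi, weight) pieces; ages are
    sampled uniformly on the integers of the chosen piece.  The default
    pieces are the quartile bands implied by the published median/IQR.
    """

    n: Mapping[str, int]
    male_frac: Mapping[str, float]
    age_bands: Mapping[str, Sequence[tuple[int, int, float]]]
    education: Mapping[str, np.ndarray]  # basic, secondary, higher
    marital: Mapping[str, np.ndarray]  # married_cohabiting, single, divorced_widowed

    def validate(self) -> None:
        for g in _GROUPS:
            if self.n[g] < 1:
                raise SpecError("group sizes must be >= 1")
            if not 0.0 <= self.male_frac[g] <= 1.0:
                raise SpecError("male fraction outside [0,1]")
            for probs in (self.education[g], self.marital[g]):
                p = np.asarray(probs, dtype=float)
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise SpecError("covariate probabilities must sum to 1")
            w = sum(w for _, _, w in self.age_bands[g])
            if abs(w - 1.0) > 1e-9:
                raise SpecError("age-band weights must sum to 1")


@dataclass(frozen=True)
class DependenceSpec:
    """Latent pairwise correlation over the seven behavioral variables."""

    corr: np.ndarray = field(default_factory=lambda: np.eye(len(_BEHAVIOR_VARS)))

    def validate(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        k = len(_BEHAVIOR_VARS)
        if c.shape != (k, k):
            raise SpecError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise SpecError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise SpecError("correlation matrix is not positive semi-definite")


def default_table1_spec() -> tuple[MarginalSpec, CovariateSpec]:
    """Defaults calibrated to the published prevalence table and demographics."""
    probs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    miss: dict[tuple[str, str], dict[str, float]] = {}
    for g in _GROUPS:
        for b in _BANDS:
            n_stratum = STRATUM_N[(g, b)]
            probs[(g, b)] = {}
            miss[(g, b)] = {}
            for var in _BEHAVIOR_VARS:
                counts = stratum_counts(var, g, b).to_numpy(dtype=float)
                denom = counts.sum()
                probs[(g, b)][var] = counts / denom
                miss[(g, b)][var] = 1.0 - denom / n_stratum
    marginals = MarginalSpec(probs, miss)

    covariates = CovariateSpec(
        n={"patient": 342, "control": 1789},
        male_frac={"patient": 0.62, "control": 0.41},
        age_bands={
            # quartile pieces: median 47, IQR 39-51 (patients); 37, 28-46 (controls)
            "patient": ((18, 38, 0.25), (39, 46, 0.25), (47, 50, 0.25), (51, 54, 0.25)),
            "control": ((18, 27, 0.25), (28, 36, 0.25), (37, 45, 0.25), (46, 54, 0.25)),
        },
        education={
            # only the higher-education shares are published (20% vs 34%);
            # the basic/secondary split is a fixed package default
            "patient": np.array([0.25, 0.55, 0.20]),
            "control": np.array([0.15, 0.51, 0.34]),
        },
        marital={
            # only the single shares are published (15% vs 22%)
            "patient": np.array([0.65, 0.15, 0.20]),
            "control": np.array([0.62, 0.22, 0.16]),
        },
    )
    marginals.validate()
    covariates.validate()
    return marginals, covariates


# --- generation ---------------------------------------------------------------

_BMI_RANGES = {"lt25": (18.5, 25.0), "b25_29_9": (25.0, 30.0), "ge30": (30.0, 40.0)}
_UNIT_LIMITS = {"female": 8.0, "male": 16.0}


def _categorical_from_latent(
    u: np.ndarray, bands: np.ndarray, probs_by_band: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Map uniform latent quantiles to category indices, thresholds per band."""
    idx = np.zeros(len(u), dtype=int)
    for b in _BANDS:
        sel = bands == b
        if not sel.any():
            continue
        cum = np.cumsum(np.asarray(probs_by_band[b], dtype=float))
        cum[-1] = 1.0  # guard float drift at the top
        idx[sel] = np.searchsorted(cum, u[sel], side="left")
    return idx


def _generate_group(
    group: str,
    marginals: MarginalSpec,
    covariates: CovariateSpec,
    chol: np.ndarray,
    seed_seq: np.random.SeedSequence,
) -> list[Respondent]:
    n = covariates.n[group]
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, seed_seq.spawn(len(_STREAMS)))
    }

    # ages: pick a quartile piece, then a uniform integer within it
    pieces = covariates.age_bands[group]
    weights = np.array([w for _, _, w in pieces])
    piece_idx = rngs["age"].choice(len(pieces), size=n, p=weights / weights.sum())
    lows = np.array([lo for lo, _, _ in pieces])[piece_idx]
    highs = np.array([hi for _, hi, _ in pieces])[piece_idx]
    ages = rngs["age"].integers(lows, highs + 1)
    bands = np.array([age_band(int(a)).value for a in ages])

    sexes = np.where(rngs["sex"].random(n) < covariates.male_frac[group], "male", "female")
    edu_tokens = np.array(["basic", "secondary", "higher"])
    edu = edu_tokens[rngs["education"].choice(3, size=n, p=np.asarray(covariates.education[group], dtype=float))]
    mar_tokens = np.array(["married_cohabiting", "single", "divorced_widowed"])
    mar = mar_tokens[rngs["marital"].choice(3, size=n, p=np.asarray(covariates.marital[group], dtype=float))]

    # Gaussian-copula latent draw over the behavioral variables
    z = rngs["latent"].standard_normal((n, len(_BEHAVIOR_VARS))) @ chol.T
    u = sps.norm.cdf(z)

    cats: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for j, var in enumerate(_BEHAVIOR_VARS):
        probs_by_band = {b: marginals.probs[(group, b)][var] for b in _BANDS}
        idx = _categorical_from_latent(u[:, j], bands, probs_by_band)
        cats[var] = np.array(VARIABLES[var])[idx]
        rates = np.array([marginals.missingness[(group, b)][var] for b in _BANDS])
        rate_per_row = rates[(bands == "b45_54").astype(int)]
        observed[var] = rngs[f"miss_{var}"].random(n) >= rate_per_row

    # continuous refinements consistent with the drawn categories
    bmi_u = rngs["bmi_value"].random(n)
    lo = np.array([_BMI_RANGES[c][0] for c in cats["bmi"]])
    hi = np.array([_BMI_RANGES[c][1] for c in cats["bmi"]])
    bmi_vals = np.round(lo + bmi_u * (hi - lo), 1)
    # rounding must not cross a class boundary
    bmi_vals = np.clip(bmi_vals, lo, np.nextafter(hi, -np.inf))

    veg_u = rngs["veg_value"].random(n)
    veg_vals = np.where(
        cats["vegetables"] == "ge6_days",
        6 + (veg_u * 2).astype(int),
        (veg_u * 6).astype(int),
    )

    unit_u = rngs["alcohol_units"].random(n)
    limits = np.array([_UNIT_LIMITS[s] for s in sexes])
    excess_units = limits + 0.5 + unit_u * 10.0
    modest_units = unit_u * (limits - 0.2)  # margin keeps rounding below the limit
    units = np.where(cats["alcohol_7d"] == "excess", excess_units, modest_units)
    units = np.where(
        (cats["alcohol_7d"] == "no_excess") & (cats["alcohol_freq"] == "none"),
        0.0,
        units,
    )
    units = np.round(units, 1)

    from .model import AlcoholFreq, Education, Exercise, Marital, Salting, Sex, Smoking

    prefix = "pat" if group == "patient" else "con"
    out = []
    for i in range(n):
        out.append(
            Respondent(
                id=f"{prefix}-{i:06d}",
                group=Group(group),
                age=int(ages[i]),
                sex=Sex(str(sexes[i])),
                education=Education(str(edu[i])),
                marital=Marital(str(mar[i])),
                smoking=Smoking(str(cats["smoking"][i])) if observed["smoking"][i] else None,
                bmi=float(bmi_vals[i]) if observed["bmi"][i] else None,
                exercise=Exercise(str(cats["exercise"][i])) if observed["exercise"][i] else None,
                veg_days=int(veg_vals[i]) if observed["vegetables"][i] else None,
                salting=Salting(str(cats["salting"][i])) if observed["salting"][i] else None,
                alcohol_freq=AlcoholFreq(str(cats["alcohol_freq"][i]))
                if observed["alcohol_freq"][i]
                else None,
                alcohol_units_7d=float(units[i]) if observed["alcohol_7d"][i] else None,
            )
        )
    return out


def generate_cohort(
    marginals: Optional[MarginalSpec] = None,
    covariates: Optional[CovariateSpec] = None,
    dependence: Optional[DependenceSpec] = None,
    seed: int = 0,
) -> Cohort:
    """Generate a combined patient+control cohort, deterministic given seed.

    Continuous values are drawn inside their target category (BMI within
    its class, 7-day units on the correct side of the sex-specific limit,
    vegetable days on the correct side of 6), so deriving the category back
    from the continuous value recovers the drawn category exactly.
    """
    if marginals is None or covariates is None:
        m_default, c_default = default_table1_spec()
        marginals = marginals or m_default
        covariates = covariates or c_default
    dependence = dependence or DependenceSpec()
    marginals.validate()
    covariates.validate()
    dependence.validate()

    corr = np.asarray(dependence.corr, dtype=float)
    # PSD-safe factor (eigh handles semi-definite matrices Cholesky rejects)
    w, v = np.linalg.eigh(corr)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    root = np.random.SeedSequence(seed)
    group_seqs = dict(zip(_GROUPS, root.spawn(len(_GROUPS))))
    respondents: list[Respondent] = []
    for g in _GROUPS:
        respondents.extend(_generate_group(g, marginals, covariates, chol, group_seqs[g]))
    return Cohort(respondents, provenance=f"synthetic(seed={seed})")


def split_groups(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Split a combined cohort into (patients, controls)."""
    pats = cohort.subset(lambda r: r.group is Group.PATIENT)
    cons = cohort.subset(lambda r: r.group is Group.CONTROL)
    return pats, cons
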