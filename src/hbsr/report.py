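"""End-to-end case-control analysis and report rendering.

Produces the study's deliverables from two validated cohorts:

* a stratified prevalence table (every behavioral category by group and
  age band, complete-case denominators, pooled z-tests with per-block
  Bonferroni marks),
* crude and adjusted odds ratios for the seven binary high-risk
  indicators and for the high HBSR band (three model tiers: crude,
  age+sex, age+sex+education+marital),
* the mean-score comparison with the high-band prevalence overall and
  stratified by sex and age band, plus the 0-10 score distributions.

Every rendered number is recomputable from the emitted tidy CSVs; the
text report is a pure view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    AgeBand,
    BmiClass,
    Cohort,
    Group,
    Respondent,
    Sex,
    high_risk_indicators,
)
from .reference import VARIABLES
from .scoring import Band, ScoringConfig, default_config, score_cohort, score_distribution
from .stats import (
    MeanScoreComparison,
    ORResult,
    bonferroni,
    fit_logistic,
    mean_score_ttest,
    prevalence_cell,
    two_proportion_z,
)

ALPHA = 0.05


def variable_category(r: Respondent, variable: str, cfg: ScoringConfig) -> Optional[str]:
    """The respondent's category token for a prevalence-table variable,
    ``None`` when the underlying answer is missing."""
    if variable == "smoking":
        return None if r.smoking is None else r.smoking.value
    if variable == "bmi":
        bc = r.bmi_class
        return None if bc is None else bc.value
    if variable == "exercise":
        return None if r.exercise is None else r.exercise.value
    if variable == "vegetables":
        if r.veg_days is None:
            return None
        return "ge6_days" if r.veg_days >= cfg.veg_days_threshold else "lt6_days"
    if variable == "salting":
        return None if r.salting is None else r.salting.value
    if variable == "alcohol_freq":
        return None if r.alcohol_freq is None else r.alcohol_freq.value
    if variable == "alcohol_7d":
        if r.alcohol_units_7d is None:
            return None
        limit = cfg.alcohol_unit_limits[r.sex.value]
        if cfg.alcohol_strict_inequality:
            return "excess" if r.alcohol_units_7d > limit else "no_excess"
        return "excess" if r.alcohol_units_7d >= limit else "no_excess"
    raise KeyError(f"unknown variable {variable!r}")


def _block_family_size(n_categories: int) -> int:
    # binary blocks print one test; larger blocks one per category
    return n_categories if n_categories > 2 else 1


def build_table1(
    patients: Cohort, controls: Cohort, cfg: Optional[ScoringConfig] = None
) -> pd.DataFrame:
    """Stratified prevalence table with pooled z-tests and Bonferroni marks.

    One row per variable x category x age band; denominators are
    complete-case within group x band.  ``p_adjusted`` multiplies the raw
    p by the variable block's family size (number of categories, or 1 for
    binary blocks); ``significant`` marks adjusted p < 0.05.
    """
    cfg = cfg or default_config()
    rows = []
    for variable, categories in VARIABLES.items():
        m = _block_family_size(len(categories))
        for band in AgeBand:
            tallies = {}
            for label, cohort in (("patient", patients), ("control", controls)):
                sub = [r for r in cohort if r.band is band]
                cats = [variable_category(r, variable, cfg) for r in sub]
                cats = [c for c in cats if c is not None]
                tallies[label] = (
                    {c: cats.count(c) for c in categories},
                    len(cats),
                )
            (pc, pn), (cc, cn) = tallies["patient"], tallies["control"]
            if pn == 0 or cn == 0:
                raise ValueError(
                    f"empty stratum for {variable} in band {band.value}"
                )
            for cat in categories:
                test = two_proportion_z(pc[cat], pn, cc[cat], cn)
                p_adj = bonferroni([test.p], m)[0]
                pcell = prevalence_cell(pc[cat], pn)
                ccell = prevalence_cell(cc[cat], cn)
                rows.append(
                    {
                        "variable": variable,
                        "category": cat,
                        "band": band.value,
                        "patient_count": pcell.count,
                        "patient_denominator": pcell.denominator,
                        "patient_pct": pcell.pct,
                        "control_count": ccell.count,
                        "control_denominator": ccell.denominator,
                        "control_pct": ccell.pct,
                        "z": test.statistic,
                        "p": test.p,
                        "p_adjusted": p_adj,
                        "significant": p_adj < ALPHA,
                    }
                )
    return pd.DataFrame(rows)


# --- odds ratios --------------------------------------------------------------

MODEL_TIERS: dict[str, tuple[str, ...]] = {
    "crude": (),
    "age_sex": ("age", "sex"),
    "full": ("age", "sex", "education", "marital"),
}


def _covariate_columns(r: Respondent) -> dict[str, float]:
    return {
        "age": float(r.age),
        "male": 1.0 if r.sex is Sex.MALE else 0.0,
        # reference levels: higher education, married/cohabiting
        "edu_basic": 1.0 if r.education.value == "basic" else 0.0,
        "edu_secondary": 1.0 if r.education.value == "secondary" else 0.0,
        "single": 1.0 if r.marital.value == "single" else 0.0,
        "divorced_widowed": 1.0 if r.marital.value == "divorced_widowed" else 0.0,
    }


_TIER_DESIGN = {
    "crude": (),
    "age_sex": ("age", "male"),
    "full": ("age", "male", "edu_basic", "edu_secondary", "single", "divorced_widowed"),
}


def _exposure_value(r: Respondent, exposure: str, cfg: ScoringConfig, score) -> Optional[float]:
    if exposure == "high_hbsr":
        if score is None or score.band is None:
            return None
        return 1.0 if score.band is Band.HIGH else 0.0
    flag = high_risk_indicators(r, cfg)[exposure]
    return None if flag is None else float(flag)


OR_EXPOSURES = (
    "daily_smoking",
    "obesity",
    "low_exercise",
    "salting",
    "low_vegetables",
    "alcohol_weekly",
    "alcohol_excess",
    "high_hbsr",
)


def run_or_analysis(
    patients: Cohort, controls: Cohort, cfg: Optional[ScoringConfig] = None
) -> pd.DataFrame:
    """Crude and adjusted ORs (patient vs control) for the seven binary
    indicators and the high HBSR band.

    Complete-case per model: rows missing the exposure are dropped; the
    demographic covariates are always present by the data model.  Columns:
    exposure, model, or, ci_low, ci_high, n_used.
    """
    from .scoring import compute_hbsr

    cfg = cfg or default_config()
    pooled = list(patients) + list(controls)
    score_list = [compute_hbsr(r, cfg) for r in pooled]
    outcome_all = np.array([1.0 if r.group is Group.PATIENT else 0.0 for r in pooled])

    rows = []
    for exposure in OR_EXPOSURES:
        expo = np.array(
            [
                v if (v := _exposure_value(r, exposure, cfg, s)) is not None else np.nan
                for r, s in zip(pooled, score_list)
            ]
        )
        covs = pd.DataFrame([_covariate_columns(r) for r in pooled])
        for tier, design_cols in _TIER_DESIGN.items():
            X = np.column_stack([expo] + [covs[c].to_numpy() for c in design_cols]) \
                if design_cols else expo[:, None]
            names = [exposure] + list(design_cols)
            fit = fit_logistic(outcome_all, X, names=names)
            res = fit.odds_ratios(covariates=MODEL_TIERS[tier])[0]
            rows.append(
                {
                    "exposure": exposure,
                    "model": tier,
                    "odds_ratio": res.or_estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_used": fit.n_used,
                }
            )
    return pd.DataFrame(rows)


# --- score analysis -----------------------------------------------------------

@dataclass
class ScoreAnalysis:
    comparison: MeanScoreComparison
    high_band: pd.DataFrame  # stratum, counts, pcts, p, p_adjusted
    distribution: pd.DataFrame  # score 0..10 x group counts (+missing)


_STRATA = (
    ("overall", lambda r: True),
    ("male", lambda r: r.sex is Sex.MALE),
    ("female", lambda r: r.sex is Sex.FEMALE),
    ("age_18_44", lambda r: r.band is AgeBand.B18_44),
    ("age_45_54", lambda r: r.band is AgeBand.B45_54),
)


def run_score_analysis(
    patients: Cohort, controls: Cohort, cfg: Optional[ScoringConfig] = None, welch: bool = True
) -> ScoreAnalysis:
    """Mean HBSR comparison, high-band prevalence (overall and stratified by
    sex and age band) and the per-group 0-10 score distributions.

    The four sex/age strata share one Bonferroni family (m=4); the overall
    test is reported unadjusted as a single planned comparison.
    """
    cfg = cfg or default_config()
    pat_scores = score_cohort(patients, cfg)
    con_scores = score_cohort(controls, cfg)
    pat_totals = [s.total for s in pat_scores if s.total is not None]
    con_totals = [s.total for s in con_scores if s.total is not None]
    if not pat_totals or not con_totals:
        raise ValueError("all scores missing in one group")
    comparison = mean_score_ttest(pat_totals, con_totals, welch=welch)

    rows = []
    raw_ps = {}
    for name, pred in _STRATA:
        cells = {}
        for label, cohort, results in (
            ("patient", patients, pat_scores),
            ("control", controls, con_scores),
        ):
            pairs = [(r, s) for r, s in zip(cohort, results) if pred(r) and s.band is not None]
            n_high = sum(1 for _, s in pairs if s.band is Band.HIGH)
            cells[label] = (n_high, len(pairs))
        (ph, pn), (ch, cn) = cells["patient"], cells["control"]
        if pn == 0 or cn == 0:
            continue
        test = two_proportion_z(ph, pn, ch, cn)
        raw_ps[name] = test.p
        rows.append(
            {
                "stratum": name,
                "patient_high": ph,
                "patient_n": pn,
                "patient_pct": prevalence_cell(ph, pn).pct if pn else math.nan,
                "control_high": ch,
                "control_n": cn,
                "control_pct": prevalence_cell(ch, cn).pct if cn else math.nan,
                "p": test.p,
            }
        )
    high = pd.DataFrame(rows)
    m_strata = max(1, len(high) - 1)  # sex/age strata family; overall unadjusted
    high["p_adjusted"] = [
        row.p if row.stratum == "overall" else bonferroni([row.p], m_strata)[0]
        for row in high.itertuples()
    ]

    pat_counts, pat_missing = score_distribution(patients, cfg)
    con_counts, con_missing = score_distribution(controls, cfg)
    dist = pd.DataFrame(
        {
            "score": list(range(11)) + ["missing"],
            "patients": list(pat_counts) + [pat_missing],
            "controls": list(con_counts) + [con_missing],
        }
    )
    return ScoreAnalysis(comparison, high, dist)


# --- report assembly ----------------------------------------------------------

@dataclass
class StudyReport:
    table1: pd.DataFrame
    odds_ratios: pd.DataFrame
    scores: ScoreAnalysis


def run_study(
    patients: Cohort, controls: Cohort, cfg: Optional[ScoringConfig] = None
) -> StudyReport:
    cfg = cfg or default_config()
    return StudyReport(
        table1=build_table1(patients, controls, cfg),
        odds_ratios=run_or_analysis(patients, controls, cfg),
        scores=run_score_analysis(patients, controls, cfg),
    )


def format_p(p: float, significant: bool = False) -> str:
    """Three-decimal display; values below .0005 print as .000, with an
    asterisk when the adjusted test is significant."""
    s = f"{p:.3f}"
    if s.startswith("0"):
        s = s[1:]
    return s + ("*" if significant else "")


def render_report(report: StudyReport) -> str:
    lines = ["Prevalence by group and age band", "=" * 60]
    for (variable, band), sub in report.table1.groupby(["variable", "band"], sort=False):
        lines.append(f"\n{variable} [{band}]")
        for row in sub.itertuples():
            lines.append(
                f"  {row.category:16s} "
                f"{row.patient_count:>4d} ({row.patient_pct:4.1f})   "
                f"{row.control_count:>4d} ({row.control_pct:4.1f})   "
                f"p={format_p(row.p, row.significant)}"
            )
    lines += ["", "Odds ratios (patient vs control)", "=" * 60]
    for row in report.odds_ratios.itertuples():
        lines.append(
            f"  {row.exposure:16s} {row.model:8s} "
            f"OR {row.odds_ratio:5.2f} [{row.ci_low:.2f}-{row.ci_high:.2f}] "
            f"n={row.n_used}"
        )
    c = report.scores.comparison
    lines += [
        "",
        "HBSR score",
        "=" * 60,
        f"  patients  mean {c.mean1:.1f} [CI {c.ci1[0]:.1f}-{c.ci1[1]:.1f}, SD {c.sd1:.2f}] n={c.n1}",
        f"  controls  mean {c.mean2:.1f} [CI {c.ci2[0]:.1f}-{c.ci2[1]:.1f}, SD {c.sd2:.2f}] n={c.n2}",
        f"  {c.method}: t={c.t:.2f}, p={format_p(c.p)}",
        "",
        "High band (score 6-10) prevalence",
    ]
    for row in report.scores.high_band.itertuples():
        lines.append(
            f"  {row.stratum:10s} {row.patient_pct:4.1f}% vs {row.control_pct:4.1f}%  "
            f"p={format_p(row.p, row.p_adjusted < ALPHA)}"
        )
    return "\n".join(lines) + "\n"


def write_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write table1.csv, odds_ratios.csv, score_summary.csv,
    score_distribution.csv and report.txt; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = report.scores.comparison
    summary = pd.DataFrame(
        [
            {"group": "patients", "n": c.n1, "mean": c.mean1, "sd": c.sd1,
             "ci_low": c.ci1[0], "ci_high": c.ci1[1]},
            {"group": "controls", "n": c.n2, "mean": c.mean2, "sd": c.sd2,
             "ci_low": c.ci2[0], "ci_high": c.ci2[1]},
        ]
    )
    summary["t"] = c.t
    summary["p"] = c.p
    paths = []
    for name, df in (
        ("table1.csv", report.table1),
        ("odds_ratios.csv", report.odds_ratios),
        ("score_summary.csv", summary),
        ("score_distribution.csv", report.scores.distribution),
        ("high_band.csv", report.scores.high_band),
    ):
        p = outdir / name
        df.to_csv(p, index=False)
        paths.append(p)
    txt = outdir / "report.txt"
    txt.write_text(render_report(report))
    paths.append(txt)
    return paths
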