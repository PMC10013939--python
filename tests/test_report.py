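"""End-to-end pipeline: prevalence table, OR tiers, score analysis, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from hbsr.cli import main as cli_main
from hbsr.model import Cohort, Group
from hbsr.report import (
    build_table1,
    run_or_analysis,
    run_score_analysis,
    run_study,
    variable_category,
    write_report,
)
from hbsr.scoring import compute_hbsr
from hbsr.simulate import generate_cohort, split_groups
from hbsr.stats import ContingencyTable2x2, crude_or

from conftest import make_respondent


def engineered_smoking_cohorts():
    """Patient 18-44 stratum with 62/133 daily smokers (2 missing answers)."""
    pats = []
    for i in range(135):
        if i < 62:
            smoking = "daily"
        elif i < 133:
            smoking = "never"
        else:
            smoking = None
        pats.append(make_respondent(f"p{i}", group=Group.PATIENT, age=30, smoking=smoking))
    cons = [
        make_respondent(f"c{i}", group=Group.CONTROL, age=30,
                        smoking="daily" if i < 254 else "never")
        for i in range(1249)
    ]
    # one respondent per group in the other band so no stratum is empty
    pats.append(make_respondent("p_old", group=Group.PATIENT, age=50))
    cons.append(make_respondent("c_old", group=Group.CONTROL, age=50))
    return Cohort(pats), Cohort(cons)


class TestBuildTable1:
    def test_engineered_cell_renders_printed_percentage(self, cfg):
        pats, cons = engineered_smoking_cohorts()
        df = build_table1(pats, cons, cfg)
        row = df[(df.variable == "smoking") & (df.category == "daily") & (df.band == "b18_44")].iloc[0]
        assert row.patient_count == 62
        assert row.patient_denominator == 133
        assert row.patient_pct == 46.6
        assert row.control_pct == 20.3

    def test_identical_groups_have_no_significance_marks(self, cfg):
        cohort = generate_cohort(seed=2)
        pats, _ = split_groups(cohort)
        # controls are a copy of the patients under new ids
        clones = [
            make_respondent(f"x{i}", group=Group.CONTROL, age=r.age, sex=r.sex,
                            smoking=r.smoking, bmi=r.bmi, exercise=r.exercise,
                            veg_days=r.veg_days, salting=r.salting,
                            alcohol_freq=r.alcohol_freq,
                            alcohol_units_7d=r.alcohol_units_7d)
            for i, r in enumerate(pats)
        ]
        df = build_table1(pats, Cohort(clones), cfg)
        assert not df.significant.any()
        assert (df.p == 1.0).all()

    def test_cells_match_independent_recount(self, cfg):
        cohort = generate_cohort(seed=6)
        pats, cons = split_groups(cohort)
        df = build_table1(pats, cons, cfg)
        for row in df.sample(20, random_state=0).itertuples():
            source = pats if True else None
            for label, source in (("patient", pats), ("control", cons)):
                count = denom = 0
                for r in source:  # independent per-respondent tally
                    if r.band.value != row.band:
                        continue
                    cat = variable_category(r, row.variable, cfg)
                    if cat is None:
                        continue
                    denom += 1
                    count += cat == row.category
                assert getattr(row, f"{label}_count") == count
                assert getattr(row, f"{label}_denominator") == denom

    def test_empty_stratum_raises(self, cfg):
        young_only = Cohort([make_respondent("a", age=20)])
        with pytest.raises(ValueError, match="empty stratum"):
            build_table1(young_only, young_only, cfg)


class TestOrAnalysis:
    def test_crude_tier_equals_contingency_or(self, cfg):
        cohort = generate_cohort(seed=4)
        pats, cons = split_groups(cohort)
        df = run_or_analysis(pats, cons, cfg)
        # rebuild the daily-smoking 2x2 by hand
        def flag(r):
            return None if r.smoking is None else r.smoking.value == "daily"
        a = sum(1 for r in pats if flag(r) is True)
        b = sum(1 for r in cons if flag(r) is True)
        c = sum(1 for r in pats if flag(r) is False)
        d = sum(1 for r in cons if flag(r) is False)
        expected = crude_or(ContingencyTable2x2(a, b, c, d))
        row = df[(df.exposure == "daily_smoking") & (df.model == "crude")].iloc[0]
        assert row.odds_ratio == pytest.approx(expected.or_estimate, rel=1e-6)
        assert row.ci_low == pytest.approx(expected.ci_low, rel=1e-4)
        assert row.n_used == a + b + c + d

    def test_adjustment_removes_planted_confounding(self):
        """Exposure with true log-OR 0.9 confounded by sex: the adjusted
        estimate recovers the truth, the crude estimate is biased upward."""
        rng = np.random.default_rng(31)
        n = 20000
        male = rng.binomial(1, 0.5, n)
        p_exp = 1 / (1 + np.exp(-(-1.5 + 2.0 * male)))
        expo = rng.binomial(1, p_exp)
        eta = -1.0 + 0.9 * expo + 1.2 * male
        case = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        from hbsr.stats import fit_logistic

        crude = fit_logistic(case, expo[:, None], names=["exposure"])
        adj = fit_logistic(case, np.column_stack([expo, male]), names=["exposure", "male"])
        assert abs(adj.params[1] - 0.9) < 0.1
        assert crude.params[1] > adj.params[1] + 0.15  # bias in planted direction

    def test_null_exposure_ci_covers_one(self, cfg):
        """Exposure independent of group: 95% CI covers OR=1 in >=93/100 seeds."""
        from hbsr.stats import fit_logistic

        covered = 0
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = 600
            y = np.r_[np.ones(150), np.zeros(450)]
            x = rng.binomial(1, 0.3, n).astype(float)
            res = fit_logistic(y, x, names=["e"]).odds_ratios()[0]
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 93

    def test_all_tiers_reported_for_all_exposures(self, cfg):
        cohort = generate_cohort(seed=10)
        pats, cons = split_groups(cohort)
        df = run_or_analysis(pats, cons, cfg)
        assert set(df.model) == {"crude", "age_sex", "full"}
        assert len(df) == 8 * 3
        assert (df.ci_low <= df.odds_ratio).all() and (df.odds_ratio <= df.ci_high).all()


class TestScoreAnalysis:
    def test_identical_cohorts_mean_difference_zero(self, cfg):
        cohort = generate_cohort(seed=14)
        pats, _ = split_groups(cohort)
        res = run_score_analysis(pats, pats, cfg)
        assert res.comparison.mean1 == res.comparison.mean2
        assert res.comparison.p == 1.0
        assert (res.high_band.p == 1.0).all()

    def test_hand_built_cohort_matches_hand_computation(self, cfg):
        # worked example: four respondents with known factor grades
        a = make_respondent("a")  # all low -> 0
        b = make_respondent("b", smoking="daily", bmi=32.0)  # 2+2 -> 4
        c = make_respondent("c", exercise="once_per_week", veg_days=3)  # 1+1 -> 2
        d = make_respondent(
            "d", smoking="daily", bmi=32.0, exercise="rare_or_none",
            veg_days=0, salting="before_tasting",
            alcohol_freq="ge2_per_week", alcohol_units_7d=20.0,
        )  # maximum -> 10
        totals = [compute_hbsr(r, cfg).total for r in (a, b, c, d)]
        assert totals == [0, 4, 2, 10]
        cohort = Cohort([a, b, c, d])
        res = run_score_analysis(cohort, cohort, cfg)
        assert res.comparison.mean1 == pytest.approx(4.0)
        assert res.distribution.set_index("score").patients.loc[[0, 2, 4, 10]].tolist() == [1, 1, 1, 1]

    def test_distribution_counts_conserve_sample_size(self, cfg):
        cohort = generate_cohort(seed=19)
        pats, cons = split_groups(cohort)
        res = run_score_analysis(pats, cons, cfg)
        dist = res.distribution.set_index("score")
        assert dist.patients.sum() == len(pats)
        assert dist.controls.sum() == len(cons)

    def test_strata_present(self, cfg):
        cohort = generate_cohort(seed=19)
        pats, cons = split_groups(cohort)
        res = run_score_analysis(pats, cons, cfg)
        assert list(res.high_band.stratum) == ["overall", "male", "female", "age_18_44", "age_45_54"]
        assert (res.high_band.p_adjusted >= res.high_band.p - 1e-12).all()


class TestCli:
    def test_simulate_then_analyze_round_trip(self, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "cohort.csv"
        res = runner.invoke(cli_main, ["simulate", "--seed", "1", "--out", str(out_csv)])
        assert res.exit_code == 0, res.output
        out_dir = tmp_path / "report"
        res = runner.invoke(cli_main, ["analyze", "--cohort", str(out_csv), "--out", str(out_dir)])
        assert res.exit_code == 0, res.output
        for name in ("table1.csv", "odds_ratios.csv", "score_summary.csv",
                     "score_distribution.csv", "report.txt"):
            assert (out_dir / name).exists()
        summary = pd.read_csv(out_dir / "score_summary.csv")
        means = dict(zip(summary.group, summary["mean"]))
        assert means["patients"] > means["controls"]  # end-to-end direction

    def test_score_subcommand(self, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "cohort.csv"
        runner.invoke(cli_main, ["simulate", "--seed", "2", "--out", str(out_csv)])
        scored = tmp_path / "scored.csv"
        res = runner.invoke(cli_main, ["score", "--cohort", str(out_csv), "--out", str(scored)])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(scored)
        complete = df.total.dropna()
        assert complete.between(0, 10).all()

    def test_missing_input_file_is_data_error(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["score", "--cohort", str(tmp_path / "nope.csv"), "--out", str(tmp_path / "o.csv")]
        )
        assert res.exit_code == 1
        assert "Error" in res.output

    def test_usage_error_exit_code(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["analyze", "--out", "x"])
        assert res.exit_code == 2

    def test_report_is_recomputable_view(self, tmp_path, cfg):
        cohort = generate_cohort(seed=9)
        pats, cons = split_groups(cohort)
        report = run_study(pats, cons, cfg)
        write_report(report, tmp_path)
        df = pd.read_csv(tmp_path / "table1.csv")
        # every percentage cell reproduces from its own count/denominator
        recomputed = (100 * df.patient_count / df.patient_denominator).round(1)
        assert np.allclose(df.patient_pct, recomputed, atol=0.051)
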