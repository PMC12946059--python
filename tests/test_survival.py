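"""Tests of the survival statistics: KM, log-rank, Cox, Schoenfeld/PH,
time-varying Cox, RMST, combined score, LRT, BH, cohort comparison."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import proportional_hazard_test

import ihcstrat as ih
from conftest import exp_survival_frame
from ihcstrat.survival import CoxFit, format_pvalue, schoenfeld_ph_test
from oracles import (
    bh_stepup,
    chi2_pearson_p,
    cox_partial_loglik,
    cox_score_test,
    km_curve,
    logrank_chi2,
)


def sim_crossing(n, a, b, lam0, rng):
    """Hazard lam(t) = lam0 * exp(a x) * t^(b x): PH for b=0, crossing otherwise."""
    x = rng.binomial(1, 0.5, n)
    e = rng.exponential(1.0, n)
    t = np.where(x == 0, e / lam0, ((b + 1) * e / (lam0 * np.exp(a))) ** (1 / (b + 1)))
    return pd.DataFrame({"time_months": t, "event": 1, "x": x.astype(float)})


class TestKaplanMeier:
    def test_worked_five_subject_example(self):
        df = pd.DataFrame({"time_months": [1, 2, 3, 4, 5], "event": [1, 0, 1, 0, 1]})
        res = ih.km_fit(df)
        f = res.fitters[None]
        assert f.predict(3) == pytest.approx(0.8 * (1 - 1 / 3), abs=1e-12)
        assert f.predict(3) == pytest.approx(0.5333, abs=1e-4)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 200)
        df = pd.DataFrame({"time_months": t, "event": 1})
        f = ih.km_fit(df).fitters[None]
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert float(f.predict(q)) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_matches_hand_product_limit(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30).round(2)
        e = rng.binomial(1, 0.7, 30)
        if e.sum() == 0:
            e[0] = 1
        df = pd.DataFrame({"time_months": t, "event": e})
        f = ih.km_fit(df).fitters[None]
        for tt, s in km_curve(t, e):
            assert float(f.predict(tt)) == pytest.approx(s, abs=1e-12)

    def test_all_censored_flat_curve_no_median(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": 0})
        res = ih.km_fit(df)
        assert float(res.fitters[None].predict(3.0)) == 1.0
        assert np.isnan(res.medians[None])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame(
            {"time_months": np.r_[t, t], "event": 1, "group": ["A"] * 4 + ["B"] * 4}
        )
        stat, p = ih.logrank_test(df, "group")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_sized_oracle(self):
        df = pd.DataFrame(
            {"time_months": [1.0, 2.5, 3.0, 4.0, 5.5, 7.0],
             "event": [1, 1, 0, 1, 1, 0],
             "group": ["A", "B", "A", "B", "A", "B"]}
        )
        stat, _ = ih.logrank_test(df, "group")
        a, b = df[df.group == "A"], df[df.group == "B"]
        expected = logrank_chi2(a.time_months, a.event, b.time_months, b.event)
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_equals_cox_score_test_on_tie_free_data(self):
        """Log-rank chi-squared == Rao score test of the binary-covariate Cox
        model (exact identity on tie-free data)."""
        rng = np.random.default_rng(2)
        df = exp_survival_frame(80, rng, group_beta=0.4)
        stat, _ = ih.logrank_test(df, "group")
        x = (df["group"] == "B").to_numpy(float)
        score = cox_score_test(df["time_months"], df["event"], x)
        assert stat == pytest.approx(score, rel=1e-6)

    def test_no_events_raises(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": 0, "group": ["A", "B"]})
        with pytest.raises(ValueError):
            ih.logrank_test(df, "group")


class TestCoxFit:
    def test_hand_sized_grid_search_oracle(self):
        """Smallest instance with a finite partial-likelihood maximum (with
        two subjects the likelihood is monotone in beta, so four are used)."""
        df = pd.DataFrame(
            {"time_months": [2.0, 5.0, 6.0, 9.0], "event": [1, 1, 1, 1],
             "x": [1.0, 0.0, 1.0, 0.0]}
        )
        fit = ih.cox_fit(df, ["x"])
        grid = np.linspace(-4, 4, 8001)
        ll = [cox_partial_loglik(b, df.time_months, df.event, df.x) for b in grid]
        best = grid[int(np.argmax(ll))]
        assert -4 < best < 4  # interior maximum
        assert fit.coefficients.loc["x", "beta"] == pytest.approx(best, abs=1e-3)

    def test_breslow_cross_check_with_statsmodels(self):
        """Independent fit (statsmodels PHReg) agrees on tie-free data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        df = exp_survival_frame(150, rng, group_beta=0.6)
        df["x"] = (df["group"] == "B").astype(float)
        fit = ih.cox_fit(df, ["x"])
        ph = sm.PHReg(df["time_months"], df[["x"]], status=df["event"], ties="breslow").fit()
        assert fit.coefficients.loc["x", "beta"] == pytest.approx(ph.params[0], abs=1e-6)

    def test_hr_equals_exp_beta_and_ci_ordered(self):
        rng = np.random.default_rng(4)
        df = exp_survival_frame(100, rng, group_beta=0.5)
        fit = ih.cox_fit(df, ["group"])
        row = fit.coefficients.iloc[0]
        assert row["hr"] == pytest.approx(np.exp(row["beta"]), rel=1e-12)
        assert row["ci_low"] < row["hr"] < row["ci_high"]

    def test_requires_events_and_variation(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": 0, "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            ih.cox_fit(df, ["x"])
        df2 = pd.DataFrame({"time_months": [1.0, 2.0], "event": 1, "x": [1.0, 1.0]})
        with pytest.raises(ValueError):
            ih.cox_fit(df2, ["x"])


class TestUnivariateScreen:
    def test_strong_effect_retained_noise_behaviour(self):
        rng = np.random.default_rng(5)
        n = 400
        g = rng.binomial(1, 0.5, n)
        z = rng.normal(size=n)
        lam = 0.2 * np.exp(0.9 * g)
        df = pd.DataFrame(
            {"time_months": rng.exponential(1 / lam), "event": 1,
             "strong": np.where(g == 1, "yes", "no"), "noise": z}
        )
        selected, table = ih.univariate_screen(df, ["strong", "noise"], alpha_in=0.1)
        assert "strong" in selected
        assert table.loc["strong", "p"] < 0.001

    def test_noise_retained_at_screening_level(self):
        """A pure-noise term passes the alpha_in=0.1 screen about 10% of the time."""
        kept = 0
        reps = 100
        for i in range(reps):
            rng = np.random.default_rng(40_000 + i)
            df = pd.DataFrame(
                {"time_months": rng.exponential(5, 300), "event": 1,
                 "z": rng.normal(size=300)}
            )
            sel, _ = ih.univariate_screen(df, ["z"], alpha_in=0.1)
            kept += bool(sel)
        assert 0.03 <= kept / reps <= 0.18

    def test_exclusion_flag_overrides_p_value(self):
        rng = np.random.default_rng(6)
        n = 300
        g = rng.binomial(1, 0.5, n)
        lam = 0.2 * np.exp(0.9 * g)
        df = pd.DataFrame(
            {"time_months": rng.exponential(1 / lam), "event": 1,
             "tps": np.where(g == 1, "high", "low")}
        )
        selected, table = ih.univariate_screen(df, ["tps"], exclude=["tps"])
        assert selected == []
        assert table.loc["tps", "p"] < 0.05
        assert bool(table.loc["tps", "excluded"])


class TestSchoenfeld:
    def test_matches_lifelines_per_term(self):
        rng = np.random.default_rng(7)
        df = sim_crossing(200, 0.5, 0.0, 0.2, rng)
        df["y"] = rng.normal(size=len(df))
        fit = ih.cox_fit(df, ["x", "y"])
        mine = schoenfeld_ph_test(fit, transform="km")
        theirs = proportional_hazard_test(fit.model, fit.data, time_transform="km")
        for term in ("x", "y"):
            assert mine.loc[term, "chisq"] == pytest.approx(
                float(theirs.summary.loc[term, "test_statistic"]), rel=1e-9
            )

    def test_single_covariate_global_equals_term(self):
        rng = np.random.default_rng(8)
        df = sim_crossing(150, 0.5, 0.0, 0.2, rng)
        fit = ih.cox_fit(df, ["x"])
        res = schoenfeld_ph_test(fit)
        assert res.loc["GLOBAL", "p"] == pytest.approx(res.loc["x", "p"], rel=1e-12)

    def test_null_calibration(self):
        """Constant HR: rejection rate near the nominal level."""
        rej, reps = 0, 200
        for i in range(reps):
            rng = np.random.default_rng(50_000 + i)
            df = sim_crossing(300, 0.5, 0.0, 0.2, rng)
            fit = ih.cox_fit(df, ["x"])
            rej += schoenfeld_ph_test(fit).loc["x", "p"] < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_power_under_crossing_hazards(self):
        rej, reps = 0, 40
        for i in range(reps):
            rng = np.random.default_rng(60_000 + i)
            df = sim_crossing(300, 1.5, -0.7, 0.2, rng)
            fit = ih.cox_fit(df, ["x"])
            rej += schoenfeld_ph_test(fit).loc["x", "p"] < 0.05
        assert rej / reps >= 0.8


class TestExtendedCox:
    def test_zero_time_function_reduces_to_plain_cox(self):
        rng = np.random.default_rng(9)
        df = sim_crossing(150, 0.5, 0.0, 0.2, rng)
        tv = ih.extended_cox_timevarying(df, "x", time_function=lambda t: np.zeros_like(t))
        plain = ih.cox_fit(df, ["x"])
        assert tv.beta0 == pytest.approx(plain.coefficients.loc["x", "beta"], abs=1e-6)
        assert tv.beta1 == 0.0

    def test_constant_hazard_ratio_beta1_null(self):
        rng = np.random.default_rng(10)
        df = sim_crossing(250, 0.5, 0.0, 0.2, rng)
        tv = ih.extended_cox_timevarying(df, "x", time_function="log")
        lo, hi = tv.beta1_ci
        assert lo <= 0.0 <= hi

    @pytest.mark.parametrize("b", [1.0, -0.7])
    def test_sign_recovery_under_log_time_effect(self, b):
        """beta(t) = a + b log t: the fitted interaction has the sign of b."""
        for i in range(6):
            rng = np.random.default_rng(70_000 + 100 * i + (0 if b > 0 else 1))
            df = sim_crossing(250, 0.5, b, 0.2, rng)
            tv = ih.extended_cox_timevarying(df, "x", time_function="log")
            assert np.sign(tv.beta1) == np.sign(b)


class TestRMST:
    def test_no_censoring_equals_truncated_mean_exactly(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(8, 300)
        df = pd.DataFrame(
            {"time_months": t, "event": 1, "g": np.repeat(["A", "B"], 150)}
        )
        res = ih.rmst_compare(df, "g", tau=10.0)
        for g in ("A", "B"):
            tg = t[(df["g"] == g).to_numpy()]
            assert res.rmst[g][0] == pytest.approx(np.minimum(tg, 10.0).mean(), abs=1e-12)

    def test_exponential_closed_form(self):
        """Exponential(rate 0.1): RMST(24) -> (1 - e^-2.4)/0.1 = 9.0928
        (n chosen so the 0.15 tolerance is ~3 standard errors)."""
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"time_months": rng.exponential(10, 20_000), "event": 1})
        est, se = ih.rmst(df, tau=24.0)
        target = (1 - np.exp(-2.4)) / 0.1
        assert abs(est - target) < 0.15
        assert 0.02 < se < 0.1  # sane uncertainty at n=20000

    def test_difference_null_under_identical_hazards(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {"time_months": rng.exponential(10, 2000), "event": 1,
             "g": rng.integers(0, 2, 2000)}
        )
        res = ih.rmst_compare(df, "g", tau=15.0)
        assert abs(res.difference) < 3 * res.diff_se + 1e-9

    def test_tau_beyond_follow_up_clipped_with_warning(self):
        df = pd.DataFrame(
            {"time_months": [1.0, 2.0, 3.0, 4.0], "event": 1, "g": ["A", "A", "B", "B"]}
        )
        with pytest.warns(RuntimeWarning, match="clip"):
            res = ih.rmst_compare(df, "g", tau=24.0)
        assert res.tau_clipped
        assert res.tau == pytest.approx(2.0)

    def test_default_tau_is_24_months(self):
        import inspect

        assert inspect.signature(ih.rmst_compare).parameters["tau"].default == 24.0


class TestCombinedScore:
    def _fabricated_fit(self):
        coef = pd.DataFrame(
            {"beta": [0.5, -1.0], "hr": np.exp([0.5, -1.0]),
             "ci_low": [np.nan] * 2, "ci_high": [np.nan] * 2, "p": [np.nan] * 2},
            index=["a", "b"],
        )
        return CoxFit(
            coefficients=coef, log_likelihood=0.0, null_log_likelihood=0.0,
            n=1, n_events=1, terms=("a", "b"),
            encoding={"a": "numeric", "b": "numeric"}, model=None,
            data=pd.DataFrame(),
        )

    def test_linear_predictor_arithmetic(self):
        fit = self._fabricated_fit()
        df = pd.DataFrame({"a": [2.0], "b": [1.0]})
        sc = ih.combined_score(fit, df, threshold=0.5)
        assert sc.scores["lp"].iloc[0] == pytest.approx(0.0)  # 0.5*2 - 1*1
        assert sc.scores["risk_group"].iloc[0] == "low_score"

    def test_median_split_near_balanced(self):
        rng = np.random.default_rng(14)
        fit = self._fabricated_fit()
        df = pd.DataFrame({"a": rng.normal(size=101), "b": rng.normal(size=101)})
        sc = ih.combined_score(fit, df)
        counts = sc.scores["risk_group"].value_counts()
        assert abs(counts.get("high_score", 0) - counts.get("low_score", 0)) <= 1

    def test_missing_covariates_excluded(self):
        fit = self._fabricated_fit()
        df = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 1.0]})
        sc = ih.combined_score(fit, df, threshold=0.0)
        assert len(sc.scores) == 2

    def test_combined_model_separates_better_than_clinical(self):
        """With true clinical + group effects, the combined score splits
        survival more strongly than the clinical-only score in most runs."""
        wins, reps = 0, 25
        for i in range(reps):
            rng = np.random.default_rng(80_000 + i)
            n = 400
            smoke = rng.binomial(1, 0.5, n)
            grp = rng.binomial(1, 0.5, n)
            age = rng.normal(size=n)
            lam = 0.2 * np.exp(-0.7 * smoke + 0.3 * age - 0.6 * grp)
            df = pd.DataFrame(
                {"time_months": rng.exponential(1 / lam), "event": 1, "age": age,
                 "smoking": np.where(smoke == 1, "Ever", "Never"),
                 "dl_group": np.where(grp == 1, "High", "Low")}
            )
            clin = ih.cox_fit(df, ["smoking", "age"])
            comb = ih.cox_fit(df, ["smoking", "age", "dl_group"])

            def split_beta(fit):
                sc = ih.combined_score(fit, df)
                d = df.assign(rg=sc.scores["risk_group"])
                return ih.cox_fit(d, ["rg"]).coefficients["beta"].iloc[0]

            b_comb, b_clin = split_beta(comb), split_beta(clin)
            assert b_comb < 0  # low_score group has lower hazard
            wins += abs(b_comb) > abs(b_clin)
        assert wins / reps >= 0.8


class TestConcordance:
    def test_perfect_and_chance_ranking(self):
        rng = np.random.default_rng(19)
        t = rng.exponential(5, 200)
        df = pd.DataFrame({"time_months": t, "event": 1})
        # risk perfectly anti-ordered with time -> C = 1
        assert ih.concordance_index(df, -t) == pytest.approx(1.0)
        # random score -> C near 0.5
        assert abs(ih.concordance_index(df, rng.normal(size=200)) - 0.5) < 0.1


class TestLikelihoodRatio:
    def test_identical_models_statistic_zero(self):
        rng = np.random.default_rng(15)
        df = exp_survival_frame(100, rng, group_beta=0.5)
        fit = ih.cox_fit(df, ["group"])
        stat, dof, p = ih.likelihood_ratio_test(fit, fit)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert dof == 0
        assert p == 1.0

    def test_power_under_true_added_effect(self):
        sig, reps = 0, 40
        for i in range(reps):
            rng = np.random.default_rng(90_000 + i)
            df = exp_survival_frame(400, rng, group_beta=0.6)
            df["z"] = rng.normal(size=len(df))
            nested = ih.cox_fit(df, ["z"])
            full = ih.cox_fit(df, ["z", "group"])
            _, _, p = ih.likelihood_ratio_test(nested, full)
            sig += p < 0.05
        assert sig / reps >= 0.9

    def test_null_p_uniform(self):
        """Pure-noise added covariate: LRT p-values are uniform (KS, alpha=0.01)."""
        from scipy.stats import kstest

        ps = []
        for i in range(200):
            rng = np.random.default_rng(100_000 + i)
            df = exp_survival_frame(150, rng, group_beta=0.5)
            df["z"] = rng.normal(size=len(df))
            nested = ih.cox_fit(df, ["group"])
            full = ih.cox_fit(df, ["group", "z"])
            ps.append(ih.likelihood_ratio_test(nested, full)[2])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_non_nested_raises(self):
        rng = np.random.default_rng(16)
        df = exp_survival_frame(80, rng)
        df["z"] = rng.normal(size=len(df))
        a = ih.cox_fit(df, ["z"])
        b = ih.cox_fit(df, ["group"])
        with pytest.raises(ValueError):
            ih.likelihood_ratio_test(a, b)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ih.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_worked_example(self):
        assert np.allclose(ih.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_direct_formula_and_monotone(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=25)
        adj = ih.bh_adjust(p)
        assert np.allclose(adj, bh_stepup(p), atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1).all() and (adj >= p - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ih.bh_adjust([0.5, 1.2])


class TestCompareCohorts:
    @staticmethod
    def clinical_from_counts(spec):
        """Rebuild a patient-level frame from per-cohort level counts."""
        rows = []
        for cohort, levels in spec.items():
            for level, n in levels.items():
                rows += [{"cohort": cohort, "v": level}] * n
        return pd.DataFrame(rows)

    def test_balanced_2x2_statistic_zero(self):
        df = self.clinical_from_counts(
            {"A": {"x": 10, "y": 10}, "B": {"x": 10, "y": 10}}
        )
        out = ih.compare_cohorts(df, "cohort")
        assert out.loc["v", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["v", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_printed_contingency_table_p_values(self):
        """The PD-L1 1%-cutoff 2x2 table reproduces p = 0.006 after rounding."""
        df = self.clinical_from_counts(
            {"MSK": {"0": 51, ">=1": 131}, "CGFL": {"0": 15, ">=1": 93}}
        )
        out = ih.compare_cohorts(df, "cohort")
        assert out.loc["v", "test"] == "Pearson chi-squared"
        assert out.loc["v", "p_display"] == "0.006"

    def test_three_by_two_matches_chi2_oracle(self):
        df = self.clinical_from_counts(
            {"MSK": {"adeno": 129, "squam": 32, "other": 21},
             "CGFL": {"adeno": 80, "squam": 21, "other": 7}}
        )
        out = ih.compare_cohorts(df, "cohort")
        _, p = chi2_pearson_p(np.array([[129, 32, 21], [80, 21, 7]]))
        assert out.loc["v", "p"] == pytest.approx(p, abs=1e-10)
        assert out.loc["v", "p_display"] == "0.4"

    def test_wilcoxon_for_continuous(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            {"cohort": np.repeat(["A", "B"], 60),
             "age": np.r_[rng.normal(60, 8, 60), rng.normal(66, 8, 60)]}
        )
        out = ih.compare_cohorts(df, "cohort", continuous=["age"])
        assert out.loc["age", "test"] == "Wilcoxon rank-sum"
        assert out.loc["age", "p"] < 0.01

    def test_fisher_used_for_small_expected_counts(self):
        df = self.clinical_from_counts(
            {"A": {"x": 3, "y": 40}, "B": {"x": 1, "y": 45}}
        )
        out = ih.compare_cohorts(df, "cohort")
        assert out.loc["v", "test"].startswith("Fisher")

    def test_unknown_levels_excluded_but_counted(self):
        df = self.clinical_from_counts(
            {"A": {"x": 20, "y": 20, "Unknown": 5}, "B": {"x": 15, "y": 25}}
        )
        out = ih.compare_cohorts(df, "cohort")
        assert out.loc["v", "n_missing"] == 5
        assert out.loc["v", "n_used"] == 80


class TestFormatPvalue:
    @pytest.mark.parametrize(
        "raw, shown",
        [
            (0.0005, "<0.001"),
            (0.005517, "0.006"),
            (0.00736, "0.007"),
            (0.036, "0.036"),
            (0.076, "0.076"),
            (0.6508, "0.7"),
            (0.3643, "0.4"),
        ],
    )
    def test_table_style_rounding(self, raw, shown):
        assert format_pvalue(raw) == shown
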