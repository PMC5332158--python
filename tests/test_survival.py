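import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import replispan as rs
from replispan.survival import FitError, _empirical_curve


def lifespan_table(lifespans):
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(lifespans))],
        "generations_at_death": lifespans,
        "status": "died",
    })


def exact_curve(model, g_max):
    g = np.arange(0, g_max + 1)
    s = model.survival(g)
    at_risk = np.arange(g_max + 1, 0, -1)   # placeholder, non-increasing
    return rs.SurvivalCurve(generations=g, survival=s, at_risk=at_risk,
                            n_total=1000)


class TestKaplanMeier:
    def test_small_example(self):
        curve = rs.km_estimate(lifespan_table([1, 2, 2, 3]))
        assert np.allclose(curve.survival, [1.0, 0.75, 0.25, 0.0])
        assert np.array_equal(curve.at_risk, [4, 4, 3, 1])

    def test_point_mass_step_function(self):
        curve = rs.km_estimate(lifespan_table([5] * 10))
        assert np.allclose(curve.survival[:5], 1.0)
        assert curve.survival[5] == 0.0

    def test_dkw_style_bound(self, wt_cohort):
        curve = rs.km_estimate(wt_cohort)
        truth = np.exp(-0.02 * curve.generations)
        assert np.max(np.abs(curve.survival - truth)) < 0.02

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rs.km_estimate(lifespan_table([]))

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_complete_data_km_equals_empirical_fraction(self, lifespans):
        """With no censoring the KM estimate is exactly the empirical
        survivor fraction (oracle equivalence)."""
        curve = rs.km_estimate(lifespan_table(lifespans))
        life = np.asarray(lifespans)
        expected = np.array([(life > g).mean() for g in curve.generations])
        assert np.allclose(curve.survival, expected, atol=1e-12)

    def test_censoring_aware_mode(self):
        table = lifespan_table([1, 2, 3, 4])
        table.loc[3, "status"] = "survived_to_end"
        default = rs.km_estimate(table)
        assert default.n_total == 3           # censored cell excluded
        censored = rs.km_estimate(table, include_censored=True)
        assert censored.n_total == 4


class TestEmpiricalHazard:
    def test_all_die_at_one(self):
        curve = rs.km_estimate(lifespan_table([1, 1, 1, 1]))
        haz = rs.empirical_hazard(curve)
        assert haz.generations[0] == 1
        assert haz.hazard[0] == 1.0

    def test_exponential_cohort_flat_two_percent(self, wt_cohort):
        curve = rs.km_estimate(wt_cohort)
        haz = rs.empirical_hazard(curve)
        keep = haz.generations <= 40
        assert np.mean(haz.hazard[keep]) == pytest.approx(0.02, rel=0.1)

    def test_gompertz_cohort_log_linear(self):
        m = rs.MortalityModel("gompertz", alpha=0.005, beta=0.15)
        table = rs.sample_lifespans(m, 20_000, seed=7)
        haz = rs.empirical_hazard(rs.km_estimate(table))
        keep = (haz.generations >= 2) & (haz.generations <= 25)
        slope = np.polyfit(haz.generations[keep],
                           np.log(haz.hazard[keep]), 1)[0]
        assert slope == pytest.approx(0.15, rel=0.15)


class TestFitSurvival:
    def test_exact_exponential_recovery(self):
        m = rs.MortalityModel("exponential", alpha=0.05)
        fit = rs.fit_survival(exact_curve(m, 50), "exponential")
        assert fit.model.alpha == pytest.approx(0.05, abs=1e-6)
        assert fit.adjusted_r2 > 1 - 1e-9

    def test_exact_gompertz_recovery(self):
        m = rs.MortalityModel("gompertz", alpha=0.005, beta=0.15)
        fit = rs.fit_survival(exact_curve(m, 50), "gompertz")
        assert fit.model.alpha == pytest.approx(0.005, abs=1e-4)
        assert fit.model.beta == pytest.approx(0.15, abs=1e-4)

    def test_weighted_and_unweighted_agree_on_exact_data(self):
        m = rs.MortalityModel("exponential", alpha=0.04)
        curve = exact_curve(m, 60)
        fw = rs.fit_survival(curve, "exponential", "inverse_survival")
        fu = rs.fit_survival(curve, "exponential", "none")
        assert fw.model.alpha == pytest.approx(fu.model.alpha, abs=1e-8)

    def test_simulated_wt_cohort_two_percent_hazard(self, wt_mortality):
        table = rs.sample_lifespans(wt_mortality, 440, seed=9)
        fit = rs.fit_survival(rs.km_estimate(table), "exponential")
        assert fit.model.alpha == pytest.approx(0.02, rel=0.15)

    def test_too_few_points(self):
        curve = rs.km_estimate(lifespan_table([1, 1, 1]))
        with pytest.raises(FitError):
            rs.fit_survival(curve, "exponential")


class TestHazardAndRls:
    def test_exponential_constant_hazard(self):
        m = rs.MortalityModel("exponential", alpha=0.02)
        fit = rs.SurvivalFit(model=m, adjusted_r2=1.0, rls=m.rls(), n_cells=1)
        haz = rs.hazard_from_fit(fit, np.arange(0, 50))
        assert np.allclose(haz.hazard, 0.02)

    def test_gompertz_hazard_value(self):
        m = rs.MortalityModel("gompertz", alpha=0.01, beta=0.1)
        assert m.hazard(10) == pytest.approx(0.01 * np.e, rel=1e-9)

    def test_gompertz_hazard_beta_to_zero_limit(self):
        m = rs.MortalityModel("gompertz", alpha=0.02, beta=1e-9)
        assert np.allclose(m.hazard(np.arange(101)), 0.02, rtol=1e-6)

    def test_rls_exponential_values(self):
        assert rs.MortalityModel("exponential", np.log(2)).rls() == pytest.approx(1.0)
        assert rs.MortalityModel("exponential", 0.02).rls() == pytest.approx(34.657, abs=1e-3)

    @pytest.mark.parametrize("alpha,beta", [
        (0.001, 0.3), (0.005, 0.15), (0.02, 0.05), (0.1, 0.4)])
    def test_gompertz_rls_matches_numeric_root(self, alpha, beta):
        """Closed-form RLS equals the numeric root of S(g) = 1/2."""
        m = rs.MortalityModel("gompertz", alpha=alpha, beta=beta)
        root = optimize.brentq(lambda g: m.survival(g) - 0.5, 1e-9, 1e4)
        assert m.rls() == pytest.approx(root, abs=1e-6)
        assert abs(m.survival(m.rls()) - 0.5) < 1e-9

    @pytest.mark.parametrize("beta", [1e-3, 1e-6, 1e-9])
    def test_gompertz_rls_approaches_exponential(self, beta):
        m = rs.MortalityModel("gompertz", alpha=0.02, beta=beta)
        assert abs(m.rls() - np.log(2) / 0.02) < 50 * beta / 0.02 + 1e-9


class TestSelectModel:
    def test_exact_exponential_curve_selects_exponential(self):
        m = rs.MortalityModel("exponential", alpha=0.03)
        assert rs.select_model(exact_curve(m, 60)).model.kind == "exponential"

    def test_exact_gompertz_curve_selects_gompertz(self):
        m = rs.MortalityModel("gompertz", alpha=0.005, beta=0.2)
        assert rs.select_model(exact_curve(m, 40)).model.kind == "gompertz"

    def test_exponential_favored_under_exponential_truth(self, wt_mortality):
        """Model selection on constant-hazard cohorts favors the
        exponential model in the clear majority of replicates."""
        kinds = [rs.select_model(rs.km_estimate(
            rs.sample_lifespans(wt_mortality, 440, seed=400 + r))).model.kind
            for r in range(40)]
        assert kinds.count("exponential") / len(kinds) >= 0.5


class TestBootstrap:
    def test_point_mass_gives_zero_width_ci(self):
        """Every resample of an all-equal table is identical, so the CI
        collapses to a point."""
        table = lifespan_table([7] * 200)
        cis, samples = rs.bootstrap_cis(table, "exponential", n_boot=100,
                                        seed=1)
        assert cis["rls"][1] - cis["rls"][0] == 0.0
        assert cis["alpha"][1] - cis["alpha"][0] == 0.0

    def test_ci_width_shrinks_with_n(self, wt_mortality):
        small = rs.sample_lifespans(wt_mortality, 100, seed=2)
        large = rs.sample_lifespans(wt_mortality, 1000, seed=3)
        ci_s, _ = rs.bootstrap_cis(small, "exponential", n_boot=150, seed=4)
        ci_l, _ = rs.bootstrap_cis(large, "exponential", n_boot=150, seed=4)
        assert (ci_s["rls"][1] - ci_s["rls"][0]
                > ci_l["rls"][1] - ci_l["rls"][0])

    def test_deterministic_given_seed(self, wt_mortality):
        table = rs.sample_lifespans(wt_mortality, 200, seed=5)
        a, _ = rs.bootstrap_cis(table, "exponential", n_boot=120, seed=6)
        b, _ = rs.bootstrap_cis(table, "exponential", n_boot=120, seed=6)
        assert a == b

    def test_rls_ci_coverage(self, wt_mortality):
        """Nested Monte-Carlo: the bootstrap 95% CI for RLS covers the true
        value (ln2 / 0.02) in about 95% of outer trials (reduced reps)."""
        true_rls = np.log(2) / 0.02
        hits = 0
        n_trials = 30
        for r in range(n_trials):
            table = rs.sample_lifespans(wt_mortality, 440, seed=700 + r)
            cis, _ = rs.bootstrap_cis(table, "exponential", n_boot=150,
                                      seed=r)
            hits += cis["rls"][0] <= true_rls <= cis["rls"][1]
        assert hits / n_trials >= 0.8


class TestNormalizeHazard:
    def test_identical_fits_give_unity(self):
        m = rs.MortalityModel("exponential", alpha=0.02)
        fit = rs.SurvivalFit(model=m, adjusted_r2=1.0, rls=m.rls(), n_cells=1)
        out = rs.normalize_hazard(fit, fit)
        assert out.fold_change.iloc[0] == pytest.approx(1.0)

    def test_twofold_lower_hazard(self):
        ref = rs.SurvivalFit(model=rs.MortalityModel("exponential", 0.02),
                             adjusted_r2=1.0, rls=1.0, n_cells=1)
        strain = rs.SurvivalFit(model=rs.MortalityModel("exponential", 0.01),
                                adjusted_r2=1.0, rls=1.0, n_cells=1)
        assert rs.normalize_hazard(strain, ref).fold_change.iloc[0] == pytest.approx(0.5)

    def test_sevenfold_pair_recovered_from_cohorts(self):
        """A strain simulated with 7x the wild-type hazard recovers a ~7x
        fold change."""
        ref_tab = rs.sample_lifespans(rs.MortalityModel("exponential", 0.02),
                                      2000, seed=8)
        mut_tab = rs.sample_lifespans(rs.MortalityModel("exponential", 0.14),
                                      2000, seed=9)
        ref = rs.fit_survival(rs.km_estimate(ref_tab), "exponential")
        mut = rs.fit_survival(rs.km_estimate(mut_tab), "exponential")
        fold = rs.normalize_hazard(mut, ref).fold_change.iloc[0]
        assert fold == pytest.approx(7.0, rel=0.15)


def test_anderson_darling_report_fields():
    rng = np.random.default_rng(0)
    out = rs.anderson_darling_report(rng.normal(size=300))
    assert set(out) == {"statistic", "p_value", "n"}
    assert out["p_value"] > 0.01
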