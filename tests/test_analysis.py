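import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import replispan as rs
from replispan.simulate import cell_rng


class TestContourGrid:
    def test_alpha_ln2_beta_zero_gives_rls_one(self):
        grid = rs.rls_contour_grid((np.log(2), np.log(2) + 0.1), (0.0, 0.1),
                                   resolution=5)
        assert grid.rls_matrix[0, 0] == pytest.approx(1.0)

    def test_monotone_decreasing_in_both_coefficients(self):
        grid = rs.rls_contour_grid((0.001, 0.2), (0.0, 0.5), resolution=40)
        assert np.all(np.diff(grid.rls_matrix, axis=0) < 0)   # alpha axis
        assert np.all(np.diff(grid.rls_matrix, axis=1) < 0)   # beta axis

    def test_beta_zero_column_is_exponential_limit(self):
        grid = rs.rls_contour_grid((0.01, 0.1), (0.0, 0.3), resolution=20)
        assert np.allclose(grid.rls_matrix[:, 0],
                           np.log(2) / grid.alpha_values)

    def test_grid_cell_matches_numeric_root(self):
        m = rs.MortalityModel("gompertz", alpha=0.001, beta=0.3)
        root = optimize.brentq(lambda g: m.survival(g) - 0.5, 1e-9, 1e4)
        grid = rs.rls_contour_grid((0.001, 0.002), (0.3, 0.4), resolution=3)
        assert grid.rls_matrix[0, 0] == pytest.approx(root, abs=1e-9)
        assert grid.rls_matrix[0, 0] == pytest.approx(17.81, abs=0.01)


class TestClassifyAging:
    def _fits(self, model, n=4000, seed=0):
        table = rs.sample_lifespans(model, n, seed=seed)
        curve = rs.km_estimate(table)
        fe = rs.fit_survival(curve, "exponential")
        fg = rs.fit_survival(curve, "gompertz")
        return table, fe, fg

    def test_exponential_truth_called_non_aging(self):
        m = rs.MortalityModel("exponential", alpha=0.02)
        table, fe, fg = self._fits(m, seed=1)
        cis, _ = rs.bootstrap_cis(table, "gompertz", n_boot=100, seed=1)
        verdict = rs.classify_aging(fe, fg, beta_ci=cis["beta"])
        assert verdict["verdict"] == "non_aging"

    def test_gompertz_truth_called_aging(self):
        m = rs.MortalityModel("gompertz", alpha=0.005, beta=0.15)
        table, fe, fg = self._fits(m, seed=2)
        cis, _ = rs.bootstrap_cis(table, "gompertz", n_boot=100, seed=2)
        verdict = rs.classify_aging(fe, fg, beta_ci=cis["beta"])
        assert verdict["verdict"] == "aging"
        assert verdict["beta_ci"][0] > 0


class TestPostSynchronize:
    def test_short_lived_cell_contributes_to_early_bins_only(self):
        traj = rs.CellTrajectory(
            cell_id="c", times=np.array([0.0]), lengths=np.array([8.0]),
            division_times=np.array([2.0, 4.0, 6.0]), generation_count=3,
            division_lengths=np.array([15.0, 16.0, 17.0]),
            generation_durations=np.array([2.0, 2.0, 2.0]))
        dists = rs.post_synchronize_to_death([traj], k_max=5)
        assert dists.n_per_bin == {1: 1, 2: 1, 3: 1, 4: 0, 5: 0}
        assert dists.lengths[1][0] == 17.0     # last generation before death
        assert dists.lengths[3][0] == 15.0

    def test_age_independent_generator_gives_flat_bins(self, growth,
                                                       wt_mortality):
        _, records = rs.sample_cell_records(wt_mortality, growth, 2000,
                                            seed=3)
        dists = rs.post_synchronize_to_death(records)
        means = [dists.lengths[k].mean() for k in range(1, 6)]
        assert np.ptp(means) < 0.25    # um, ~4-sigma of a bin mean

    def test_terminal_only_effect_shifts_last_bin(self, growth, wt_mortality):
        """Doubling-time inflation applied only to the final generation
        appears only in bin k=1."""
        _, records = rs.sample_cell_records(
            wt_mortality, growth, 1500, seed=4,
            last_generation_time_inflation=1.5)
        dists = rs.post_synchronize_to_death(records)
        t1 = dists.doubling_times[1].mean()
        others = [dists.doubling_times[k].mean() for k in range(2, 6)]
        assert t1 == pytest.approx(1.5 * 2.05, rel=0.05)
        assert np.allclose(others, 2.05, rtol=0.05)
        table = rs.ks_generation_comparison(dists)
        row = table[(table.quantity == "doubling_time")
                    & (table.pair == "2v1")].iloc[0]
        assert row.stars == "**"


class TestKsComparison:
    def test_identical_samples_no_stars(self):
        x = np.arange(100.0)
        dists = rs.DeathAlignedDistributions(
            lengths={1: x, 2: x}, doubling_times={1: x, 2: x},
            n_per_bin={1: 100, 2: 100})
        table = rs.ks_generation_comparison(dists)
        assert (table.stars == "").all()
        assert (table.p_value > 0.99).all()

    def test_three_sigma_shift_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(16.0, 2.2, 300)
        b = rng.normal(16.0 + 3 * 2.2, 2.2, 300)
        dists = rs.DeathAlignedDistributions(
            lengths={1: a, 2: b}, doubling_times={1: a, 2: a},
            n_per_bin={1: 300, 2: 300})
        table = rs.ks_generation_comparison(dists)
        row = table[(table.quantity == "length") & (table.pair == "2v1")]
        assert row.stars.iloc[0] == "**"

    def test_empty_bin_skipped_with_note(self):
        x = np.arange(50.0)
        dists = rs.DeathAlignedDistributions(
            lengths={1: x, 2: np.array([])},
            doubling_times={1: x, 2: np.array([])},
            n_per_bin={1: 50, 2: 0})
        table = rs.ks_generation_comparison(dists)
        assert (table.note == "insufficient samples").all()


class TestDeathPhenotype:
    def test_short_cell(self):
        traj = rs.CellTrajectory(
            cell_id="c", times=np.array([0.0, 1.0, 2.0]),
            lengths=np.array([8.0, 10.0, 12.0]),
            division_times=np.array([0.5]), generation_count=1,
            fate="died", terminal_duration=1.5)
        assert rs.classify_death_phenotype(traj) == "short"

    def test_elongated_cell(self):
        traj = rs.CellTrajectory(
            cell_id="c", times=np.array([0.0, 7.0]),
            lengths=np.array([8.0, 30.0]),
            division_times=np.array([0.5]), generation_count=1,
            fate="died", terminal_duration=7.0)
        assert rs.classify_death_phenotype(traj) == "elongated"

    def test_surviving_cell_rejected(self):
        traj = rs.CellTrajectory(
            cell_id="c", times=np.array([0.0, 1.0]),
            lengths=np.array([8.0, 9.0]), division_times=np.array([0.5]),
            generation_count=1, fate="survived_to_end")
        with pytest.raises(ValueError):
            rs.classify_death_phenotype(traj)

    def test_simulated_cohort_recovers_short_fraction(self, growth,
                                                      wt_mortality):
        """Classifying simulated dying cells recovers the configured 72%
        short / 28% elongated split."""
        table = rs.sample_lifespans(wt_mortality, 400, seed=6)
        table = rs.assign_terminal_phenotypes(table, rs.PhenotypeProbs(),
                                              seed=7)
        calls = []
        for i, row in enumerate(table.itertuples()):
            traj = rs.simulate_trajectory(growth,
                                          int(row.generations_at_death),
                                          row.terminal_phenotype,
                                          cell_rng(600, i))
            calls.append(rs.classify_death_phenotype(traj))
        frac_short = calls.count("short") / len(calls)
        assert frac_short == pytest.approx(0.72, abs=0.08)


class TestSiblingFates:
    def test_example_proportions(self):
        fates = (["never_divided"] * 135 + ["divided_once"] * 29
                 + ["divided_multiple"] * 40)
        table = pd.DataFrame({
            "cell_id": range(204), "generations_at_death": 10,
            "status": "died", "sibling_fate": fates})
        out = rs.sibling_fate_by_age(table, age_bins=[0, 100], n_boot=100)
        props = next(iter(out["proportions"].values()))
        assert props["never_divided"] == pytest.approx(135 / 204, abs=1e-9)
        assert props["divided_once"] == pytest.approx(29 / 204, abs=1e-9)
        assert props["divided_multiple"] == pytest.approx(40 / 204, abs=1e-9)

    def test_point_mass_fate_zero_sd(self):
        table = pd.DataFrame({
            "cell_id": range(50), "generations_at_death": 5,
            "status": "died", "sibling_fate": "never_divided"})
        out = rs.sibling_fate_by_age(table, age_bins=[0, 100], n_boot=100)
        sds = next(iter(out["bootstrap_sd"].values()))
        assert all(v == 0.0 for v in sds.values())

    def test_chi_square_null_p_uniform(self, wt_mortality):
        """With age-independent fates the chi-square p-values over repeated
        cohorts are consistent with a uniform distribution."""
        pvals = []
        for r in range(40):
            table = rs.sample_lifespans(wt_mortality, 245, seed=800 + r)
            table = rs.assign_terminal_phenotypes(table, rs.PhenotypeProbs(),
                                                  seed=900 + r)
            out = rs.sibling_fate_by_age(table, n_boot=100, seed=r)
            if np.isfinite(out["chi2_p"]):
                pvals.append(out["chi2_p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDefectTallies:
    def test_observed_count_ratios(self):
        events = pd.DataFrame({
            "population": ["all"] * 1182 + ["terminal"] * 141,
            "defect_class": (["unequal"] * 88 + ["normal"] * 1094
                             + ["bridge"] * 56 + ["normal"] * 85),
        })
        overall, terminal, fold = rs.tally_segregation_defects(events)
        assert overall.defect_rate == pytest.approx(88 / 1182, abs=1e-9)
        assert terminal.defect_rate == pytest.approx(56 / 141, abs=1e-9)
        assert fold == pytest.approx((56 / 141) / (88 / 1182), rel=1e-9)

    def test_zero_defects(self):
        events = pd.DataFrame({
            "population": ["all"] * 10 + ["terminal"] * 5,
            "defect_class": "normal"})
        overall, terminal, fold = rs.tally_segregation_defects(events)
        assert overall.defect_rate == 0.0
        assert np.isnan(fold)

    def test_unknown_label_rejected(self):
        events = pd.DataFrame({"population": ["all"],
                               "defect_class": ["lagging"]})
        with pytest.raises(ValueError):
            rs.tally_segregation_defects(events)


class TestDefectLethality:
    def test_bridge_asymmetric_lethality(self):
        events = pd.DataFrame({
            "defect_class": ["bridge"] * 78,
            "died": [True] * 31 + [False] * 47})
        out = rs.defect_lethality(events)
        row = out[out.defect_class == "bridge"].iloc[0]
        assert row.p_death == pytest.approx(31 / 78, abs=1e-9)
        assert row.ci_low < 31 / 78 < row.ci_high

    def test_all_death_class(self):
        events = pd.DataFrame({"defect_class": ["multi"] * 20, "died": True})
        out = rs.defect_lethality(events)
        assert out.p_death.iloc[0] == 1.0

    def test_empty_class_omitted(self):
        events = pd.DataFrame({"defect_class": ["normal"] * 5, "died": False})
        out = rs.defect_lethality(events)
        assert set(out.defect_class) == {"normal"}
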