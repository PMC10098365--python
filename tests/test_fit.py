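"""Inverse engine: percentile times, regime split, rate regressions,
threshold-distribution fits, end-to-end pipeline."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from seedtherm import (FitConfig, FitError, GerminationRecord, fit_pipeline,
                       fit_suboptimal, fit_supraoptimal,
                       fit_threshold_distribution, seed_at_quantile,
                       split_regimes, time_to_germination)
from seedtherm.fit import (build_gr_table, percentile_times_from_curve,
                           pooled_cumulative_curve)


def make_records(curve, temp=24.0, size=100, dish="d1"):
    """(time, cumulative count) pairs -> records of one dish."""
    return [GerminationRecord(dish=dish, temperature_C=temp, time_d=t,
                              tr_count=c, er_count=c, dish_size=size)
            for t, c in curve]


class TestPercentileTimes:
    def test_exact_node(self):
        out = percentile_times_from_curve(np.array([1., 3., 5.]),
                                          np.array([20., 50., 80.]), [50.])
        assert out == [(50.0, 3.0, True)]

    def test_linear_interpolation_between_nodes(self):
        out = percentile_times_from_curve(np.array([2., 3.]),
                                          np.array([40., 60.]), [50.])
        (_, t_g, reached), = out
        assert reached and t_g == pytest.approx(2.5)

    def test_percentile_above_plateau_not_reached(self):
        out = percentile_times_from_curve(np.array([2., 10.]),
                                          np.array([30., 55.]), [60.])
        assert out[0][2] is False and np.isnan(out[0][1])

    def test_pooling_monotonizes_scoring_noise(self):
        # a dish whose count dips is monotonized by the running maximum
        recs = [GerminationRecord("d1", 24.0, t, c, c, 10)
                for t, c in [(1.0, 2), (2.0, 5), (3.0, 5)]]
        recs += [GerminationRecord("d2", 24.0, t, c, c, 10)
                 for t, c in [(1.0, 4), (2.0, 3), (3.0, 6)]]
        times, cum = pooled_cumulative_curve(recs)
        assert np.all(np.diff(cum) >= 0)

    def test_empty_timecourse_rejected(self):
        with pytest.raises(FitError, match="empty"):
            pooled_cumulative_curve([])

    def test_times_monotone_in_percentile(self, small_experiment):
        _, records = small_experiment
        one_temp = [r for r in records if r.temperature_C == 24.0]
        table = build_gr_table(one_temp, [10., 20., 30., 40.])
        assert table["t_g"].is_monotonic_increasing


class TestSplitRegimes:
    def grid_table(self, grs, temps):
        return pd.DataFrame({"temperature": temps,
                             "percentile": [50.0] * len(temps),
                             "t_g": [1 / g for g in grs], "gr": grs})

    def test_argmax_temperature_in_both_regimes(self):
        temps = [12, 16, 20, 24, 28, 32]
        grs = [0.03, 0.06, 0.09, 0.11, 0.07, 0.02]
        sub, supra, ref = split_regimes(self.grid_table(grs, temps))
        assert sub == [12, 16, 20, 24]
        assert supra == [24, 28, 32]
        assert ref == 50.0

    def test_monotone_rates_leave_one_sided_fit(self):
        temps = [12, 16, 20, 24]
        with pytest.warns(UserWarning, match="monotone increasing"):
            sub, supra, _ = split_regimes(
                self.grid_table([0.02, 0.05, 0.08, 0.11], temps))
        assert sub == temps and supra == []

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(FitError, match=">= 3"):
            split_regimes(self.grid_table([0.05, 0.08], [16, 20]))


def exact_gr_table(params, temps, percentiles, g_ref):
    """Noiseless GR values from the closed-form quantile inverse."""
    rows = []
    for temp in temps:
        for g in percentiles:
            seed = seed_at_quantile(g / g_ref, params)
            t_g = time_to_germination(temp, seed, params)
            rows.append((temp, g, t_g, 1.0 / t_g))
    return pd.DataFrame(rows, columns=["temperature", "percentile", "t_g",
                                       "gr"])


class TestRegimeFits:
    PCT = [10., 20., 30., 40., 50.]

    def test_suboptimal_exact_recovery(self, clean_regime_params):
        table = exact_gr_table(clean_regime_params, [12., 15., 18., 21.],
                               self.PCT, g_ref=60.0)
        fit = fit_suboptimal(table, [12., 15., 18., 21.])
        # every percentile line passes exactly through (T_base, 0)
        assert fit["x_intercept"].to_numpy() == pytest.approx(
            [8.0] * 5, abs=1e-9)
        z = norm.ppf(np.array(self.PCT) / 60.0)
        assert fit["theta_cold"].to_numpy() == pytest.approx(144 + 30 * z)

    def test_supraoptimal_exact_recovery(self, clean_regime_params):
        table = exact_gr_table(clean_regime_params, [25., 27., 29., 31.],
                               self.PCT, g_ref=60.0)
        fit = fit_supraoptimal(table, [25., 27., 29., 31.])
        z = norm.ppf(np.array(self.PCT) / 60.0)
        assert fit["T_c"].to_numpy() == pytest.approx(35 - 2 * z, abs=1e-9)
        assert (-1.0 / fit["slope"]).to_numpy() == pytest.approx(
            [99.0] * 5)

    def test_rate_scaling_property(self, clean_regime_params):
        """Doubling all rates halves theta and leaves T_base unchanged."""
        table = exact_gr_table(clean_regime_params, [12., 15., 18., 21.],
                               [50.], g_ref=60.0)
        doubled = table.assign(gr=table["gr"] * 2)
        fit1 = fit_suboptimal(table, [12., 15., 18., 21.])
        fit2 = fit_suboptimal(doubled, [12., 15., 18., 21.])
        assert fit2["theta_cold"].iloc[0] == pytest.approx(
            fit1["theta_cold"].iloc[0] / 2)
        assert fit2["x_intercept"].iloc[0] == pytest.approx(
            fit1["x_intercept"].iloc[0])

    def test_flat_rates_are_a_regime_error(self):
        table = pd.DataFrame({"temperature": [12., 16., 20.],
                              "percentile": [50.] * 3,
                              "t_g": [10.] * 3, "gr": [0.1] * 3})
        with pytest.raises(FitError, match="slope"):
            fit_suboptimal(table, [12., 16., 20.], strict=True)

    def test_wrong_sign_supra_slope_is_error(self):
        table = pd.DataFrame({"temperature": [26., 28., 30.],
                              "percentile": [50.] * 3,
                              "t_g": [20., 15., 10.],
                              "gr": [0.05, 1 / 15, 0.1]})
        with pytest.raises(FitError, match="slope"):
            fit_supraoptimal(table, [26., 28., 30.], strict=True)

    def test_three_point_closed_form_ols(self):
        # single percentile on an exact line: intercept by hand
        table = pd.DataFrame({"temperature": [26., 28., 30.],
                              "percentile": [50.] * 3,
                              "t_g": [11., 99 / 7, 99 / 5],
                              "gr": [(35 - t) / 99 for t in (26., 28., 30.)]})
        fit = fit_supraoptimal(table, [26., 28., 30.])
        assert fit["T_c"].iloc[0] == pytest.approx(35.0)


class TestThresholdDistribution:
    def test_symmetric_values_give_median(self):
        med, _, _ = fit_threshold_distribution([120., 140., 160.],
                                               [30., 50., 70.], 100.0)
        assert med == pytest.approx(140.0)

    def test_exact_recovery_by_construction(self):
        g = np.array([10., 30., 50., 70., 90.])
        v = 144 + 30 * norm.ppf(g / 100.0)
        med, sd, diag = fit_threshold_distribution(v, g, 100.0)
        assert med == pytest.approx(144.0)
        assert sd == pytest.approx(30.0)
        assert diag["r2"] == pytest.approx(1.0)

    def test_constant_values_have_zero_sd(self):
        _, sd, _ = fit_threshold_distribution([140., 140., 140.],
                                              [30., 50., 70.], 100.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_sign_corrected_for_decreasing_thresholds(self):
        g = np.array([20., 40., 60., 80.])
        v = 35 - 2.5 * norm.ppf(g / 100.0)   # ceiling temperatures
        med, sd, _ = fit_threshold_distribution(v, g, 100.0)
        assert (med, sd) == (pytest.approx(35.0), pytest.approx(2.5))

    def test_single_percentile_rejected(self):
        with pytest.raises(FitError, match="2 distinct percentiles"):
            fit_threshold_distribution([140.], [50.], 100.0)


class TestFitPipeline:
    def test_stochastic_recovery_single_run(self, black_ar_params):
        """One simulated gradient-plate experiment recovers the generating
        cardinal temperatures to within a few degrees."""
        from seedtherm import presets, simulate_experiment
        design = presets.recovery_design("black_ar_1", rng_seed=4)
        fit = fit_pipeline(simulate_experiment(design, black_ar_params))
        assert fit.T_base == pytest.approx(8.0, abs=2.5)
        assert fit.T_opt == pytest.approx(24.0, abs=2.5)
        assert fit.T_c_50 == pytest.approx(35.0, abs=2.5)
        assert fit.T_base < fit.T_opt < fit.T_c_50

    def test_bias_shrinks_with_sample_size(self, black_ar_params):
        """Parameter-recovery consistency: errors at 10 x 100 seeds per
        temperature are no worse than at 3 x 30 (same rng seeds)."""
        from seedtherm import ExperimentDesign, simulate_experiment

        def median_errors(n_dishes, seeds_per_dish):
            errs = {"T_base": [], "T_opt": [], "T_c_50": []}
            for s in range(6):
                design = ExperimentDesign(
                    temperatures=(10., 13., 16., 19., 22., 24., 28., 31.,
                                  34.),
                    n_dishes=n_dishes, seeds_per_dish=seeds_per_dish,
                    scoring_times=tuple(float(d) for d in range(1, 61)),
                    rng_seed=500 + s)
                fit = fit_pipeline(simulate_experiment(design,
                                                       black_ar_params))
                for key, true in [("T_base", 8.), ("T_opt", 24.),
                                  ("T_c_50", 35.)]:
                    errs[key].append(abs(getattr(fit, key) - true))
            return {k: float(np.median(v)) for k, v in errs.items()}

        small = median_errors(3, 30)
        large = median_errors(10, 100)
        for key in small:
            assert large[key] <= small[key] + 0.5

    def test_zero_germination_fails_informatively(self):
        records = [GerminationRecord("d1", t, d, 0, 0, 30)
                   for t in (10., 15., 20., 25.) for d in (1., 2., 3.)]
        with pytest.raises(FitError, match="no germination"):
            fit_pipeline(records)

    def test_too_few_temperatures_rejected(self, small_experiment):
        _, records = small_experiment  # 3 temperatures only
        with pytest.raises(FitError, match="4 temperatures"):
            fit_pipeline(records)

    def test_recovered_theta_monotone_in_percentile(self, black_ar_params):
        from seedtherm import presets, simulate_experiment
        design = presets.recovery_design("black_ar_1", rng_seed=8)
        fit = fit_pipeline(simulate_experiment(design, black_ar_params))
        theta = fit.sub_regressions.sort_values("percentile")["theta_cold"]
        # comonotonic generation: slower percentiles need more degree-days
        assert theta.is_monotonic_increasing
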