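"""Cohort statistics: OLS fits, prediction intervals, MCRS scenario,
ANOVA/ANCOVA against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from clamrepro.cohort_stats import (
    LinearFit,
    count_ancova,
    fit_linear,
    mcrs_scenario,
    occupancy_anova,
    predict_with_ci,
)
from clamrepro.sectioning import section_gonad
from clamrepro.stereology import cavalieri_volume
from clamrepro.synthetic_gonad import generate_gonad


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.df == (1, 3)

    def test_matches_hand_computed_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 3.0, 5.0, 4.0, 6.0])
        # normal-equations oracle
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        resid = y - (slope * x + intercept)
        assert fit.resid_se == pytest.approx(np.sqrt((resid**2).sum() / 3))

    def test_residuals_orthogonal_to_x(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 3 * x + rng.normal(size=40)
        fit = fit_linear(x, y)
        resid = y - fit.predict(x)
        assert abs((resid * x).sum()) < 1e-8 * np.abs(y).sum()

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noise_free_sectioned_cohort_recovers_generator_slope(self, small_config):
        # Cavalieri volumes of noise-free gonads lie on the configured line
        tls = np.array([20.0, 23.0, 26.0, 29.0, 32.0])
        vols = []
        for i, tl in enumerate(tls):
            gonad = generate_gonad(tl, "4A", small_config, seed=i, noise=False)
            table = section_gonad(gonad)
            vols.append(
                cavalieri_volume(table.areas["G_a_mm2"], table.plan.spacing_um)
            )
        fit = fit_linear(tls, np.asarray(vols))
        assert fit.slope == pytest.approx(
            small_config.gv_slope_mm3_per_mm, rel=5e-3
        )


class TestPredictWithCi:
    def test_published_coefficients_reproduce_headline_predictions(self):
        fit = LinearFit.from_coefficients(3.01e4, -5.21e5)
        assert predict_with_ci(fit, 22.0)[0] == pytest.approx(141_200.0)
        assert predict_with_ci(fit, 25.0)[0] == pytest.approx(231_500.0)

    def test_zero_residual_degenerates_to_point(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 5 * x - 2)
        point, lo, hi = predict_with_ci(fit, 4.0)
        assert lo == pytest.approx(point)
        assert hi == pytest.approx(point)

    def test_ci_narrowest_at_mean_of_x(self, rng):
        x = rng.uniform(0, 10, 30)
        fit = fit_linear(x, 2 * x + rng.normal(size=30))
        def width(x0):
            _, lo, hi = predict_with_ci(fit, x0)
            return hi - lo
        assert width(fit.x_mean) < width(fit.x_mean + 2)
        assert width(fit.x_mean) < width(fit.x_mean - 2)

    def test_prediction_interval_wider_than_mean_interval(self, rng):
        x = rng.uniform(0, 10, 30)
        fit = fit_linear(x, 2 * x + rng.normal(size=30))
        _, lo_m, hi_m = predict_with_ci(fit, 5.0)
        _, lo_p, hi_p = predict_with_ci(fit, 5.0, interval="prediction")
        assert hi_p - lo_p > hi_m - lo_m

    def test_extrapolation_warns(self, rng):
        x = rng.uniform(0, 10, 30)
        fit = fit_linear(x, 2 * x + rng.normal(size=30))
        with pytest.warns(UserWarning, match="extrapolates"):
            predict_with_ci(fit, 50.0)


class TestMcrsScenario:
    def test_published_coefficients_give_forty_percent_headline(self):
        fit = LinearFit.from_coefficients(3.01e4, -5.21e5)
        scenario = mcrs_scenario(fit)
        assert scenario.percent_reduction == pytest.approx(39.0065, abs=1e-3)
        assert scenario.percent_reduction_rounded == 40.0
        assert scenario.percent_increase_old_over_new == pytest.approx(63.95, abs=0.01)

    def test_equal_sizes_give_zero_reduction(self):
        fit = LinearFit.from_coefficients(3.01e4, -5.21e5)
        assert mcrs_scenario(fit, 25.0, 25.0).percent_reduction == 0.0

    def test_invariant_under_rescaling_output_units(self):
        base = mcrs_scenario(LinearFit.from_coefficients(3.01e4, -5.21e5))
        doubled = mcrs_scenario(LinearFit.from_coefficients(6.02e4, -10.42e5))
        assert doubled.percent_reduction == pytest.approx(base.percent_reduction)

    def test_nonpositive_prediction_rejected(self):
        fit = LinearFit.from_coefficients(3.01e4, -5.21e5)
        with pytest.raises(ValueError, match="non-positive"):
            mcrs_scenario(fit, 10.0, 25.0)


def _balanced_occupancy(values):
    rows = []
    for (stage, dev_class), cell_values in values.items():
        for i, v in enumerate(cell_values):
            rows.append(
                dict(
                    specimen_id=f"{stage}-{i}",
                    stage=stage,
                    dev_class=dev_class,
                    percent=v,
                )
            )
    return pd.DataFrame(rows)


class TestOccupancyAnova:
    def test_balanced_two_by_two_matches_closed_form(self):
        values = {
            ("F4A", "mature"): [18.0, 20.0, 19.0, 21.0],
            ("F4A", "immature"): [20.0, 22.0, 21.0, 23.0],
            ("F4B", "mature"): [7.0, 9.0, 8.0, 10.0],
            ("F4B", "immature"): [13.0, 15.0, 14.0, 16.0],
        }
        df = _balanced_occupancy(values)
        res = occupancy_anova(df)["anova"]

        # closed-form balanced two-way ANOVA oracle
        arr = {k: np.asarray(v) for k, v in values.items()}
        n = 4
        grand = np.mean([v for a in arr.values() for v in a])
        m_stage = {
            s: np.mean(np.concatenate([arr[(s, c)] for c in ("mature", "immature")]))
            for s in ("F4A", "F4B")
        }
        m_class = {
            c: np.mean(np.concatenate([arr[(s, c)] for s in ("F4A", "F4B")]))
            for c in ("mature", "immature")
        }
        ss_stage = 2 * n * sum((m - grand) ** 2 for m in m_stage.values())
        ss_class = 2 * n * sum((m - grand) ** 2 for m in m_class.values())
        ss_cells = n * sum((a.mean() - grand) ** 2 for a in arr.values())
        ss_inter = ss_cells - ss_stage - ss_class
        ss_err = sum(((a - a.mean()) ** 2).sum() for a in arr.values())
        ms_err = ss_err / (4 * n - 4)

        assert res.loc["C(stage)", "sum_sq"] == pytest.approx(ss_stage)
        assert res.loc["C(dev_class)", "sum_sq"] == pytest.approx(ss_class)
        assert res.loc["C(stage):C(dev_class)", "sum_sq"] == pytest.approx(ss_inter)
        assert res.loc["Residual", "sum_sq"] == pytest.approx(ss_err)
        assert res.loc["C(stage)", "F"] == pytest.approx(ss_stage / ms_err)
        # balanced design: component sums of squares partition the total
        total = sum(((np.asarray(v) - grand) ** 2).sum() for v in values.values())
        assert res["sum_sq"].sum() == pytest.approx(total)

    def test_identical_values_give_zero_effects(self):
        values = {
            (s, c): [10.0, 10.0, 10.0]
            for s in ("F4A", "F4B")
            for c in ("mature", "immature")
        }
        res = occupancy_anova(_balanced_occupancy(values))
        assert res["anova"]["sum_sq"].drop("Residual").max() == pytest.approx(0.0, abs=1e-18)
        assert float(res["tukey"]["stage"]["diff"].iloc[0]) == pytest.approx(0.0)

    def test_empty_cell_named_in_error(self):
        values = {
            ("F4A", "mature"): [18.0, 20.0],
            ("F4A", "immature"): [20.0, 22.0],
            ("F4B", "mature"): [7.0],
            ("F4B", "immature"): [13.0, 15.0],
        }
        with pytest.raises(ValueError, match="F4B"):
            occupancy_anova(_balanced_occupancy(values))


class TestCountAncova:
    @staticmethod
    def _cohort_counts(rng, tl_effect=2.0, noise=0.1):
        rows = []
        for i in range(26):
            tl = rng.uniform(19, 33)
            stage = "F4A" if i < 20 else "F4B"
            for dev_class, base in (("mature", 11.0 if stage == "F4A" else 9.5), ("immature", 13.0)):
                log_count = base + tl_effect * np.log(tl) + rng.normal(0, noise)
                rows.append(
                    dict(
                        specimen_id=f"s{i}",
                        stage=stage,
                        dev_class=dev_class,
                        count=float(np.exp(log_count)),
                        TL_mm=tl,
                    )
                )
        return pd.DataFrame(rows)

    def test_zero_covariate_effect_reduces_to_anova(self, rng):
        df = self._cohort_counts(rng, tl_effect=0.0, noise=0.15)
        res = count_ancova(df)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        data = df.copy()
        data["log_count"] = np.log(data["count"])
        plain = anova_lm(
            smf.ols("log_count ~ C(stage) * C(dev_class)", data=data).fit(), typ=2
        )
        f_ancova = res["ancova"].loc["C(stage)", "F"]
        f_anova = plain.loc["C(stage)", "F"]
        assert f_ancova == pytest.approx(f_anova, rel=0.25)

    def test_parallel_lines_recover_exact_offset(self, rng):
        # no noise: adjusted stage difference equals the constructed offset
        df = self._cohort_counts(rng, noise=0.0)
        res = count_ancova(df)
        assert res["simple_effects"]["mature"]["adjusted_log_difference"] == pytest.approx(
            -1.5
        )
        assert res["simple_effects"]["immature"]["adjusted_log_difference"] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_homogeneity_of_slopes_reported_first(self, rng):
        res = count_ancova(self._cohort_counts(rng))
        assert "homogeneity_of_slopes" in res
        assert res["homogeneity_of_slopes"].shape[0] == 2

    def test_nonpositive_counts_rejected(self, rng):
        df = self._cohort_counts(rng)
        df.loc[0, "count"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            count_ancova(df)
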