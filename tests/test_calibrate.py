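"""Calibration: OLS fits, Cochran/Mandel tests, model selection, inversion."""

import math

import numpy as np
import pytest

import terpfet as tf
from terpfet import calibrate as cal
from terpfet import simulate as sim
from terpfet.pipeline import calibration_response_matrix
from terpfet.simulate import update_kinetics


def _normal_equations_oracle(x, y):
    """Brute-force normal-equations solve, independent of fit_line."""
    A = np.array([[len(x), np.sum(x)], [np.sum(x), np.sum(x * x)]])
    b = np.array([np.sum(y), np.sum(x * y)])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept


class TestFitLine:
    def test_exact_line(self):
        x = np.array([0.05, 0.125, 0.5, 1.0, 2.5, 10.0])
        fit = cal.fit_line(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.s_yx == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = rng.integers(6, 40)
            x = np.sort(rng.uniform(0.01, 10, n))
            y = rng.normal(rng.uniform(-5, 5) + rng.uniform(0.1, 4) * x, 0.3)
            fit = cal.fit_line(x, y)
            slope, intercept = _normal_equations_oracle(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-12)
            assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)

    def test_replicates_collapse(self):
        x1 = np.array([0.05, 0.5, 1.0, 2.5, 10.0])
        y1 = 3 * x1 + 0.2
        x3, y3 = np.repeat(x1, 3), np.repeat(y1, 3)
        f1, f3 = cal.fit_line(x1, y1), cal.fit_line(x3, y3)
        assert f3.slope == pytest.approx(f1.slope)
        assert f3.intercept == pytest.approx(f1.intercept)
        assert f3.n == 3 * f1.n

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            cal.fit_line([1, 2, 3, 4], [1, 2, 3, 4])


class TestCochran:
    def test_equal_variances_statistic_is_one_over_k(self):
        groups = [[0.0, 1.0, 2.0]] * 11  # identical nonzero variances
        res = cal.cochran_test(groups)
        assert res.statistic == pytest.approx(1 / 11)
        assert res.passed

    def test_dominant_variance_fails(self):
        groups = [[0.0, 0.001, 0.002]] * 10 + [[0.0, 5.0, 10.0]]
        res = cal.cochran_test(groups)
        assert res.statistic > 0.99
        assert not res.passed

    def test_all_zero_variances_pass_trivially(self):
        res = cal.cochran_test([[1.0, 1.0]] * 5)
        assert res.passed
        assert res.statistic == pytest.approx(1 / 5)

    def test_critical_value_matches_independent_mc(self):
        """The cached critical value agrees with an independently seeded
        Monte-Carlo quantile of C under normal sampling within 0.01."""
        crit = cal.cochran_critical(11, 2, 0.01)
        rng = np.random.default_rng(20240917)
        samples = rng.normal(size=(200_000, 11, 3))
        variances = samples.var(axis=2, ddof=1)
        c = variances.max(axis=1) / variances.sum(axis=1)
        assert crit == pytest.approx(np.quantile(c, 0.99), abs=0.01)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            cal.cochran_test([[1, 2, 3], [1, 2]])


class TestMandel:
    LEVELS = np.repeat([0.05, 0.125, 0.5, 1.0, 2.5, 5.0, 10.0], 3)

    def test_exact_line_passes_with_zero_statistic(self):
        res = cal.mandel_test(self.LEVELS, 2 * self.LEVELS + 1)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.passed

    def test_exact_parabola_fails(self):
        res = cal.mandel_test(self.LEVELS, self.LEVELS ** 2)
        assert not res.passed
        assert math.isinf(res.statistic)

    def test_noisy_curvature_detected(self):
        rng = np.random.default_rng(3)
        y = 2 * self.LEVELS - 0.08 * self.LEVELS ** 2 + rng.normal(0, 0.01, self.LEVELS.size)
        assert not cal.mandel_test(self.LEVELS, y).passed

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cal.mandel_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])


def _simulated_responses(analyte, cfg, by_name, n_rep=3):
    design = tf.build_calibration_design(by_name[analyte])
    table = sim.simulate_calibration(cfg, {analyte: design.adjusted_levels}, n_rep=n_rep)
    return design, calibration_response_matrix(table, by_name[analyte],
                                               len(design.nominal_levels))


class TestSelectModel:
    def test_noiseless_linear_is_entire(self, by_name, noiseless_config):
        design, y = _simulated_responses("limonene", noiseless_config, by_name)
        sel = cal.select_model(design, y)
        assert sel.kind == "entire"
        assert sel.fits[0].r > 0.9999

    def test_noiseless_two_regime_splits_at_one(self, by_name, noiseless_config):
        cfg = update_kinetics(noiseless_config, "linalool",
                              kink_amount=1.0, kink_slope_ratio=0.4)
        design, y = _simulated_responses("linalool", cfg, by_name)
        sel = cal.select_model(design, y)
        assert sel.kind == "split"
        assert sel.split_point == pytest.approx(1.00)
        low, high = sel.fits
        assert low.x_range == (0.050, 1.00)
        assert high.x_range == (1.00, 10.0)

    def test_saturation_never_selects_entire(self, by_name):
        """Detector saturation below the top calibrator forces a restricted
        or split model for every seed; the modal outcome over seeds is the
        restricted range dropping the 7.5 and 10 ug calibrators."""
        kinds = []
        for seed in range(8):
            cfg = update_kinetics(sim.default_config(seed=seed), "fenchone",
                                  saturation_amount=6.0)
            design, y = _simulated_responses("fenchone", cfg, by_name)
            try:
                sel = cal.select_model(design, y)
            except cal.ModelSelectionError:
                continue
            kinds.append((sel.kind, sel.dropped_top_levels))
            assert sel.kind != "entire"
        assert kinds.count(("restricted", 2)) >= len(kinds) / 2

    def test_no_admissible_model_raises(self, by_name):
        design = tf.build_calibration_design(by_name["limonene"])
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, size=(11, 3))  # structureless responses
        with pytest.raises(cal.ModelSelectionError):
            cal.select_model(design, y)


class TestPredictAmount:
    def _entire(self, by_name, noiseless_config):
        design, y = _simulated_responses("limonene", noiseless_config, by_name)
        return design, cal.select_model(design, y)

    def test_forward_inverse_identity(self, by_name, noiseless_config):
        design, sel = self._entire(by_name, noiseless_config)
        for level in design.adjusted_levels:
            response = sel.fits[0].predict(level)
            amount, flags = cal.predict_amount(sel, response)
            assert amount == pytest.approx(level, rel=1e-9)
            assert not flags - {"transition_zone"}

    def test_above_range_flag(self, by_name, noiseless_config):
        _, sel = self._entire(by_name, noiseless_config)
        top = sel.fits[0].predict(10.0)
        _, flags = cal.predict_amount(sel, top * 1.5)
        assert "above_range" in flags

    def test_split_boundary_uses_low_fit_with_transition_flag(
            self, by_name, noiseless_config):
        cfg = update_kinetics(noiseless_config, "linalool",
                              kink_amount=1.0, kink_slope_ratio=0.4)
        design, y = _simulated_responses("linalool", cfg, by_name)
        sel = cal.select_model(design, y)
        boundary_response = sel.fits[0].predict(1.00)
        amount, flags = cal.predict_amount(sel, boundary_response)
        assert amount == pytest.approx(1.00, rel=1e-9)
        assert "transition_zone" in flags

    def test_split_inverse_identity_both_sides(self, by_name, noiseless_config):
        cfg = update_kinetics(noiseless_config, "linalool",
                              kink_amount=1.0, kink_slope_ratio=0.4)
        design, y = _simulated_responses("linalool", cfg, by_name)
        sel = cal.select_model(design, y)
        for level in design.adjusted_levels:
            fit = sel.fits[0] if level <= 1.0 else sel.fits[1]
            amount, _ = cal.predict_amount(sel, fit.predict(level))
            assert amount == pytest.approx(level, rel=1e-9)

    def test_zero_slope_errors(self):
        fit = cal.CalibrationFit(slope=0.0, intercept=1.0, s_yx=0.0, r=0.0,
                                 n=6, x_mean=1.0, q_x=1.0, x_range=(0.0, 1.0))
        sel = cal.ModelSelection("entire", (fit,), None, 0)
        with pytest.raises(ZeroDivisionError):
            cal.predict_amount(sel, 1.0)
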