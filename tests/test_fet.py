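"""FET verification: scan normalisation, plateaus, size linearity, MHE."""

import math

import numpy as np
import pandas as pd
import pytest

from terpfet import fet
from terpfet import simulate as sim
from terpfet.fet import ScanSeries, compare_mhe, find_plateau, mhe_fit, size_linearity
from terpfet.simulate import evaporated_fraction, update_kinetics


def _series(values, conditions=None, axis="time", reference=None):
    conditions = conditions or list(range(1, len(values) + 1))
    reference = conditions[0] if reference is None else reference
    return ScanSeries(axis=axis, conditions=tuple(map(float, conditions)),
                      mean_areas=tuple(values), normalized=tuple(values),
                      reference_condition=float(reference))


def _scan_table(analyte, conditions, areas, axis="time", sample_type="standard",
                weight=5.0):
    col = {"time": "thermostat_time_min", "temperature": "thermostat_temp_c",
           "weight": "sample_weight_mg"}[axis]
    rows = []
    for c, a in zip(conditions, areas):
        row = {"sample_id": f"s{c}", "analyte": analyte, "rt_min": 24.5,
               "area_target": a, "area_q1": a * 0.6, "area_q2": a * 0.3,
               "sample_weight_mg": weight, "thermostat_temp_c": 100.0,
               "thermostat_time_min": 20.0, "injection_index": 1,
               "sample_type": sample_type}
        row[col] = c
        rows.append(row)
    return pd.DataFrame(rows)


class TestNormalizeScan:
    def test_constant_series_all_one(self):
        table = _scan_table("limonene", [70, 80, 90, 100], [5e4] * 4, "temperature")
        series = fet.normalize_scan(table, "limonene", "temperature", 100)
        assert series.normalized == pytest.approx((1.0,) * 4)
        assert all(series.in_band)

    def test_reference_point_is_one(self):
        table = _scan_table("limonene", [70, 100, 130], [2e4, 5e4, 4e4], "temperature")
        series = fet.normalize_scan(table, "limonene", "temperature", 100)
        idx = series.conditions.index(100.0)
        assert series.normalized[idx] == 1.0

    def test_rescaling_invariance(self):
        table = _scan_table("limonene", [70, 100, 130], [2e4, 5e4, 4e4], "temperature")
        scaled = table.assign(area_target=table.area_target * 17.3)
        a = fet.normalize_scan(table, "limonene", "temperature", 100)
        b = fet.normalize_scan(scaled, "limonene", "temperature", 100)
        assert a.normalized == pytest.approx(b.normalized)

    def test_degradation_pushes_high_temperature_out_of_band(self, noiseless_config):
        """Simulated temperature scan with a 110 C degradation onset: the
        170 C point falls below the 0.7 band edge, as the closed-form
        evaporation/degradation law predicts."""
        cfg = update_kinetics(noiseless_config, "limonene",
                              degradation_onset=110.0, degradation_rate=0.05)
        grid = list(range(70, 171, 10))
        table = sim.simulate_fet_scan("temperature", grid, 2, cfg)
        table = table[table.sample_type == "standard"]
        series = fet.normalize_scan(table, "limonene", "temperature", 100)
        kin = cfg.kinetics["limonene"]
        expected = (evaporated_fraction(kin, 170.0, 20.0)
                    / evaporated_fraction(kin, 100.0, 20.0))
        at170 = series.normalized[series.conditions.index(170.0)]
        assert at170 == pytest.approx(expected, rel=1e-9)
        assert at170 < 0.7

    def test_missing_reference_errors(self):
        table = _scan_table("limonene", [70, 100], [1e4, 2e4], "temperature")
        with pytest.raises(ValueError, match="reference condition"):
            fet.normalize_scan(table, "limonene", "temperature", 160)


class TestFindPlateau:
    def test_constant_series_first_condition(self):
        assert find_plateau(_series([1.0, 1.0, 1.0, 1.0])) == 1.0

    def test_onset_where_values_enter_band(self):
        # 0.6 lies outside the 30 % band of the final value, 0.8 inside
        assert find_plateau(_series([0.4, 0.6, 0.8, 1.0, 1.0])) == 3.0

    def test_never_stabilising_returns_none(self):
        assert find_plateau(_series([1.0, 3.0, 0.2, 1.6, 0.4])) is None

    def test_evaporation_kinetics_plateau_at_20_min(self):
        """k = 0.05/min puts 1 - exp(-k t) inside 30 % of its 40-min value
        first at t = 20 on the standard time grid."""
        grid = [2.5, 5, 10, 15, 20, 25, 30, 35, 40]
        values = [1 - math.exp(-0.05 * t) for t in grid]
        norm = [v / values[grid.index(20)] for v in values]
        series = _series(norm, conditions=grid, reference=20)
        assert find_plateau(series) == 20.0

    def test_monotone_in_tolerance(self):
        series = _series([0.3, 0.75, 0.9, 1.0, 1.0])
        onsets = [find_plateau(series, tol) for tol in (0.40, 0.30, 0.15, 0.05)]
        numeric = [o if o is not None else float("inf") for o in onsets]
        assert numeric == sorted(numeric)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            find_plateau(_series([1.0, 1.0]))


class TestSizeLinearity:
    def test_proportional_r2_one_no_flag(self):
        w = [2.5, 5.0, 7.5, 10.0, 15.0]
        r2, flag = size_linearity(w, [10 * x for x in w])
        assert r2 == pytest.approx(1.0)
        assert flag is False

    def test_saturation_at_top_sets_flag(self):
        w = [2.5, 5.0, 7.5, 10.0, 12.5, 15.0]
        areas = [10 * x for x in w[:3]] + [75.0, 76.0, 77.0]  # capped above 7.5 mg
        r2, flag = size_linearity(w, areas)
        assert r2 <= 0.99
        assert flag is True

    def test_pure_noise_low_r2_no_flag(self):
        rng = np.random.default_rng(4)
        w = np.repeat([2.5, 5.0, 7.5, 10.0, 15.0], 2)
        r2, flag = size_linearity(w, rng.normal(100.0, 5.0, w.size))
        assert r2 < 0.5
        assert flag is False

    def test_too_few_weights(self):
        with pytest.raises(ValueError):
            size_linearity([5.0, 5.0, 10.0], [1.0, 1.1, 2.0])


class TestMHEFit:
    def test_exact_geometric_series(self):
        fit = mhe_fit([1000, 500, 250, 125, 62.5])
        assert fit.slope == pytest.approx(math.log(0.5), rel=1e-12)
        assert fit.q_hat == pytest.approx(0.5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.total_area == pytest.approx(1000 / 0.5, rel=1e-12)

    @pytest.mark.parametrize("q", [0.1, 0.3, 0.62, 0.9])
    def test_recovers_q_to_machine_precision(self, q):
        areas = 2000.0 * (1 - q) ** np.arange(6)
        assert mhe_fit(areas).q_hat == pytest.approx(q, rel=1e-10)

    def test_constant_series_flagged_undefined(self):
        fit = mhe_fit([100.0, 100.0, 100.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert not fit.q_defined
        assert math.isnan(fit.q_hat)

    def test_rejects_nonpositive_areas(self):
        with pytest.raises(ValueError):
            mhe_fit([100.0, 0.0, 10.0])
        with pytest.raises(ValueError):
            mhe_fit([100.0, 50.0])


class TestCompareMHE:
    def test_identical_slopes_pass(self):
        f = mhe_fit([1000, 500, 250])
        deviation, ok = compare_mhe(f, f)
        assert deviation == 0.0 and ok

    def test_thirty_percent_boundary_fails(self):
        sample = mhe_fit(np.exp([-0.0, -0.7, -1.4]))
        standard = mhe_fit(np.exp([-0.0, -1.0, -2.0]))
        deviation, ok = compare_mhe(sample, standard)
        assert deviation == pytest.approx(30.0, abs=1e-9)
        assert ok is False  # strict inequality

    def test_adsorption_deviation_matches_closed_form(self, noiseless_config):
        """Flower MHE with adsorption 0.2 at q = 0.5: slope deviation
        |ln 0.4 - ln 0.5| / |ln 0.5| = 32.19 %, a failing comparison."""
        cfg = noiseless_config
        cfg.extraction_fraction = 0.5
        cfg.adsorption_excess = 0.2
        table = sim.simulate_mhe({"limonene": 1.0}, 5, cfg)
        sample = fet.mhe_fit_from_table(table, "limonene", "flower")
        standard = fet.mhe_fit_from_table(table, "limonene", "standard")
        deviation, ok = compare_mhe(sample, standard)
        expected = abs(math.log(0.4) - math.log(0.5)) / abs(math.log(0.5)) * 100
        assert deviation == pytest.approx(expected, rel=1e-9)
        assert not ok

    def test_log_base_invariance(self):
        """Fitting in log10 scales both slopes by ln(10); the percentage
        deviation between sample and standard is unchanged."""
        a_sample = [900.0, 450.0, 220.0, 110.0]
        a_standard = [1000.0, 480.0, 250.0, 120.0]
        dev_ln, _ = compare_mhe(mhe_fit(a_sample), mhe_fit(a_standard))
        x = np.arange(4)
        s10 = np.polyfit(x, np.log10(a_sample), 1)[0]
        t10 = np.polyfit(x, np.log10(a_standard), 1)[0]
        dev_10 = abs(s10 - t10) / abs(t10) * 100
        assert dev_ln == pytest.approx(dev_10, rel=1e-9)


def test_verify_analyte_report(default_config):
    scans = {
        "temperature": sim.simulate_fet_scan("temperature", list(range(70, 171, 10)),
                                             2, default_config),
        "time": sim.simulate_fet_scan("time", [2.5, 5, 10, 15, 20, 25, 30, 35, 40],
                                      2, default_config),
    }
    mhe = sim.simulate_mhe({"limonene": 1.0}, 5, default_config)
    report = fet.verify_analyte(scans, mhe, "limonene")
    assert report["mhe_pass"]
    assert report["mhe_slope_deviation_pct"] < 30
    assert report["mhe_q_hat_standard"] == pytest.approx(0.3, abs=0.05)
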