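"""Calibration chain: concentration correction, standards, equilibrium, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoroot.isotope_processing import (
    CycleCalibration,
    ProbeReading,
    QCFlag,
    calibrate_cycle,
    calibrate_series,
    daily_summaries,
    equilibrium_alpha,
    fit_concentration_correction,
    liquid_to_vapour,
    method_comparison,
    qc_flags,
    vapour_to_liquid,
)


def _logistic(ppm, lower, upper, inflection, slope):
    return lower + (upper - lower) / (1.0 + (ppm / inflection) ** slope)


class TestConcentrationCorrection:
    def test_flat_series_needs_no_correction(self):
        ppm = np.geomspace(2000, 25000, 12)
        readings = [(p, -8.2) for p in ppm]
        curve = fit_concentration_correction(readings)
        assert np.allclose(curve.correction(ppm), 0.0, atol=1e-6)

    def test_recovers_known_logistic(self):
        rng = np.random.default_rng(0)
        ppm = np.geomspace(1000, 30000, 40)
        true = _logistic(ppm, -5.0, -8.2, 4000.0, 2.0)
        curve = fit_concentration_correction(
            list(zip(ppm, true + rng.normal(0, 0.02, ppm.size)))
        )
        assert curve.r_squared > 0.99
        assert np.allclose(curve.fitted(ppm), true, atol=0.05)

    def test_high_ppm_reading_corrected_not_rejected(self):
        # readings above the QC floor (6000 ppm) stay in the data stream;
        # the floor is an annotation threshold, not a hard cut
        ppm = np.geomspace(1000, 30000, 20)
        curve = fit_concentration_correction([(p, _logistic(p, -5, -8.2, 4000, 2)) for p in ppm])
        corrected = curve.apply(-8.0, 6500.0)
        assert np.isfinite(corrected)

    def test_degenerate_ppm_range_rejected(self):
        with pytest.raises(ValueError, match="3-fold"):
            fit_concentration_correction([(9000 + i, -8.2) for i in range(10)])

    def test_too_few_readings_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_concentration_correction([(1000, -8.0), (9000, -8.2)])


class TestCycleCalibration:
    def test_standards_measured_exactly_gives_identity(self):
        out, cal = calibrate_cycle([(-4.4, -4.4), (-19.5, -19.5)], [-13.0, -7.5])
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0)
        assert np.allclose(out, [-13.0, -7.5])

    def test_worked_two_point_example(self):
        # knowns (−4.4, −19.5), measured (−6.0, −21.3): slope 15.1/15.3
        out, cal = calibrate_cycle([(-4.4, -6.0), (-19.5, -21.3)], [-13.0])
        assert cal.slope == pytest.approx(0.987, abs=1e-3)
        assert out[0] == pytest.approx(-11.31, abs=0.01)

    def test_identical_measured_values_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_cycle([(-4.4, -6.0), (-19.5, -6.0)], [-13.0])

    def test_calibration_idempotent(self):
        standards = [(-4.4, -6.0), (-19.5, -21.3)]
        once, cal = calibrate_cycle(standards, [-13.0, -9.2])
        # recalibrating with the already-calibrated standards is the identity
        recal_standards = [(k, cal.apply(m)) for k, m in standards]
        twice, _ = calibrate_cycle(recal_standards, list(once))
        assert np.allclose(twice, once, atol=1e-12)

    def test_missing_standards_inherit_nearest_cycle(self):
        samples = pd.DataFrame(
            {"cycle": [0, 1, 1, 5], "delta_vapour": [-10.0, -11.0, -12.0, -13.0]}
        )
        standards = pd.DataFrame(
            {
                "cycle": [0, 0, 5, 5],
                "known": [-4.4, -19.5, -4.4, -19.5],
                "delta_vapour": [-5.0, -20.0, -4.4, -19.5],
            }
        )
        out = calibrate_series(samples, standards)
        assert not out.loc[out["cycle"] == 0, "calibration_inherited"].any()
        assert out.loc[out["cycle"] == 1, "calibration_inherited"].all()
        # cycle 1 inherits cycle 0's map (slope 15.1/15 ≈ 1.0067)
        c0 = CycleCalibration(0, (-4.4, -19.5), (-5.0, -20.0))
        assert out.loc[out["cycle"] == 1, "delta_calibrated"].iloc[0] == pytest.approx(
            c0.apply(-11.0)
        )


class TestEquilibriumFractionation:
    def test_alpha_override_identity(self):
        assert vapour_to_liquid(-15.0, 20.0, alpha_override=1.0) == pytest.approx(-15.0)

    def test_majoube_worked_value(self):
        # vapour −19.5 ‰ equilibrated at 20 °C ↔ liquid ≈ −9.90 ‰
        assert vapour_to_liquid(-19.5, 20.0) == pytest.approx(-9.90, abs=0.05)

    def test_liquid_decreases_with_temperature(self):
        temps = np.linspace(-5, 45, 30)
        liquids = vapour_to_liquid(-15.0, temps)
        assert (np.diff(liquids) < 0).all()

    def test_alpha_strictly_decreasing(self):
        temps = np.linspace(-10, 50, 50)
        assert (np.diff(equilibrium_alpha(temps)) < 0).all()

    def test_round_trip_with_inverse(self):
        for t in (0.0, 12.5, 30.0):
            assert vapour_to_liquid(liquid_to_vapour(-9.0, t), t) == pytest.approx(-9.0, abs=1e-12)

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            vapour_to_liquid(-15.0, 60.0)

    @given(st.floats(-30, 0), st.floats(-30, 0), st.floats(-5, 45))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_strictly_increasing_in_vapour_delta(self, d1, d2, t):
        if abs(d1 - d2) < 1e-6:
            return
        lo, hi = sorted((d1, d2))
        assert vapour_to_liquid(lo, t) < vapour_to_liquid(hi, t)


class TestQCFlags:
    def _reading(self, ppm=12000.0, r_s=0.6):
        return ProbeReading("p", pd.Timestamp("2018-07-01"), -10.0, ppm, r_s, 15.0)

    def test_rs_below_standard_threshold_is_clean(self):
        flags = qc_flags(self._reading(r_s=0.6), standards_rs_mean=0.60, standards_rs_sd=0.07)
        assert QCFlag.CONTAMINATED not in flags

    def test_ppm_boundary(self):
        assert QCFlag.LOW_PPM in qc_flags(self._reading(ppm=5999.0), 0.6, 0.07)
        assert QCFlag.LOW_PPM not in qc_flags(self._reading(ppm=6000.0), 0.6, 0.07)

    def test_rs_boundary(self):
        flags = qc_flags(self._reading(r_s=0.68), standards_rs_mean=0.60, standards_rs_sd=0.07)
        assert QCFlag.CONTAMINATED in flags

    def test_nonpositive_ppm_rejected_at_construction(self):
        with pytest.raises(ValueError, match="h2o_ppm"):
            ProbeReading("p", pd.Timestamp("2018-07-01"), -10.0, 0.0, 0.6, 15.0)


class TestDailySummaries:
    def _frame(self, values, probe="tree_1", flagged=None):
        ts = pd.date_range("2018-07-01", periods=len(values), freq="2h")
        df = pd.DataFrame({"probe_id": probe, "timestamp": ts, "delta_liquid": values})
        df["contaminated"] = flagged if flagged is not None else False
        return df

    def test_constant_series(self):
        out = daily_summaries(self._frame([-9.0] * 11))
        assert out["mean"].iloc[0] == pytest.approx(-9.0)
        assert out["sd"].iloc[0] == pytest.approx(0.0)
        assert out["n"].iloc[0] == 11

    def test_hand_computed_mean_and_sd(self):
        vals = [-8.0, -8.5, -9.0, -9.5, -10.0, -8.2, -8.8, -9.3, -9.9, -8.6, -9.1]
        out = daily_summaries(self._frame(vals))
        assert out["mean"].iloc[0] == pytest.approx(np.mean(vals))
        assert out["sd"].iloc[0] == pytest.approx(np.std(vals, ddof=1))

    def test_fully_flagged_day_kept_with_zero_n(self):
        out = daily_summaries(self._frame([-9.0] * 5, flagged=[True] * 5))
        assert len(out) == 1
        assert out["n"].iloc[0] == 0
        assert out["low_n"].iloc[0]

    def test_empty_input_gives_empty_result(self):
        out = daily_summaries(pd.DataFrame(columns=["probe_id", "timestamp", "delta_liquid"]))
        assert out.empty


class TestMethodComparison:
    def test_identity_line(self):
        res = method_comparison([(-9.0, -9.0), (-5.0, -5.0), (-12.0, -12.0), (-7.0, -7.0)])
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["mean_bias"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        pairs = [(r + 0.5, r) for r in (-12.0, -9.0, -6.0, -3.0)]
        res = method_comparison(pairs)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.5)
        assert res["mean_bias"] == pytest.approx(0.5)

    def test_recovers_attenuated_slope(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(-15, -3, 60)
        in_situ = 0.95 * ref + rng.normal(0, 0.1, 60)
        res = method_comparison(list(zip(in_situ, ref)))
        assert res["slope"] == pytest.approx(0.95, abs=0.02)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError, match="3 paired"):
            method_comparison([(-9.0, -9.0), (-5.0, -5.0)])
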