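"""Calibration fitting, back-calculation, surrogate correction factors."""

import numpy as np
import pandas as pd
import pytest

from steroquant.calibration import (
    CalibrationModel,
    CorrectionFactorModel,
    agreement_analysis,
    back_calculate,
    compute_response,
    derive_correction_factor,
    fit_calibration,
    quantify_targeted,
    quantify_untargeted,
    quantify_samples,
    CorrectionFactor,
)
from steroquant.errors import (
    CalibrationError,
    ConfigError,
    DataError,
    MissingInternalStandardError,
)
from steroquant.simulate import GeneratorConfig, generate_calibration

LEVELS = np.geomspace(0.1, 2000.0, 12)


def wls_oracle(x, y, w):
    """Matrix-free weighted least squares via accumulated sums."""
    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
    slope = (sw * swxy - swx * swy) / (sw * swxx - swx**2)
    intercept = (swy - slope * swx) / sw
    return slope, intercept


class TestResponse:
    def test_ratio(self):
        assert compute_response(1000.0, 500.0) == 2.0

    def test_zero_area(self):
        assert compute_response(0.0, 500.0) == 0.0

    def test_zero_is_area_raises(self):
        with pytest.raises(MissingInternalStandardError):
            compute_response(1000.0, 0.0)


class TestCalibrationFit:
    def test_exact_line_recovered(self):
        res = fit_calibration(LEVELS, 0.05 * LEVELS)
        assert res.slope == pytest.approx(0.05, rel=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.accepted and not res.failed_levels

    @pytest.mark.parametrize("weighting", ["none", "1/x", "1/x^2"])
    def test_matches_accumulation_oracle(self, weighting, rng):
        y = 0.05 * LEVELS * np.exp(rng.normal(0, 0.05, LEVELS.size))
        w = {"none": np.ones_like(LEVELS), "1/x": 1 / LEVELS, "1/x^2": 1 / LEVELS**2}[weighting]
        slope, intercept = wls_oracle(LEVELS, y, w)
        res = fit_calibration(LEVELS, y, weighting=weighting)
        assert res.slope == pytest.approx(slope, rel=1e-9)
        assert res.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-12)

    def test_noiseless_four_decades_linear(self):
        res = fit_calibration(LEVELS, 0.05 * LEVELS)
        assert np.log10(LEVELS[-1] / LEVELS[0]) > 4
        assert res.r_squared >= 0.999

    def test_gross_outlier_level_flagged(self):
        y = 0.05 * LEVELS.copy()
        bad = 5  # a mid level reads 2x too high
        y[bad] *= 2.0
        res = fit_calibration(LEVELS, y)
        assert LEVELS[bad] in res.failed_levels
        # independent check: refit without that level back-calculates it at ~+100%
        keep = np.arange(LEVELS.size) != bad
        slope, intercept = wls_oracle(LEVELS[keep], y[keep], 1 / LEVELS[keep] ** 2)
        back = (y[bad] - intercept) / slope
        assert back / LEVELS[bad] == pytest.approx(2.0, rel=0.01)

    def test_rejected_when_too_many_levels_fail(self, rng):
        y = 0.05 * LEVELS * np.exp(rng.normal(0, 0.8, LEVELS.size))
        res = fit_calibration(LEVELS, y)
        assert len(res.failed_levels) > 0.25 * LEVELS.size
        assert not res.accepted
        with pytest.raises(CalibrationError):
            res.back_calculate(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1.0] * 12, [0.05] * 12)


class TestBackCalculate:
    def test_inverse_of_line(self):
        res = fit_calibration(LEVELS, 0.05 * LEVELS)
        conc, flags = back_calculate(res, 2.5)
        assert conc == pytest.approx(50.0, rel=1e-9)
        assert not flags

    def test_round_trip_identity(self):
        res = fit_calibration(LEVELS, 0.05 * LEVELS + 0.003)
        for c in (0.5, 7.3, 912.0):
            conc, _ = back_calculate(res, res.predict(c))
            assert conc == pytest.approx(c, rel=1e-9)

    def test_range_flags(self):
        res = fit_calibration(LEVELS, 0.05 * LEVELS)
        below, flags_lo = back_calculate(res, 0.05 * 0.01)
        assert "below_lloq" in flags_lo and below < res.lloq
        _, flags_hi = back_calculate(res, 0.05 * 5000)
        assert "above_uloq" in flags_hi


class TestCorrectionFactor:
    @staticmethod
    def surrogate_curve():
        return fit_calibration(LEVELS, 0.05 * LEVELS, analyte="A4")

    def test_constructed_11ka4_series_recovers_0329(self):
        # analyte responses map to apparent concentrations of conc / 0.329
        curve = self.surrogate_curve()
        responses = 0.05 * LEVELS / 0.329
        cf = derive_correction_factor(list(zip(LEVELS, responses)), curve, "11KA4")
        assert cf.value == pytest.approx(0.329, rel=1e-9)
        assert cf.surrogate == "A4" and cf.n_levels == 12
        assert cf.constant_within_15pct

    def test_identity_factor_for_surrogate_itself(self):
        curve = self.surrogate_curve()
        cf = derive_correction_factor(list(zip(LEVELS, 0.05 * LEVELS)), curve)
        assert cf.value == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("truth", [0.1, 0.329, 1.0, 3.0])
    def test_parameter_recovery_under_noise(self, truth, panel):
        rng = np.random.default_rng(7)
        curve = fit_calibration(
            LEVELS, 0.05 * LEVELS * np.exp(rng.normal(0, 0.05, LEVELS.size)), analyte="A4"
        )
        responses = 0.05 * LEVELS / truth * np.exp(rng.normal(0, 0.05, LEVELS.size))
        cf = CorrectionFactorModel(LEVELS, responses, curve, "U").fit()
        assert cf.value == pytest.approx(truth, rel=0.05)

    def test_non_positive_apparent_concentration_errors(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS + 0.5, analyte="A4")
        with pytest.raises(CalibrationError):
            derive_correction_factor([(0.1, 0.0), (1.0, 0.01), (10.0, 0.2)], curve)

    def test_too_few_levels(self):
        with pytest.raises(CalibrationError):
            CorrectionFactorModel([1.0, 2.0], [0.05, 0.1], self.surrogate_curve())


class TestQuantify:
    def test_untargeted_applies_factor(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS, analyte="A4")
        cf = CorrectionFactor("11KA4", "A4", 0.329, 1.0, 12)
        # response equivalent to 100 nmol/L A4 -> 32.9 nmol/L of 11KA4
        q = quantify_untargeted(0.05 * 100.0, curve, cf)
        assert q.concentration == pytest.approx(32.9, rel=1e-9)
        assert q.mode == "untargeted"

    def test_unit_factor_reduces_to_surrogate(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS, analyte="A4")
        cf = CorrectionFactor("U", "A4", 1.0, 1.0, 12)
        q = quantify_untargeted(0.05 * 42.0, curve, cf)
        assert q.concentration == pytest.approx(42.0, rel=1e-9)

    def test_surrogate_mismatch_is_config_error(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS, analyte="P4")
        cf = CorrectionFactor("11KA4", "A4", 0.329, 1.0, 12)
        with pytest.raises(ConfigError):
            quantify_untargeted(1.0, curve, cf)

    def test_unverified_factor_flag_propagates(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS, analyte="A4")
        cf = CorrectionFactor("U", "A4", 1.0, 1.0, 12, verified=False)
        assert "unverified_factor" in quantify_untargeted(0.5, curve, cf).flags

    def test_dilution_multiplied_before_range_flags(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS, analyte="P4")
        q = quantify_targeted(0.05 * 600.0, curve, dilution_factor=4.0)
        assert q.concentration == pytest.approx(2400.0, rel=1e-9)
        assert {"diluted", "above_uloq"} <= q.flags

    def test_scale_consistency_doubling_response(self):
        curve = fit_calibration(LEVELS, 0.05 * LEVELS, analyte="A4")
        cf = CorrectionFactor("U", "A4", 0.5, 1.0, 12)
        q1 = quantify_untargeted(0.05 * 10, curve, cf)
        q2 = quantify_untargeted(0.05 * 20, curve, cf)
        assert q2.concentration == pytest.approx(2 * q1.concentration, rel=1e-9)

    def test_quantify_samples_end_to_end_against_truth(self, make_config):
        config = make_config(seed=11, noise_cv=0.0)
        calib, truth = generate_calibration(config)
        areas = pd.DataFrame(
            {
                "sample_id": ["s1"] * 2,
                "analyte": ["P4", "11KA4"],
                # response = slope_true * conc; area = response * is_area
                "area": [
                    truth["slopes"]["P4"] * 50.0 * 1e5,
                    truth["slopes"]["11KA4"] * 20.0 * 1e5,
                ],
                "is_area": [1e5, 1e5],
            }
        )
        out = quantify_samples(config.panel, calib, areas)
        p4 = out[out.analyte == "P4"].iloc[0]
        ka = out[out.analyte == "11KA4"].iloc[0]
        assert p4.conc_nmol_per_l == pytest.approx(50.0, rel=1e-6)
        assert ka.conc_nmol_per_l == pytest.approx(20.0, rel=1e-6)
        assert p4["mode"] == "targeted" and ka["mode"] == "untargeted"


class TestAgreement:
    def test_identical_vectors(self):
        x = [1.0, 2.0, 5.0, 9.0]
        res = agreement_analysis(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.offset == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)

    def test_constant_20pct_bias(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        res = agreement_analysis(x, 1.2 * x)
        assert res.slope == pytest.approx(1.2, rel=1e-9)
        assert res.offset == pytest.approx(0.0, abs=1e-9)

    def test_injected_matrix_bias_recovered(self, rng):
        x = rng.lognormal(1.0, 0.8, 60)
        y = 1.15 * x * np.exp(rng.normal(0, 0.05, x.size))
        res = agreement_analysis(x, y)
        assert res.slope == pytest.approx(1.15, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            agreement_analysis([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
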