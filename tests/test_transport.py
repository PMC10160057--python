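"""Transport quantification: calibration, depletion correction, rates,
P_app, efflux ratios, shear stress and reservoir-depletion checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import eptrans as ep
from eptrans.errors import ValidationError
from eptrans.transport import (
    CalibrationRegression,
    ConcentrationReconstructor,
    TransferRateRegression,
)


class TestCalibration:
    @pytest.mark.parametrize(
        "points, slope, intercept",
        [
            ([(0, 0), (1, 10), (2, 20)], 0.1, 0.0),
            ([(0, 1), (1, 11), (2, 21)], 0.1, -0.1),
        ],
    )
    def test_exact_standard_lines(self, points, slope, intercept):
        curve = ep.fit_calibration(points)
        assert curve.slope == pytest.approx(slope)
        assert curve.intercept == pytest.approx(intercept, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.warning is None

    def test_noisy_standards_recover_generating_slope(self, rng):
        conc = np.linspace(0, 10, 8)
        signal = conc / 0.05 + rng.normal(0, 0.01, conc.size)
        curve = ep.fit_calibration(list(zip(conc, signal)))
        assert curve.slope == pytest.approx(0.05, rel=0.05)

    def test_signal_to_concentration_inverts_standards(self):
        curve = ep.fit_calibration([(0, 1), (1, 11), (2, 21)])
        assert curve.signal_to_concentration(11.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0), (1, 10)],  # too few
            [(0, 5), (1, 5), (2, 5)],  # zero signal variance
            [(0, 0), (0, 1), (0, 2)],  # one distinct concentration
        ],
    )
    def test_degenerate_standards_rejected(self, points):
        with pytest.raises(ValidationError):
            ep.fit_calibration(points)

    def test_low_r_squared_flagged_not_suppressed(self, rng):
        conc = np.array([0.0, 1.0, 2.0, 3.0])
        signal = conc * 10 + rng.normal(0, 5.0, 4)
        with pytest.warns(UserWarning):
            curve = ep.fit_calibration(list(zip(conc, np.abs(signal))))
        assert curve.warning is not None


class TestReconstruction:
    @pytest.mark.parametrize(
        "readings, method, expected",
        [
            ([1.0], "literal_eq2", [0.2]),
            ([1.0, 2.0], "literal_eq2", [0.2, 0.5]),
            ([1.0], "mass_balance", [1.0]),
            ([1.0, 2.0], "mass_balance", [1.0, 2.5]),
        ],
    )
    def test_hand_recursion_examples(self, readings, method, expected,
                                     default_protocol):
        series = ep.SampleSeries(
            times=60.0 * np.arange(1, len(readings) + 1), readings=readings
        )
        rec = ep.reconstruct_concentrations(series, default_protocol, method)
        np.testing.assert_allclose(rec.concentrations, expected)
        assert rec.method == method

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.0, 100.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_literal_recursion_equals_nonrecursive_summation(self, readings):
        """The recursion must equal an independently coded direct sum
        C_T = sum_t (R_t*V_c - R_{t-1}*V_s)/V_n with R_0 = 0."""
        protocol = ep.SamplingProtocol()
        series = ep.SampleSeries(
            times=60.0 * np.arange(1, len(readings) + 1), readings=readings
        )
        rec = ep.reconstruct_concentrations(series, protocol, "literal_eq2")
        prev = 0.0
        expected = []
        total = 0.0
        for r in readings:
            total += (
                r * protocol.channel_volume_ul - prev * protocol.sample_volume_ul
            ) / protocol.normalization_volume_ul
            expected.append(total)
            prev = r
        np.testing.assert_allclose(rec.concentrations, expected, rtol=1e-12)

    def test_mass_balance_ledger_against_brute_force(self, default_protocol):
        readings = [0.5, 1.25, 0.8, 2.0]
        series = ep.SampleSeries(
            times=[60, 120, 180, 240], readings=readings
        )
        rec = ep.reconstruct_concentrations(series, default_protocol, "mass_balance")
        removed = 0.0  # analyte mass carried off so far, per channel volume
        expected = []
        for r in readings:
            expected.append(r + removed / default_protocol.channel_volume_ul)
            removed += r * default_protocol.sample_volume_ul
        np.testing.assert_allclose(rec.concentrations, expected)

    def test_oversized_aliquot_rejected(self):
        with pytest.raises(ValidationError):
            ep.SamplingProtocol(channel_volume_ul=200, sample_volume_ul=300)

    def test_negative_reading_rejected(self):
        rec = ConcentrationReconstructor().fit()
        with pytest.raises(ValidationError):
            rec.transform([-1.0])


class TestTransferRate:
    def test_exact_line(self):
        series = ep.SampleSeries(times=[0, 1, 2, 3], readings=[0, 3, 6, 9],
                                 time_unit="h")
        rate = ep.fit_transfer_rate(series)
        assert rate.slope == pytest.approx(3.0)
        assert rate.r_squared == pytest.approx(1.0)

    def test_flat_series_has_zero_slope(self):
        series = ep.SampleSeries(times=[0, 1, 2, 3], readings=[5, 5, 5, 5])
        rate = ep.fit_transfer_rate(series)
        assert rate.slope == pytest.approx(0.0, abs=1e-12)

    def test_window_restricts_fit(self):
        # linear for 3 h then saturating; 0-3 h window sees only the line
        t = np.array([0.0, 60, 120, 180, 240, 300])
        c = np.array([0.0, 1, 2, 3, 3.2, 3.3])
        series = ep.SampleSeries(times=t, readings=c)
        rate = ep.fit_transfer_rate(series, window=ep.DEFAULT_GLUCOSE_WINDOW_MIN)
        assert rate.slope == pytest.approx(1.0 / 60.0)
        assert rate.n_points == 4

    def test_fewer_than_two_points_in_window_rejected(self):
        series = ep.SampleSeries(times=[0.0, 240.0], readings=[0.0, 1.0])
        with pytest.raises(ValidationError):
            ep.fit_transfer_rate(series, window=(0.0, 60.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        offset=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    def test_slope_shift_invariant_and_scale_equivariant(self, offset, scale):
        t = np.array([0.0, 60, 120, 180])
        c = np.array([0.0, 0.9, 2.1, 3.0])
        base = TransferRateRegression().fit(t, c).slope_
        shifted = TransferRateRegression().fit(t, c + offset).slope_
        scaled = TransferRateRegression().fit(t, c * scale).slope_
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestApparentPermeability:
    def test_zero_rate_gives_zero(self):
        papp = ep.apparent_permeability(
            0.0, c0_uM=2.5, receiver_volume_ul=200, membrane_area_cm2=0.1
        )
        assert papp.value_cm_s == 0.0

    def test_unit_conversion_against_dimensional_analysis(self):
        # independent chain: 1 μM/h * 200 μL = 2e-10 mol/h of analyte;
        # / (0.1 cm² * 2.5e-6 mol/L) = 8e-4 L/(h cm²) = 0.8 cm³/(h cm²)
        # = 0.8/3600 cm/s
        expected = (1e-6 * 200e-6) / (0.1 * 2.5e-6) * 1e3 / 3600.0
        papp = ep.apparent_permeability(
            1.0, c0_uM=2.5, receiver_volume_ul=200, membrane_area_cm2=0.1,
            time_unit="h",
        )
        assert papp.value_cm_s == pytest.approx(expected)
        assert papp.value_cm_s == pytest.approx(2.22e-4, rel=1e-2)

    def test_doubling_area_halves_papp(self):
        kwargs = dict(c0_uM=2.5, receiver_volume_ul=200, time_unit="h")
        one = ep.apparent_permeability(1.0, membrane_area_cm2=0.1, **kwargs)
        two = ep.apparent_permeability(1.0, membrane_area_cm2=0.2, **kwargs)
        assert one.value_cm_s == pytest.approx(2 * two.value_cm_s)

    def test_zero_donor_concentration_rejected(self):
        with pytest.raises(ValidationError):
            ep.apparent_permeability(
                1.0, c0_uM=0.0, receiver_volume_ul=200, membrane_area_cm2=0.1
            )


class TestEffluxSummary:
    def test_ratio_of_slopes(self):
        summary = ep.efflux_summary(2.0, 1.0)
        assert summary.efflux_ratio == pytest.approx(2.0)
        assert not summary.flags

    def test_equal_slopes_mean_no_vectorial_transport(self):
        assert ep.efflux_summary(1.3, 1.3).efflux_ratio == pytest.approx(1.0)

    def test_nonpositive_absorption_flagged_not_infinite(self):
        summary = ep.efflux_summary(2.0, 0.0)
        assert np.isnan(summary.efflux_ratio)
        assert any("undefined" in f for f in summary.flags)

    def test_inhibition_percent(self):
        summary = ep.efflux_summary(2.0, 1.0, rate_inhibited=0.5)
        assert summary.inhibition_percent == pytest.approx(75.0)


class TestShearStress:
    def test_reference_perfusion_condition(self, chip_geometry):
        """0.7 mPa·s medium at 10 μL/min in a 1.0 x 0.35 mm channel."""
        tau = ep.shear_stress(chip_geometry, flow_ul_min=10.0)
        assert round(tau, 2) == 0.06

    def test_zero_flow(self, chip_geometry):
        assert ep.shear_stress(chip_geometry, 0.0) == 0.0

    def test_linear_in_flow_rate(self, chip_geometry):
        tau10 = ep.shear_stress(chip_geometry, 10.0)
        tau1 = ep.shear_stress(chip_geometry, 1.0)
        assert tau1 == pytest.approx(tau10 / 10.0)
        assert tau1 == pytest.approx(0.006, abs=5e-4)

    def test_inverse_square_in_height(self):
        heights = np.linspace(0.2, 1.0, 7)
        taus = [
            ep.shear_stress(
                ep.ChannelGeometry(1.0, h, 10.0, 0.1), 10.0
            )
            for h in heights
        ]
        np.testing.assert_allclose(taus, taus[0] * (heights[0] / heights) ** 2)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValidationError):
            ep.ChannelGeometry(1.0, 0.0, 10.0, 0.1)


class TestReservoirDepletion:
    def test_albumin_protocol_leaves_equilibrium_undisturbed(self):
        protocol = ep.SamplingProtocol(
            channel_volume_ul=200, sample_volume_ul=10, source_volume_ul=3000
        )
        check = ep.reservoir_depletion_check(protocol, n_samples=4)
        assert check.depleted_fraction == pytest.approx(0.0133, abs=1e-4)
        assert not check.flagged

    def test_over_depletion_flagged(self):
        protocol = ep.SamplingProtocol(source_volume_ul=200)
        check = ep.reservoir_depletion_check(protocol, n_samples=4)
        assert check.depleted_fraction == pytest.approx(2.0)
        assert check.flagged

    def test_threshold_logic(self):
        protocol = ep.SamplingProtocol(
            sample_volume_ul=10, source_volume_ul=3000
        )
        check = ep.reservoir_depletion_check(protocol, 4, threshold=0.01)
        assert check.flagged


class TestSklearnContract:
    @pytest.mark.parametrize(
        "estimator",
        [
            CalibrationRegression(min_r_squared=0.95),
            ConcentrationReconstructor(method="mass_balance"),
            TransferRateRegression(window=(0, 180)),
        ],
    )
    def test_get_params_roundtrip_and_clone(self, estimator):
        params = estimator.get_params()
        cloned = clone(estimator)
        assert cloned.get_params() == params
        estimator.set_params(**params)

    def test_calibration_predict_matches_curve(self):
        est = CalibrationRegression().fit([0, 10, 20], [0, 1, 2])
        np.testing.assert_allclose(est.predict([5.0]), [0.5])
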