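"""Instrument calibration, power-law fitting, broadband recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydronirs.calibration import (
    STANDARD_GRID,
    calibrate_cw,
    calibrate_fd,
    extrapolate_musp,
    fit_power_law,
    recover_broadband_mua,
    scale_cw_to_absolute,
)
from hydronirs.optics import FDSample, OpticalProperties, fd_forward


def _phantom(geometry):
    wl = np.array([730.0, 785.0, 830.0, 940.0])
    return OpticalProperties(
        wavelengths=wl,
        mua=np.full(4, 0.0075),
        musp=1.2 * (wl / 800.0) ** (-0.6),
    )


class TestFDCalibration:
    def test_constructed_gain_and_offset_recovered_exactly(self, geometry):
        phantom = _phantom(geometry)
        gains = {730.0: 2.5, 785.0: 0.7, 830.0: 1.3, 940.0: 4.0}
        offsets = {730.0: 0.1, 785.0: -0.2, 830.0: 0.05, 940.0: 0.3}
        raw = []
        for i, wl in enumerate(phantom.wavelengths):
            amp, ph = fd_forward(phantom.mua[i], phantom.musp[i], geometry, 126.0)
            raw.append(FDSample(wl, 126.0, amp * gains[wl], ph + offsets[wl]))
        cal = calibrate_fd(raw, phantom, geometry)
        for wl in gains:
            assert cal.gains[wl] == pytest.approx(gains[wl], rel=1e-12)
            assert cal.phase_offsets[wl] == pytest.approx(offsets[wl], abs=1e-12)
        # applying the calibration reproduces the forward model exactly
        calibrated = cal.apply(raw)
        for i, s in enumerate(calibrated):
            amp, ph = fd_forward(phantom.mua[i], phantom.musp[i], geometry, 126.0)
            assert s.amplitude == pytest.approx(amp, rel=1e-12)
            assert s.phase == pytest.approx(ph, abs=1e-12)

    def test_calibration_is_idempotent(self, geometry):
        phantom = _phantom(geometry)
        raw = []
        for i, wl in enumerate(phantom.wavelengths):
            amp, ph = fd_forward(phantom.mua[i], phantom.musp[i], geometry, 126.0)
            raw.append(FDSample(wl, 126.0, amp * 3.0, ph + 0.2))
        cal = calibrate_fd(raw, phantom, geometry)
        recal = calibrate_fd(cal.apply(raw), phantom, geometry)
        for wl in recal.gains:
            assert recal.gains[wl] == pytest.approx(1.0, abs=1e-12)
            assert recal.phase_offsets[wl] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_phantom_degrades_inversion_gracefully(self, geometry):
        # 0.5% calibration noise should not more than double the inversion
        # error seen under 1% measurement noise with a perfect calibration
        from hydronirs.optics import invert_fd

        phantom = _phantom(geometry)
        rng = np.random.default_rng(11)
        test_mua, test_musp = 0.012, 1.1

        def median_error(cal_noise):
            errs = []
            for _ in range(40):
                raw = []
                for i, wl in enumerate(phantom.wavelengths):
                    amp, ph = fd_forward(phantom.mua[i], phantom.musp[i],
                                         geometry, 126.0)
                    g = 2.0 * np.exp(rng.normal(0.0, cal_noise))
                    d = 0.1 + rng.normal(0.0, cal_noise)
                    raw.append(FDSample(wl, 126.0, amp * g, ph + d))
                cal = calibrate_fd(raw, phantom, geometry)
                amp, ph = fd_forward(test_mua, test_musp, geometry, 126.0)
                meas = FDSample(830.0, 126.0,
                                amp * 2.0 * np.exp(rng.normal(0.0, 0.01)),
                                ph + 0.1 + rng.normal(0.0, 0.005))
                s = cal.apply([meas])[0]
                res = invert_fd([s], geometry, x0=(test_mua, test_musp))
                errs.append(abs(res.mua - test_mua) / test_mua)
            return np.median(errs)

        assert median_error(0.005) < 2.0 * median_error(0.0)

    def test_missing_phantom_wavelength_reported(self, geometry):
        phantom = _phantom(geometry)
        raw = [FDSample(999.0, 126.0, 1.0, 0.1)]
        with pytest.raises(ValueError, match="999"):
            calibrate_fd(raw, phantom, geometry)


class TestCWCalibration:
    def test_gain_removed_by_construction(self, rng):
        wl = STANDARD_GRID
        true_refl = 1e-5 * np.exp(-((wl - 850.0) / 120.0) ** 2)
        gain = 1e4 * (1.0 + 0.3 * np.sin(wl / 40.0))
        reflectivity = np.full(wl.shape, 0.99)
        out, mask = calibrate_cw(true_refl * gain, gain * reflectivity,
                                 reflectivity, wl)
        assert not mask.any()
        assert np.allclose(out, true_refl, rtol=1e-12)

    def test_identical_inputs_with_unit_reflectivity_give_ones(self):
        wl = STANDARD_GRID
        spectrum = np.linspace(1.0, 2.0, wl.size)
        out, _ = calibrate_cw(spectrum, spectrum, 1.0, wl)
        assert np.allclose(out, 1.0)

    def test_dead_pixel_masks_exactly_one_wavelength(self):
        wl = STANDARD_GRID
        standard = np.ones(wl.size)
        standard[40] = 0.0
        out, mask = calibrate_cw(np.ones(wl.size), standard, 1.0, wl)
        assert mask.sum() == 1
        assert np.isnan(out[40])
        assert np.isfinite(np.delete(out, 40)).all()

    def test_scale_invariance_of_calibration(self, rng):
        wl = STANDARD_GRID
        raw = rng.uniform(1.0, 2.0, wl.size)
        std = rng.uniform(1.0, 2.0, wl.size)
        out1, _ = calibrate_cw(raw, std, 0.99, wl)
        out2, _ = calibrate_cw(raw * 37.2, std * 37.2, 0.99, wl)
        assert np.allclose(out1, out2, rtol=1e-12)


class TestPowerLaw:
    def test_closed_form_recovery_at_study_wavelengths(self):
        wl = np.array([730.0, 785.0, 830.0, 940.0])
        law = fit_power_law(wl, 1.2 * (wl / 800.0) ** (-1.3))
        assert law.amplitude_a == pytest.approx(1.2, rel=1e-9)
        assert law.power_b == pytest.approx(1.3, rel=1e-9)
        # matches an independent log-log linear-regression oracle
        slope, intercept = np.polyfit(
            np.log(wl / 800.0), np.log(1.2 * (wl / 800.0) ** (-1.3)), 1
        )
        assert law.power_b == pytest.approx(-slope, rel=1e-12)
        assert law.amplitude_a == pytest.approx(np.exp(intercept), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.3, max_value=3.0),
        b=st.floats(min_value=0.0, max_value=4.0),
    )
    def test_exact_on_noiseless_power_law_data(self, a, b):
        wl = np.array([730.0, 785.0, 830.0, 940.0])
        law = fit_power_law(wl, a * (wl / 800.0) ** (-b))
        assert abs(law.amplitude_a - a) <= 1e-9 * max(a, 1.0)
        assert abs(law.power_b - b) <= 1e-9 * max(b, 1.0)
        assert law.fit_residual < 1e-12

    def test_evaluation_at_reference_wavelength_returns_amplitude(self):
        law = fit_power_law([730.0, 940.0], [1.5, 1.1])
        assert extrapolate_musp(law, [800.0])[0] == pytest.approx(
            law.amplitude_a, rel=1e-12
        )

    def test_constant_musp_gives_zero_power(self):
        law = fit_power_law([730.0, 785.0, 830.0], [0.9, 0.9, 0.9])
        assert law.power_b == pytest.approx(0.0, abs=1e-12)
        assert law.amplitude_a == pytest.approx(0.9, rel=1e-12)

    def test_halving_relative_wavelength_doubles_musp_at_unit_power(self):
        law = fit_power_law([700.0, 1000.0], [1.0 * (700 / 800.0) ** -1.0,
                                              1.0 * (1000 / 800.0) ** -1.0])
        vals = extrapolate_musp(law, [400.0, 800.0])
        assert vals[0] == pytest.approx(2.0 * vals[1], rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([800.0], [1.0])
        with pytest.raises(ValueError):
            fit_power_law([700.0, 900.0], [1.0, -0.1])


class TestScaleCWToAbsolute:
    def _fd_props(self, lut, geometry):
        # anchors chosen on the 2 nm working grid so construction is exact
        wl = np.array([730.0, 784.0, 830.0, 940.0])
        law = fit_power_law(wl, 1.1 * (wl / 800.0) ** (-1.0))
        mua = np.array([0.008, 0.009, 0.01, 0.02])
        return OpticalProperties(wavelengths=wl, mua=mua,
                                 musp=extrapolate_musp(law, wl)), law

    def _model_spectrum(self, lut, props, law):
        wl = STANDARD_GRID
        mua = np.interp(wl, props.wavelengths, props.mua)
        musp = extrapolate_musp(law, wl)
        return lut.cw_at(mua, musp), mua, musp

    def test_already_absolute_spectrum_gets_unit_scale(self, lut, geometry):
        props, law = self._fd_props(lut, geometry)
        model, _, _ = self._model_spectrum(lut, props, law)
        scaled, gain, resid = scale_cw_to_absolute(
            model, STANDARD_GRID, props, law, lut
        )
        assert np.allclose(gain, 1.0, atol=1e-10)
        assert np.allclose(scaled, model, rtol=1e-10)

    def test_wavelength_independent_gain_recovered(self, lut, geometry):
        props, law = self._fd_props(lut, geometry)
        model, _, _ = self._model_spectrum(lut, props, law)
        scaled, gain, resid = scale_cw_to_absolute(
            model / 3.7, STANDARD_GRID, props, law, lut, mode="scalar"
        )
        assert np.allclose(gain, 3.7, rtol=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(scaled, model, rtol=1e-9)

    def test_smooth_gain_removed_at_anchors(self, lut, geometry):
        props, law = self._fd_props(lut, geometry)
        model, _, _ = self._model_spectrum(lut, props, law)
        wl = STANDARD_GRID
        smooth_gain = np.exp(0.1 * np.sin((wl - 700.0) / 90.0))
        scaled, _, _ = scale_cw_to_absolute(
            model * smooth_gain, wl, props, law, lut, mode="anchored_smooth"
        )
        anchors = props.wavelengths
        got = np.interp(anchors, wl, scaled)
        want = np.interp(anchors, wl, model)
        assert np.allclose(got, want, rtol=1e-2)

    def test_fd_wavelength_outside_grid_rejected(self, lut, geometry):
        props = OpticalProperties(
            wavelengths=np.array([650.0, 800.0]),
            mua=np.array([0.01, 0.01]),
            musp=np.array([1.0, 1.0]),
        )
        law = fit_power_law([730.0, 940.0], [1.2, 1.0])
        with pytest.raises(ValueError, match="outside"):
            scale_cw_to_absolute(
                np.ones(STANDARD_GRID.size), STANDARD_GRID, props, law, lut
            )


class TestBroadbandRecovery:
    def test_round_trip_from_forward_model(self, lut):
        wl = STANDARD_GRID
        law = fit_power_law([730.0, 940.0],
                            [1.1 * (730 / 800.0) ** -1.0,
                             1.1 * (940 / 800.0) ** -1.0])
        musp = extrapolate_musp(law, wl)
        mua_true = 0.005 + 0.02 * np.exp(-((wl - 970.0) / 40.0) ** 2)
        refl = lut.cw_at(mua_true, musp)
        rec = recover_broadband_mua(refl, musp, lut, wl)
        assert rec.valid
        assert np.nanmax(np.abs(rec.mua - mua_true) / mua_true) < 0.005

    def test_reflectance_at_node_recovers_node_mua(self, lut):
        i, j = 25, 30
        refl = np.array([lut.cw_reflectance[i, j]])
        musp = np.array([lut.musp_grid[j]])
        rec = recover_broadband_mua(refl, musp, lut, np.array([800.0]),
                                    max_masked_fraction=1.0)
        assert rec.mua[0] == pytest.approx(lut.mua_grid[i], rel=1e-4)

    def test_monotone_map_reflectance_to_absorption(self, lut):
        musp = np.full(20, 1.0)
        refl = np.linspace(
            lut.cw_at(0.05, 1.0), lut.cw_at(0.002, 1.0), 20
        ).ravel()
        rec = recover_broadband_mua(refl, musp, lut,
                                    np.linspace(700, 1000, 20),
                                    max_masked_fraction=1.0)
        assert np.all(np.diff(rec.mua) < 0)

    def test_out_of_range_masked_and_flagged(self, lut):
        wl = np.linspace(700.0, 1000.0, 10)
        musp = np.full(10, 1.0)
        refl = np.full(10, 1e3)  # far above any tabulated reflectance
        with pytest.warns(UserWarning, match="flagged invalid"):
            rec = recover_broadband_mua(refl, musp, lut, wl)
        assert not rec.valid
        assert rec.n_masked == 10
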