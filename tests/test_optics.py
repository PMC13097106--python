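"""Forward models, look-up table, FD inversion, Goertzel estimator."""

import numpy as np
import pytest

from hydronirs.montecarlo import WhiteMonteCarlo
from hydronirs.optics import (
    DEFAULT_MUA_GRID,
    DEFAULT_MUSP_GRID,
    FDSample,
    LookupTable,
    MeasurementGeometry,
    build_lut,
    cw_forward,
    fd_forward,
    goertzel,
    invert_fd,
)


class TestForwardModel:
    def test_dc_limit_has_zero_phase(self, geometry):
        amp, phase = fd_forward(0.01, 1.0, geometry, frequency_mhz=0.0)
        assert amp > 0
        assert phase == pytest.approx(0.0, abs=1e-15)

    def test_cw_equals_fd_amplitude_at_zero_frequency(self, geometry):
        amp, _ = fd_forward(0.013, 0.8, geometry, frequency_mhz=0.0)
        assert cw_forward(0.013, 0.8, geometry) == pytest.approx(amp, rel=1e-14)

    def test_amplitude_strictly_decreasing_in_absorption(self, geometry):
        mua = np.linspace(0.002, 0.05, 50)
        amps = [fd_forward(m, 1.0, geometry, 126.0)[0] for m in mua]
        assert np.all(np.diff(amps) < 0)

    def test_cw_reflectance_monotone_in_scattering(self, geometry):
        # At a 20 mm separation the measurement is in the far field: raising
        # musp raises mu_eff and the exponential attenuation dominates the
        # source-strength prefactor, so reflectance falls monotonically.
        musp = np.linspace(0.3, 2.0, 40)
        refl = [cw_forward(0.01, s, geometry) for s in musp]
        assert np.all(np.diff(refl) < 0)

    def test_phase_increases_with_modulation_frequency(self, geometry):
        freqs = np.linspace(119.0, 134.0, 16)
        phases = [fd_forward(0.01, 1.0, geometry, f)[1] for f in freqs]
        assert np.all(np.diff(phases) > 0)

    def test_phase_within_principal_interval(self, geometry):
        for mua, musp in [(0.001, 0.3), (0.06, 2.5), (0.01, 1.0)]:
            _, phase = fd_forward(mua, musp, geometry, 134.0)
            assert -np.pi < phase <= np.pi

    @pytest.mark.parametrize("mua,musp", [(0.0, 1.0), (-0.01, 1.0), (0.01, 0.0)])
    def test_nonpositive_properties_rejected(self, geometry, mua, musp):
        with pytest.raises(ValueError):
            fd_forward(mua, musp, geometry, 126.0)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            MeasurementGeometry(source_detector_separation=-1.0)
        with pytest.raises(ValueError):
            MeasurementGeometry(refractive_index=0.9)


class TestGoertzel:
    def test_pure_cosine_at_bin_frequency(self):
        n, k = 1024, 32
        t = np.arange(n)
        x = 2.5 * np.cos(2 * np.pi * k * t / n)
        amp, phase = goertzel(x, float(n), float(k))
        assert amp == pytest.approx(2.5, abs=1e-9)
        assert phase == pytest.approx(0.0, abs=1e-9)

    def test_zero_signal(self):
        amp, _ = goertzel(np.zeros(64), 64.0, 4.0)
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_matches_fft_bin_on_random_signal(self, rng):
        x = rng.standard_normal(1024)
        spectrum = np.fft.rfft(x)
        for k in (1, 17, 100, 511):
            amp, phase = goertzel(x, 1024.0, float(k))
            ref = spectrum[k]
            assert amp == pytest.approx(2 * np.abs(ref) / 1024, rel=1e-9)
            assert phase == pytest.approx(np.angle(ref), abs=1e-9)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            goertzel(np.ones(16), 16.0, 8.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            goertzel(np.ones(1), 16.0, 2.0)


class TestLookupTable:
    def test_node_values_equal_direct_forward(self, lut, geometry):
        for i in (0, 17, 59):
            for j in (0, 30, 59):
                mua = lut.mua_grid[i]
                musp = lut.musp_grid[j]
                assert lut.cw_reflectance[i, j] == pytest.approx(
                    cw_forward(mua, musp, geometry), rel=1e-12
                )
                amp, phase = fd_forward(mua, musp, geometry,
                                        lut.frequencies_mhz[0])
                assert lut.fd_amplitude[0, i, j] == pytest.approx(amp, rel=1e-12)
                assert lut.fd_phase[0, i, j] == pytest.approx(phase, abs=1e-12)

    def test_interpolation_at_nodes_is_exact(self, lut):
        mm, ss = np.meshgrid(lut.mua_grid[::9], lut.musp_grid[::9], indexing="ij")
        interp = lut.cw_at(mm, ss)
        direct = lut.cw_reflectance[::9, ::9]
        assert np.allclose(interp, direct, rtol=1e-9)

    def test_off_node_interpolation_below_half_percent(self, lut, geometry):
        mua_mid = np.sqrt(lut.mua_grid[:-1] * lut.mua_grid[1:])[::6]
        musp_mid = np.sqrt(lut.musp_grid[:-1] * lut.musp_grid[1:])[::6]
        mm, ss = np.meshgrid(mua_mid, musp_mid, indexing="ij")
        interp = lut.cw_at(mm, ss)
        direct = np.vectorize(lambda a, s: cw_forward(a, s, geometry))(mm, ss)
        assert np.max(np.abs(interp - direct) / direct) < 0.005

    def test_cw_strictly_decreasing_in_mua(self, lut):
        assert np.all(np.diff(lut.cw_reflectance, axis=0) < 0)

    def test_fd_phase_increases_with_frequency(self, lut):
        assert np.all(np.diff(lut.fd_phase, axis=0) > 0)

    def test_serialization_round_trip(self, lut, tmp_path):
        path = tmp_path / "lut.json"
        lut.to_json(path)
        back = LookupTable.from_json(path)
        assert np.array_equal(back.mua_grid, lut.mua_grid)
        assert np.array_equal(back.cw_reflectance, lut.cw_reflectance)
        assert np.array_equal(back.fd_phase, lut.fd_phase)
        assert back.geometry == lut.geometry
        assert back.builder == lut.builder

    def test_grids_must_ascend(self, lut, geometry):
        with pytest.raises(ValueError):
            LookupTable(
                mua_grid=lut.mua_grid[::-1],
                musp_grid=lut.musp_grid,
                frequencies_mhz=lut.frequencies_mhz,
                cw_reflectance=lut.cw_reflectance,
                fd_amplitude=lut.fd_amplitude,
                fd_phase=lut.fd_phase,
                geometry=geometry,
            )

    def test_coarse_grid_warns(self, geometry):
        with pytest.warns(UserWarning, match="too coarse"):
            build_lut(
                mua_grid=np.geomspace(0.001, 0.06, 4),
                musp_grid=np.geomspace(0.3, 2.5, 4),
                geometry=geometry,
                interp_tolerance=1e-4,
            )

    def test_white_mc_builder_reproducible_with_seed(self, geometry):
        kwargs = dict(
            mua_grid=np.geomspace(0.005, 0.03, 3),
            musp_grid=np.geomspace(0.8, 1.5, 3),
            geometry=geometry,
            frequencies_mhz=(126.0,),
            builder="white_mc",
            mc_photons=30_000,
            mc_seed=7,
        )
        lut_a = build_lut(**kwargs)
        lut_b = build_lut(**kwargs)
        assert np.array_equal(lut_a.cw_reflectance, lut_b.cw_reflectance)
        assert np.array_equal(lut_a.fd_amplitude, lut_b.fd_amplitude)
        assert np.array_equal(lut_a.fd_phase, lut_b.fd_phase)

    def test_white_mc_requires_seed(self, geometry):
        with pytest.raises(ValueError, match="seed"):
            build_lut(builder="white_mc", geometry=geometry)


class TestInversion:
    def test_round_trip_on_property_grid(self, geometry):
        for mua in np.geomspace(0.003, 0.04, 5):
            for musp in np.geomspace(0.5, 2.0, 5):
                samples = []
                for f in (122.0, 130.0):
                    amp, phase = fd_forward(mua, musp, geometry, f)
                    samples.append(FDSample(830.0, f, amp, phase))
                res = invert_fd(samples, geometry)
                assert res.mua == pytest.approx(mua, rel=1e-4)
                assert res.musp == pytest.approx(musp, rel=1e-4)
                assert not res.out_of_range

    def test_single_sample_round_trip(self, geometry):
        amp, phase = fd_forward(0.01, 1.0, geometry, 126.0)
        res = invert_fd([FDSample(830.0, 126.0, amp, phase)], geometry)
        assert res.mua == pytest.approx(0.01, rel=1e-4)
        assert res.musp == pytest.approx(1.0, rel=1e-4)

    def test_median_absorption_error_under_noise(self, geometry):
        rel_errors = []
        rng = np.random.default_rng(42)
        for _ in range(100):
            samples = []
            for f in (122.0, 130.0):
                amp, phase = fd_forward(0.01, 1.0, geometry, f)
                amp *= np.exp(rng.normal(0.0, 0.01))
                phase += rng.normal(0.0, 0.005)
                samples.append(FDSample(830.0, f, amp, phase))
            res = invert_fd(samples, geometry, x0=(0.012, 0.9))
            rel_errors.append(abs(res.mua - 0.01) / 0.01)
        assert np.median(rel_errors) < 0.05

    def test_optimum_beats_random_parameter_draws(self, geometry):
        rng = np.random.default_rng(3)
        amp, phase = fd_forward(0.015, 1.2, geometry, 126.0)
        amp *= 1.01
        sample = FDSample(830.0, 126.0, amp, phase)
        res = invert_fd([sample], geometry)

        def objective(mua, musp):
            a, p = fd_forward(mua, musp, geometry, 126.0)
            return ((np.log(a) - np.log(amp)) / 0.01) ** 2 + (
                (p - phase) / 0.005
            ) ** 2

        best_obj = objective(res.mua, res.musp)
        for _ in range(200):
            mua = rng.uniform(0.001, 0.06)
            musp = rng.uniform(0.3, 2.5)
            assert best_obj <= objective(mua, musp) + 1e-9

    def test_unattainable_measurement_flagged_out_of_range(self, geometry):
        # amplitude far above anything the medium can produce pins the
        # optimum at the parameter bounds
        amp, phase = fd_forward(0.001, 2.5, geometry, 126.0)
        res = invert_fd([FDSample(830.0, 126.0, amp * 1e4, phase)], geometry)
        assert res.out_of_range

    def test_empty_samples_rejected(self, geometry):
        with pytest.raises(ValueError):
            invert_fd([], geometry)


class TestWhiteMonteCarloEngine:
    def test_seeded_runs_are_identical(self):
        a = WhiteMonteCarlo(n_photons=20_000, seed=5)
        a.run()
        b = WhiteMonteCarlo(n_photons=20_000, seed=5)
        b.run()
        assert np.array_equal(a._w_hist, b._w_hist)
        assert np.array_equal(a._wl_hist, b._wl_hist)

    def test_requires_seed(self):
        with pytest.raises(ValueError):
            WhiteMonteCarlo(n_photons=1000).run()

    def test_reflectance_requires_run(self):
        engine = WhiteMonteCarlo(n_photons=1000, seed=1)
        with pytest.raises(RuntimeError):
            engine.reflectance(0.01, 1.0, 20.0, 0.0)


def test_default_grids_cover_physiological_range():
    assert DEFAULT_MUA_GRID[0] <= 0.001 and DEFAULT_MUA_GRID[-1] >= 0.06
    assert DEFAULT_MUSP_GRID[0] <= 0.3 and DEFAULT_MUSP_GRID[-1] >= 2.5
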