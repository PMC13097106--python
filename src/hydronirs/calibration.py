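"""Instrument-response removal and broadband optical-property recovery.

The clinical instrument measures FD amplitude/phase in arbitrary units with
unknown per-wavelength gain and phase offset, and CW spectra multiplied by
the spectral response of the lamp/fiber/spectrometer chain. Calibration
measurements on references with known optics remove both:

* a solid silicone phantom with known (mua, musp) calibrates the FD channel;
* a diffuse reflectance standard (known reflectivity) calibrates the CW
  channel.

After calibration, the FD channel gives absolute (mua, musp) at its four
wavelengths; the scattering power law fitted to those anchors extrapolates
musp over the full 700-1000 nm band; the calibrated CW spectrum, scaled to
the forward model at the FD anchors, is then inverted wavelength-by-
wavelength through the look-up table to yield the absolute broadband
absorption spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import (
    FDSample,
    LookupTable,
    MeasurementGeometry,
    OpticalProperties,
    fd_forward,
)

__all__ = [
    "ScatteringPowerLaw",
    "FDCalibration",
    "CWCalibration",
    "BroadbandRecovery",
    "calibrate_fd",
    "calibrate_cw",
    "fit_power_law",
    "extrapolate_musp",
    "scale_cw_to_absolute",
    "recover_broadband_mua",
]

STANDARD_GRID = np.arange(700.0, 1000.0 + 1e-9, 2.0)
"""Uniform 2 nm working wavelength grid, 700-1000 nm."""


@dataclass
class ScatteringPowerLaw:
    """Power-law wavelength dependence of reduced scattering.

    ``musp(lambda) = amplitude_a * (lambda / reference_wavelength) ** (-power_b)``
    with the scattering amplitude ``a`` equal to musp at the reference
    wavelength (800 nm by convention) and ``b`` the scattering power.
    """

    amplitude_a: float  # mm^-1
    power_b: float
    reference_wavelength: float = 800.0  # nm
    fit_residual: float = 0.0  # RMS of log-space residuals

    def __post_init__(self) -> None:
        if self.amplitude_a <= 0:
            raise ValueError("amplitude_a must be > 0")

    def __call__(self, wavelengths) -> np.ndarray:
        return extrapolate_musp(self, wavelengths)


@dataclass
class FDCalibration:
    """Per-wavelength amplitude gain and phase offset of the FD channel."""

    gains: dict[float, float]
    phase_offsets: dict[float, float]

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gains.values()):
            raise ValueError("gains must be > 0")

    def apply(self, samples) -> list[FDSample]:
        """Convert raw FD samples to forward-model units."""
        out = []
        for s in samples:
            if s.wavelength not in self.gains:
                raise KeyError(
                    f"no calibration for wavelength {s.wavelength} nm "
                    f"(have {sorted(self.gains)})"
                )
            out.append(
                FDSample(
                    wavelength=s.wavelength,
                    modulation_frequency=s.modulation_frequency,
                    amplitude=s.amplitude / self.gains[s.wavelength],
                    phase=s.phase - self.phase_offsets[s.wavelength],
                )
            )
        return out


@dataclass
class CWCalibration:
    """Spectral gain of the CW channel over the working grid.

    ``mask`` marks wavelengths with unusable (non-positive) reference counts.
    """

    wavelengths: np.ndarray
    gains: np.ndarray
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.wavelengths.shape, dtype=bool)
        if np.any(self.gains[~self.mask] <= 0):
            raise ValueError("gains must be > 0 on the usable grid")


def calibrate_fd(
    raw_phantom_samples,
    phantom_props: OpticalProperties,
    geometry: MeasurementGeometry = MeasurementGeometry(),
) -> FDCalibration:
    """Derive FD gains/offsets from a measurement of the calibration phantom.

    Applying the returned calibration to the phantom measurement reproduces
    the forward model of the phantom exactly (one gain/offset per
    wavelength; with several frequencies per wavelength the geometric-mean
    gain and circular-mean offset are used).
    """
    raw_phantom_samples = list(raw_phantom_samples)
    missing = sorted(
        {s.wavelength for s in raw_phantom_samples}
        - set(np.round(phantom_props.wavelengths, 6))
    )
    if missing:
        raise ValueError(f"phantom reference missing wavelengths: {missing}")
    by_wl: dict[float, list[FDSample]] = {}
    for s in raw_phantom_samples:
        by_wl.setdefault(s.wavelength, []).append(s)
    gains: dict[float, float] = {}
    offsets: dict[float, float] = {}
    for wl, samples in by_wl.items():
        idx = int(np.argmin(np.abs(phantom_props.wavelengths - wl)))
        mua = phantom_props.mua[idx]
        musp = phantom_props.musp[idx]
        log_g = []
        d_phase = []
        for s in samples:
            amp_m, ph_m = fd_forward(mua, musp, geometry, s.modulation_frequency)
            log_g.append(np.log(s.amplitude / amp_m))
            d_phase.append(s.phase - ph_m)
        gains[wl] = float(np.exp(np.mean(log_g)))
        offsets[wl] = float(
            np.angle(np.mean(np.exp(1j * np.asarray(d_phase))))
        )
    return FDCalibration(gains=gains, phase_offsets=offsets)


def calibrate_cw(
    raw_spectrum: np.ndarray,
    standard_measurement: np.ndarray,
    standard_reflectivity,
    wavelengths: np.ndarray = STANDARD_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrate a raw CW spectrum against the reflectance-standard scan.

    ``out = raw / standard * standard_reflectivity``; wavelengths with
    non-positive standard counts are masked (NaN) and reported.

    Returns ``(calibrated_spectrum, mask)`` where ``mask`` is True at
    masked wavelengths.
    """
    raw = np.asarray(raw_spectrum, dtype=float)
    std = np.asarray(standard_measurement, dtype=float)
    refl = np.broadcast_to(np.asarray(standard_reflectivity, dtype=float), raw.shape)
    if raw.shape != std.shape:
        raise ValueError("raw and standard spectra must share the grid")
    mask = std <= 0
    out = np.full(raw.shape, np.nan)
    out[~mask] = raw[~mask] / std[~mask] * refl[~mask]
    return out, mask


def fit_power_law(wavelengths, musp_values, reference_wavelength: float = 800.0) -> ScatteringPowerLaw:
    """Least-squares power-law fit ``musp = a (lambda/lambda0)^-b``.

    The fit is linear in log-log space (exact and convex); the residual is
    the RMS of log-space misfit.
    """
    wl = np.asarray(wavelengths, dtype=float)
    mu = np.asarray(musp_values, dtype=float)
    ok = np.isfinite(wl) & np.isfinite(mu)
    wl, mu = wl[ok], mu[ok]
    if np.unique(wl).size < 2:
        raise ValueError("need at least two distinct wavelengths")
    if np.any(mu <= 0):
        raise ValueError("musp values must be positive")
    x = np.log(wl / reference_wavelength)
    y = np.log(mu)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return ScatteringPowerLaw(
        amplitude_a=float(np.exp(intercept)),
        power_b=float(-slope),
        reference_wavelength=reference_wavelength,
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )


def extrapolate_musp(law: ScatteringPowerLaw, wavelengths) -> np.ndarray:
    """Evaluate the scattering power law on a wavelength grid (mm^-1)."""
    wl = np.asarray(wavelengths, dtype=float)
    return law.amplitude_a * (wl / law.reference_wavelength) ** (-law.power_b)


def scale_cw_to_absolute(
    calibrated_cw: np.ndarray,
    wavelengths: np.ndarray,
    fd_props: OpticalProperties,
    law: ScatteringPowerLaw,
    lut: LookupTable,
    mode: str = "anchored_smooth",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale a calibrated CW spectrum onto the forward model's absolute units.

    At each FD wavelength the model reflectance implied by the FD-derived
    (mua, musp) anchors the scale. ``anchored_smooth`` interpolates the
    log-gain linearly between anchors (constant beyond the outermost ones),
    absorbing residual spectral instrument response; ``scalar`` applies one
    least-squares gain.

    Returns ``(scaled_spectrum, gain_spectrum, anchor_residual_rms)`` where
    the residual is the log-space anchor mismatch after scaling (zero for
    ``anchored_smooth`` by construction).
    """
    wl = np.asarray(wavelengths, dtype=float)
    cw = np.asarray(calibrated_cw, dtype=float)
    anchors = np.asarray(fd_props.wavelengths, dtype=float)
    if anchors.min() < wl.min() or anchors.max() > wl.max():
        raise ValueError("FD wavelength outside the CW grid")
    model = np.asarray(
        lut.cw_at(fd_props.mua, fd_props.musp), dtype=float
    ).ravel()
    meas = np.interp(anchors, wl, cw)
    if np.any(meas <= 0) or np.any(~np.isfinite(meas)):
        raise ValueError("calibrated CW spectrum non-positive at an FD anchor")
    log_gain_anchor = np.log(model / meas)
    if mode == "anchored_smooth":
        log_gain = np.interp(wl, anchors, log_gain_anchor)
        residual = 0.0
    elif mode == "scalar":
        g = float(np.mean(log_gain_anchor))
        log_gain = np.full(wl.shape, g)
        residual = float(np.sqrt(np.mean((log_gain_anchor - g) ** 2)))
    else:
        raise ValueError("mode must be 'anchored_smooth' or 'scalar'")
    gain = np.exp(log_gain)
    return cw * gain, gain, residual


@dataclass
class BroadbandRecovery:
    """Broadband absolute absorption spectrum with out-of-range bookkeeping."""

    wavelengths: np.ndarray
    mua: np.ndarray  # NaN where masked
    n_masked: int
    valid: bool


def recover_broadband_mua(
    absolute_reflectance: np.ndarray,
    musp_spectrum: np.ndarray,
    lut: LookupTable,
    wavelengths: np.ndarray = STANDARD_GRID,
    max_masked_fraction: float = 0.2,
    n_dense: int = 800,
) -> BroadbandRecovery:
    """Invert the look-up table wavelength-by-wavelength at fixed musp(lambda).

    For each wavelength the CW reflectance is a strictly decreasing function
    of mua at the known musp; a dense sampling of the interpolated table is
    inverted monotonically. Out-of-range wavelengths (reflectance or musp
    outside the table) are masked and counted; a sample with more than
    ``max_masked_fraction`` masked is flagged invalid.
    """
    refl = np.asarray(absolute_reflectance, dtype=float)
    musp = np.asarray(musp_spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if not (refl.shape == musp.shape == wl.shape):
        raise ValueError("inputs must share the wavelength grid")

    mua_dense = np.geomspace(lut.mua_grid[0], lut.mua_grid[-1], n_dense)
    mua_out = np.full(wl.shape, np.nan)
    in_musp = (musp >= lut.musp_grid[0]) & (musp <= lut.musp_grid[-1])
    finite = np.isfinite(refl) & (refl > 0)
    cols = np.nonzero(in_musp & finite)[0]
    if cols.size:
        # one spline evaluation for the full (mua_dense x wavelength) fan
        mm = np.broadcast_to(mua_dense[:, None], (n_dense, cols.size))
        ss = np.broadcast_to(musp[cols][None, :], (n_dense, cols.size))
        curves = lut.cw_at(mm.ravel(), ss.ravel()).reshape(n_dense, cols.size)
        for j, i in enumerate(cols):
            curve = curves[:, j]  # strictly decreasing in mua
            if refl[i] > curve[0] or refl[i] < curve[-1]:
                continue
            mua_out[i] = np.interp(-refl[i], -curve, mua_dense)
    n_masked = int(np.sum(~np.isfinite(mua_out)))
    frac = n_masked / wl.size
    valid = frac <= max_masked_fraction
    if not valid:
        warnings.warn(
            f"{frac:.0%} of wavelengths out of LUT range; sample flagged invalid",
            stacklevel=2,
        )
    return BroadbandRecovery(
        wavelengths=wl, mua=mua_out, n_masked=n_masked, valid=valid
    )
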