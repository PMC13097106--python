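"""Forward models of diffuse light transport and frequency-domain inversion.

Homogeneous semi-infinite tissue probed in reflectance geometry at a fixed
source-detector separation. Two forward engines are provided:

* an extrapolated-boundary diffusion approximation (complex photon-density-wave
  Green's function, isotropic source at one transport mean free path) -- fast,
  closed form, the default look-up-table builder;
* a seeded white Monte Carlo engine (:mod:`hydronirs.montecarlo`) -- slower,
  higher fidelity, used as an independent reference.

Units: mm for length, mm^-1 for optical coefficients, MHz for modulation
frequency, radians for phase. Amplitudes are in model units (reflectance per
mm^2 per injected photon); measured amplitudes are relative and must be
calibrated (:mod:`hydronirs.calibration`) before inversion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import least_squares
from scipy.signal import lfilter

SPEED_OF_LIGHT_MM_PER_NS = 299.792458

__all__ = [
    "MeasurementGeometry",
    "OpticalProperties",
    "FDSample",
    "LookupTable",
    "InversionResult",
    "fd_forward",
    "cw_forward",
    "build_lut",
    "invert_fd",
    "goertzel",
]


@dataclass(frozen=True)
class MeasurementGeometry:
    """Reflectance measurement geometry on a semi-infinite medium."""

    source_detector_separation: float = 20.0  # mm
    refractive_index: float = 1.4
    geometry_tag: str = "semi_infinite"

    def __post_init__(self) -> None:
        if self.source_detector_separation <= 0:
            raise ValueError("source_detector_separation must be > 0")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.geometry_tag != "semi_infinite":
            raise ValueError(f"unsupported geometry_tag {self.geometry_tag!r}")


@dataclass
class OpticalProperties:
    """Absorption and reduced scattering spectra on a wavelength grid (mm^-1)."""

    wavelengths: np.ndarray
    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mua = np.asarray(self.mua, dtype=float)
        self.musp = np.asarray(self.musp, dtype=float)
        if not (self.wavelengths.shape == self.mua.shape == self.musp.shape):
            raise ValueError("wavelengths, mua, musp must share a shape")
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ValueError("optical coefficients must be positive")
        if np.any(self.musp < 10 * self.mua):
            warnings.warn(
                "musp < 10*mua at some wavelengths: diffusion approximation "
                "may be inaccurate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class FDSample:
    """One frequency-domain measurement: amplitude + phase at one wavelength."""

    wavelength: float  # nm
    modulation_frequency: float  # MHz
    amplitude: float  # arbitrary (or model) units, > 0
    phase: float  # radians

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


# ---------------------------------------------------------------------------
# boundary-condition coefficients
# ---------------------------------------------------------------------------


def _fresnel_unpolarized(cos_i: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for internal incidence, n_rel = n_in/n_out."""
    cos_i = np.clip(cos_i, 0.0, 1.0)
    sin_i = np.sqrt(1.0 - cos_i**2)
    sin_t = n_rel * sin_i
    out = np.ones_like(cos_i)
    ok = sin_t < 1.0
    cos_t = np.sqrt(1.0 - np.minimum(sin_t, 1.0) ** 2)
    rs = ((n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)) ** 2
    rp = ((n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)) ** 2
    out = np.where(ok, 0.5 * (rs + rp), 1.0)
    return out


_BOUNDARY_CACHE: dict[float, tuple[float, float, float]] = {}


def _boundary_coefficients(n: float) -> tuple[float, float, float]:
    """(A, C_phi, C_j) for refractive-index-mismatched boundary.

    A enters the extrapolated boundary distance z_b = 2AD.  C_phi and C_j
    weight fluence and flux in the radiance-integral expression for diffuse
    reflectance (Fresnel-moment integrals evaluated numerically).
    """
    key = round(float(n), 6)
    if key in _BOUNDARY_CACHE:
        return _BOUNDARY_CACHE[key]
    r_phi, _ = integrate.quad(
        lambda t: 2.0 * np.sin(t) * np.cos(t) * _fresnel_unpolarized(np.cos(t), n),
        0.0,
        np.pi / 2,
    )
    r_j, _ = integrate.quad(
        lambda t: 3.0 * np.sin(t) * np.cos(t) ** 2 * _fresnel_unpolarized(np.cos(t), n),
        0.0,
        np.pi / 2,
    )
    reff = (r_phi + r_j) / (2.0 - r_phi + r_j)
    a_coef = (1.0 + reff) / (1.0 - reff)
    c_phi = 0.25 * (1.0 - r_phi)
    c_j = 0.5 * (1.0 - r_j)
    _BOUNDARY_CACHE[key] = (a_coef, c_phi, c_j)
    return a_coef, c_phi, c_j


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def _fd_complex(
    mua: np.ndarray,
    musp: np.ndarray,
    geometry: MeasurementGeometry,
    frequency_mhz: float,
) -> np.ndarray:
    """Complex diffuse reflectance of a photon-density wave (dipole model)."""
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    rho = geometry.source_detector_separation
    n = geometry.refractive_index
    a_coef, c_phi, c_j = _boundary_coefficients(n)

    mut = mua + musp
    d = 1.0 / (3.0 * mut)
    z0 = 1.0 / mut
    zb = 2.0 * a_coef * d

    omega = 2.0 * np.pi * frequency_mhz * 1e-3  # rad/ns
    k = np.sqrt((mua + 1j * omega * n / SPEED_OF_LIGHT_MM_PER_NS) / d)
    # principal branch already has Re k > 0 for Re(arg) > 0

    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    e1 = np.exp(-k * r1) / r1
    e2 = np.exp(-k * r2) / r2
    phi = (e1 - e2) / (4.0 * np.pi * d)
    flux = (
        z0 * (k + 1.0 / r1) * e1 / r1 + (z0 + 2.0 * zb) * (k + 1.0 / r2) * e2 / r2
    ) / (4.0 * np.pi)
    return c_phi * phi + c_j * flux


def fd_forward(
    mua: float,
    musp: float,
    geometry: MeasurementGeometry = MeasurementGeometry(),
    frequency_mhz: float = 126.0,
) -> tuple[float, float]:
    """Frequency-domain reflectance amplitude and phase at one wavelength.

    Phase is the (positive) lag of the detected photon-density wave; it is 0
    at zero modulation frequency and grows with frequency.

    Parameters
    ----------
    mua, musp
        Absorption and reduced scattering coefficients, mm^-1 (> 0).
    geometry
        Probe geometry (separation, refractive index).
    frequency_mhz
        Modulation frequency in MHz (>= 0).

    Returns
    -------
    amplitude : float
        Reflectance magnitude in model units (> 0).
    phase : float
        Phase lag in radians, in (-pi, pi].
    """
    if mua <= 0 or musp <= 0:
        raise ValueError("optical properties must be positive")
    if frequency_mhz < 0:
        raise ValueError("modulation frequency must be >= 0")
    r = _fd_complex(np.asarray(mua), np.asarray(musp), geometry, frequency_mhz)
    amplitude = float(np.abs(r))
    phase = float(-np.angle(r))
    return amplitude, phase


def cw_forward(
    mua: float,
    musp: float,
    geometry: MeasurementGeometry = MeasurementGeometry(),
) -> float:
    """Continuous-wave (zero modulation) diffuse reflectance, model units."""
    amplitude, _ = fd_forward(mua, musp, geometry, frequency_mhz=0.0)
    return amplitude


# ---------------------------------------------------------------------------
# Goertzel single-bin spectral estimator
# ---------------------------------------------------------------------------


def goertzel(
    signal: np.ndarray, sample_rate: float, target_frequency: float
) -> tuple[float, float]:
    """Amplitude and phase of one spectral component via the Goertzel recursion.

    Equals the discrete Fourier component at ``target_frequency``; for a pure
    cosine ``A*cos(2*pi*f*t + phi)`` at a bin frequency it returns ``(A, phi)``.

    The second-order recursion ``s[k] = x[k] + 2*cos(w)*s[k-1] - s[k-2]`` is
    evaluated with a direct-form IIR filter.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if target_frequency >= sample_rate / 2:
        raise ValueError("target frequency must be below Nyquist")
    if target_frequency < 0:
        raise ValueError("target frequency must be >= 0")
    n = x.size
    w = 2.0 * np.pi * target_frequency / sample_rate
    s = lfilter([1.0], [1.0, -2.0 * np.cos(w), 1.0], x)
    # DFT value X = (s[N-1] - exp(-iw) s[N-2]) * exp(-iw (N-1))
    dft = (s[-1] - np.exp(-1j * w) * s[-2]) * np.exp(-1j * w * (n - 1))
    if target_frequency == 0.0:
        amplitude = float(np.abs(dft)) / n
    else:
        amplitude = 2.0 * float(np.abs(dft)) / n
    phase = float(np.angle(dft)) if amplitude > 0 else 0.0
    return amplitude, phase


# ---------------------------------------------------------------------------
# look-up table
# ---------------------------------------------------------------------------


@dataclass
class LookupTable:
    """Gridded forward-model reflectance over (mua, musp) at fixed geometry.

    ``cw_reflectance`` has shape (n_mua, n_musp); ``fd_amplitude`` and
    ``fd_phase`` have shape (n_freq, n_mua, n_musp).
    """

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    frequencies_mhz: np.ndarray
    cw_reflectance: np.ndarray
    fd_amplitude: np.ndarray
    fd_phase: np.ndarray
    geometry: MeasurementGeometry
    builder: str = "diffusion"
    _cw_spline: RectBivariateSpline | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for g in (self.mua_grid, self.musp_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly ascending")
        if self.builder not in ("diffusion", "white_mc"):
            raise ValueError("builder must be 'diffusion' or 'white_mc'")

    # -- interpolation -----------------------------------------------------

    def _spline(self) -> RectBivariateSpline:
        if self._cw_spline is None:
            self._cw_spline = RectBivariateSpline(
                np.log(self.mua_grid),
                np.log(self.musp_grid),
                np.log(self.cw_reflectance),
                kx=3,
                ky=3,
            )
        return self._cw_spline

    def cw_at(self, mua, musp):
        """Interpolated CW reflectance (cubic spline in log-log-log space)."""
        val = self._spline().ev(np.log(mua), np.log(musp))
        return np.exp(val)

    def fd_at(self, mua, musp, frequency_mhz: float):
        """Interpolated FD amplitude and phase at one tabulated frequency."""
        idx = int(np.argmin(np.abs(self.frequencies_mhz - frequency_mhz)))
        if abs(self.frequencies_mhz[idx] - frequency_mhz) > 1e-9:
            raise ValueError(f"frequency {frequency_mhz} MHz not tabulated")
        amp_sp = RectBivariateSpline(
            np.log(self.mua_grid),
            np.log(self.musp_grid),
            np.log(self.fd_amplitude[idx]),
            kx=3,
            ky=3,
        )
        ph_sp = RectBivariateSpline(
            np.log(self.mua_grid),
            np.log(self.musp_grid),
            self.fd_phase[idx],
            kx=3,
            ky=3,
        )
        return (
            np.exp(amp_sp.ev(np.log(mua), np.log(musp))),
            ph_sp.ev(np.log(mua), np.log(musp)),
        )

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        """Write a single self-describing JSON file (lossless floats)."""
        payload = {
            "format": "hydronirs-lut",
            "version": 1,
            "builder": self.builder,
            "geometry": {
                "source_detector_separation": self.geometry.source_detector_separation,
                "refractive_index": self.geometry.refractive_index,
                "geometry_tag": self.geometry.geometry_tag,
            },
            "mua_grid": self.mua_grid.tolist(),
            "musp_grid": self.musp_grid.tolist(),
            "frequencies_mhz": self.frequencies_mhz.tolist(),
            "cw_reflectance": self.cw_reflectance.tolist(),
            "fd_amplitude": self.fd_amplitude.tolist(),
            "fd_phase": self.fd_phase.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LookupTable":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "hydronirs-lut":
            raise ValueError("not a hydronirs look-up-table file")
        geom = MeasurementGeometry(**payload["geometry"])
        return cls(
            mua_grid=np.asarray(payload["mua_grid"]),
            musp_grid=np.asarray(payload["musp_grid"]),
            frequencies_mhz=np.asarray(payload["frequencies_mhz"]),
            cw_reflectance=np.asarray(payload["cw_reflectance"]),
            fd_amplitude=np.asarray(payload["fd_amplitude"]),
            fd_phase=np.asarray(payload["fd_phase"]),
            geometry=geom,
            builder=payload["builder"],
        )


DEFAULT_MUA_GRID = np.geomspace(0.001, 0.06, 60)
DEFAULT_MUSP_GRID = np.geomspace(0.3, 2.5, 60)


def build_lut(
    mua_grid: np.ndarray = DEFAULT_MUA_GRID,
    musp_grid: np.ndarray = DEFAULT_MUSP_GRID,
    geometry: MeasurementGeometry = MeasurementGeometry(),
    frequencies_mhz=(120.0, 124.0, 128.0, 132.0),
    builder: str = "diffusion",
    interp_tolerance: float = 0.005,
    check_interpolation: bool = True,
    mc_photons: int = 2_000_000,
    mc_seed: int | None = None,
) -> LookupTable:
    """Tabulate the forward model over an optical-property grid.

    With ``builder='white_mc'`` a seeded white Monte Carlo run (scaled over
    absorption and scattering) fills the table; the default diffusion builder
    evaluates the closed form at every node. A probe at cell midpoints
    measures the interpolation error and warns if it exceeds
    ``interp_tolerance`` (diffusion builder only -- the MC table is noisy at
    that level by construction).
    """
    mua_grid = np.asarray(mua_grid, dtype=float)
    musp_grid = np.asarray(musp_grid, dtype=float)
    freqs = np.asarray(frequencies_mhz, dtype=float)
    mm, ss = np.meshgrid(mua_grid, musp_grid, indexing="ij")

    if builder == "diffusion":
        cw = np.abs(_fd_complex(mm, ss, geometry, 0.0))
        fd_amp = np.empty((freqs.size, *mm.shape))
        fd_phase = np.empty_like(fd_amp)
        for i, f in enumerate(freqs):
            r = _fd_complex(mm, ss, geometry, f)
            fd_amp[i] = np.abs(r)
            fd_phase[i] = -np.angle(r)
    elif builder == "white_mc":
        from .montecarlo import WhiteMonteCarlo

        if mc_seed is None:
            raise ValueError("white_mc builder requires mc_seed")
        engine = WhiteMonteCarlo(n_photons=mc_photons, seed=mc_seed)
        engine.run()
        rho = geometry.source_detector_separation
        cw = np.abs(engine.reflectance(mm, ss, rho, 0.0))
        fd_amp = np.empty((freqs.size, *mm.shape))
        fd_phase = np.empty_like(fd_amp)
        for i, f in enumerate(freqs):
            r = engine.reflectance(mm, ss, rho, f)
            fd_amp[i] = np.abs(r)
            fd_phase[i] = -np.angle(r)
    else:
        raise ValueError("builder must be 'diffusion' or 'white_mc'")

    lut = LookupTable(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        frequencies_mhz=freqs,
        cw_reflectance=cw,
        fd_amplitude=fd_amp,
        fd_phase=fd_phase,
        geometry=geometry,
        builder=builder,
    )

    if check_interpolation and builder == "diffusion":
        mid_mua = np.sqrt(mua_grid[:-1] * mua_grid[1:])[::7]
        mid_musp = np.sqrt(musp_grid[:-1] * musp_grid[1:])[::7]
        pm, ps = np.meshgrid(mid_mua, mid_musp, indexing="ij")
        direct = np.abs(_fd_complex(pm, ps, geometry, 0.0))
        interp = lut.cw_at(pm, ps)
        err = float(np.max(np.abs(interp - direct) / direct))
        if err > interp_tolerance:
            warnings.warn(
                f"LUT grid too coarse: max CW interpolation error {err:.2e} "
                f"exceeds {interp_tolerance:.2e}",
                stacklevel=2,
            )
    return lut


# ---------------------------------------------------------------------------
# FD inversion
# ---------------------------------------------------------------------------


@dataclass
class InversionResult:
    """Recovered optical properties at a single wavelength."""

    mua: float
    musp: float
    residual: float
    out_of_range: bool
    n_samples: int


_LOG_BOUNDS = (np.log([5e-4, 0.1]), np.log([0.15, 4.0]))


def invert_fd(
    samples,
    geometry: MeasurementGeometry = MeasurementGeometry(),
    sigma_log_amplitude: float = 0.01,
    sigma_phase: float = 0.005,
    x0: tuple[float, float] | None = None,
) -> InversionResult:
    """Recover (mua, musp) from calibrated FD amplitude+phase samples.

    Bounded least squares on (log mua, log musp), jointly over log-amplitude
    and phase residuals weighted by 1/sigma per channel. Without a warm
    start, four seeds from a coarse objective scan are tried (best kept).
    An optimum pinned at the parameter bounds is flagged ``out_of_range``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("at least one FD sample required")
    freqs = np.array([s.modulation_frequency for s in samples])
    log_amp = np.log([s.amplitude for s in samples])
    phases = np.array([s.phase for s in samples])

    def residuals(p):
        mua, musp = np.exp(p)
        out = np.empty(2 * freqs.size)
        for i, f in enumerate(freqs):
            r = _fd_complex(np.asarray(mua), np.asarray(musp), geometry, f)
            out[i] = (np.log(np.abs(r)) - log_amp[i]) / sigma_log_amplitude
            out[freqs.size + i] = (-np.angle(r) - phases[i]) / sigma_phase
        return out

    lo, hi = _LOG_BOUNDS
    if x0 is not None:
        seeds = [np.log(np.asarray(x0, dtype=float))]
    else:
        gm = np.geomspace(1.5e-3, 0.1, 10)
        gs = np.geomspace(0.15, 3.5, 10)
        obj = np.empty((gm.size, gs.size))
        for i, m in enumerate(gm):
            for j, s in enumerate(gs):
                obj[i, j] = np.sum(residuals(np.log([m, s])) ** 2)
        order = np.argsort(obj, axis=None)[:4]
        seeds = [
            np.log([gm[k // gs.size], gs[k % gs.size]]) for k in order
        ]

    best = None
    for seed in seeds:
        sol = least_squares(
            residuals,
            np.clip(seed, lo, hi),
            bounds=(lo, hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-10:
            break

    mua, musp = np.exp(best.x)
    at_bound = bool(
        np.any(np.isclose(best.x, lo, atol=1e-6))
        or np.any(np.isclose(best.x, hi, atol=1e-6))
    )
    return InversionResult(
        mua=float(mua),
        musp=float(musp),
        residual=float(np.sqrt(2.0 * best.cost / (2 * freqs.size))),
        out_of_range=at_bound,
        n_samples=len(samples),
    )
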