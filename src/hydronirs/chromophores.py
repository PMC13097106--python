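"""Beer's-law spectral unmixing of broadband absorption spectra.

The tissue absorption spectrum over 700-1000 nm is modelled as a
nonnegative combination of oxy-/deoxyhemoglobin (muM), water and lipid
(volume fractions of the pure-component absorption), a melanin shape
(fraction), plus a spectrally constant background term that absorbs tissue
heterogeneity and missing chromophores (allowed slightly negative).

Melanin is estimated once from the pre-dialysis baseline window and held
fixed for the rest of the session, mirroring the assumption that epidermal
melanin does not change over hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import nnls

__all__ = [
    "ChromophoreBasis",
    "ChromophoreState",
    "load_basis",
    "fit_chromophores",
    "estimate_baseline_melanin",
    "derived_metrics",
]

BACKGROUND_FLOOR = -0.005  # mm^-1, lower bound of the constant term


@dataclass
class ChromophoreBasis:
    """Extinction/absorption basis spectra on a common wavelength grid."""

    wavelengths: np.ndarray  # nm
    eps_hbo2: np.ndarray  # mm^-1 per uM
    eps_hb: np.ndarray  # mm^-1 per uM
    mua_water: np.ndarray  # mm^-1 at fraction 1
    mua_lipid: np.ndarray  # mm^-1 at fraction 1
    mua_melanin: np.ndarray  # mm^-1 at fraction 1
    provenance: str = ""

    def __post_init__(self) -> None:
        spectra = (
            self.eps_hbo2,
            self.eps_hb,
            self.mua_water,
            self.mua_lipid,
            self.mua_melanin,
        )
        if any(s.shape != self.wavelengths.shape for s in spectra):
            raise ValueError("basis spectra must share the wavelength grid")
        if any(np.any(s < 0) for s in spectra):
            raise ValueError("basis spectra must be nonnegative")

    def compose(
        self,
        hbo2: float,
        hb: float,
        water: float,
        lipid: float,
        melanin: float = 0.0,
        background: float = 0.0,
    ) -> np.ndarray:
        """Absorption spectrum of a chromophore mixture (Beer's law), mm^-1."""
        return (
            self.eps_hbo2 * hbo2
            + self.eps_hb * hb
            + self.mua_water * water
            + self.mua_lipid * lipid
            + self.mua_melanin * melanin
            + background
        )

    def resample(self, wavelengths) -> "ChromophoreBasis":
        wl = np.asarray(wavelengths, dtype=float)
        return ChromophoreBasis(
            wavelengths=wl,
            eps_hbo2=np.interp(wl, self.wavelengths, self.eps_hbo2),
            eps_hb=np.interp(wl, self.wavelengths, self.eps_hb),
            mua_water=np.interp(wl, self.wavelengths, self.mua_water),
            mua_lipid=np.interp(wl, self.wavelengths, self.mua_lipid),
            mua_melanin=np.interp(wl, self.wavelengths, self.mua_melanin),
            provenance=self.provenance,
        )

    def smoothed(self, fwhm_nm: float) -> "ChromophoreBasis":
        """Basis convolved to an instrument spectral resolution (Gaussian)."""
        step = float(np.median(np.diff(self.wavelengths)))
        sigma = fwhm_nm / 2.3548 / step
        return ChromophoreBasis(
            wavelengths=self.wavelengths,
            eps_hbo2=gaussian_filter1d(self.eps_hbo2, sigma, mode="nearest"),
            eps_hb=gaussian_filter1d(self.eps_hb, sigma, mode="nearest"),
            mua_water=gaussian_filter1d(self.mua_water, sigma, mode="nearest"),
            mua_lipid=gaussian_filter1d(self.mua_lipid, sigma, mode="nearest"),
            mua_melanin=gaussian_filter1d(self.mua_melanin, sigma, mode="nearest"),
            provenance=self.provenance + f" [smoothed to {fwhm_nm} nm FWHM]",
        )


@dataclass
class ChromophoreState:
    """Chromophore concentrations from one spectrum fit, plus derived metrics."""

    hbo2: float  # uM
    hb: float  # uM
    water_fraction: float
    lipid_fraction: float
    melanin_fraction: float
    background_mua: float  # mm^-1
    fit_residual: float  # mm^-1 RMS

    @property
    def hbt(self) -> float:
        return self.hbo2 + self.hb

    @property
    def sto2(self) -> float:
        """Tissue oxygen saturation, percent; NaN when HbT is zero."""
        if self.hbt <= 0:
            return float("nan")
        return 100.0 * self.hbo2 / self.hbt

    @property
    def water_ratio(self) -> float:
        """water / (water + lipid); NaN when the denominator is zero."""
        denom = self.water_fraction + self.lipid_fraction
        if denom <= 0:
            return float("nan")
        return self.water_fraction / denom


def load_basis(
    source_tag: str = "synthetic",
    wavelengths=None,
    resolution_fwhm_nm: float | None = None,
) -> ChromophoreBasis:
    """Load a packaged chromophore basis, optionally resampled/smoothed.

    ``resolution_fwhm_nm`` convolves the basis to the instrument's spectral
    resolution so that fits to resolution-limited spectra are unbiased.
    """
    name = f"chromophore_basis_{source_tag}.csv"
    pkg = resources.files("hydronirs") / "data" / name
    if not pkg.is_file():
        raise FileNotFoundError(f"packaged basis fixture missing: {name}")
    with resources.as_file(pkg) as path:
        data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar = resources.files("hydronirs") / "data" / f"chromophore_basis_{source_tag}.json"
    provenance = ""
    if sidecar.is_file():
        import json

        provenance = json.loads(sidecar.read_text()).get("provenance", "")
    basis = ChromophoreBasis(
        wavelengths=data[:, 0],
        eps_hbo2=data[:, 1],
        eps_hb=data[:, 2],
        mua_water=data[:, 3],
        mua_lipid=data[:, 4],
        mua_melanin=data[:, 5],
        provenance=provenance,
    )
    if resolution_fwhm_nm is not None:
        basis = basis.smoothed(resolution_fwhm_nm)
    if wavelengths is not None:
        basis = basis.resample(wavelengths)
    return basis


def _design_matrix(basis: ChromophoreBasis, include_melanin: bool) -> np.ndarray:
    cols = [basis.eps_hbo2, basis.eps_hb, basis.mua_water, basis.mua_lipid]
    if include_melanin:
        cols.append(basis.mua_melanin)
    cols.append(np.ones_like(basis.wavelengths))
    return np.column_stack(cols)


def fit_chromophores(
    mua_spectrum: np.ndarray,
    basis: ChromophoreBasis,
    melanin_mode="free",
) -> ChromophoreState:
    """Nonnegative least-squares Beer's-law fit of one absorption spectrum.

    ``melanin_mode`` is ``"free"`` (melanin fitted, nonnegative) or
    ``("fixed", value)`` (its contribution subtracted before fitting).
    Concentrations are constrained nonnegative; the constant background may
    go slightly negative (floor -0.005 mm^-1). NaN wavelengths are ignored.
    """
    y = np.asarray(mua_spectrum, dtype=float)
    if y.shape != basis.wavelengths.shape:
        raise ValueError("spectrum and basis must share the wavelength grid")
    ok = np.isfinite(y)
    if melanin_mode == "free":
        include_mel = True
        mel_fixed = 0.0
    else:
        mode, mel_fixed = melanin_mode
        if mode != "fixed":
            raise ValueError("melanin_mode must be 'free' or ('fixed', value)")
        include_mel = False
        y = y - basis.mua_melanin * mel_fixed
    a_full = _design_matrix(basis, include_mel)
    a = a_full[ok]
    n_free = a.shape[1]
    if ok.sum() < n_free + 6:
        raise ValueError("need at least 6 more valid wavelengths than components")
    cond = np.linalg.cond(a / np.linalg.norm(a, axis=0))
    if cond > 1e8:
        raise ValueError(f"ill-conditioned basis (condition number {cond:.2e})")
    # Shift the background floor so the problem becomes pure NNLS, solved
    # exactly by the Lawson-Hanson active-set algorithm: with
    # b' = background - floor >= 0 the model is y - floor = A_conc@c + b'.
    col_scale = np.linalg.norm(a, axis=0)
    y_shift = y[ok] - BACKGROUND_FLOOR
    xs, _ = nnls(a / col_scale, y_shift)
    x = xs / col_scale
    x[-1] += BACKGROUND_FLOOR
    resid = float(np.sqrt(np.mean((a @ x - y[ok]) ** 2)))
    mel = float(x[4]) if include_mel else float(mel_fixed)
    return ChromophoreState(
        hbo2=float(x[0]),
        hb=float(x[1]),
        water_fraction=float(x[2]),
        lipid_fraction=float(x[3]),
        melanin_fraction=mel,
        background_mua=float(x[-1]),
        fit_residual=resid,
    )


def estimate_baseline_melanin(
    baseline_mua_spectra, basis: ChromophoreBasis
) -> float:
    """Median of free-melanin fits over the pre-dialysis baseline window.

    Robust to a corrupted spectrum within the window; the returned value is
    intended to be passed to subsequent fits as ``("fixed", value)``.
    """
    values = []
    for spec in baseline_mua_spectra:
        try:
            state = fit_chromophores(spec, basis, melanin_mode="free")
        except ValueError:
            continue
        values.append(state.melanin_fraction)
    if not values:
        raise ValueError("no valid baseline spectra for melanin estimation")
    return float(np.median(values))


def derived_metrics(state: ChromophoreState) -> tuple[float, float, float]:
    """(HbT, StO2, water ratio); undefined ratios are NaN, never 0."""
    return state.hbt, state.sto2, state.water_ratio
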