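"""Synthetic dialysis-cohort generator and raw-measurement renderer.

Generates a virtual cohort with the statistical structure the analysis
assumes -- group-specific chromophore and scattering trajectories, adverse
events, blood-pressure records with hypotension episodes, ultrafiltration
volumes -- and renders each session into raw FD/CW measurement bundles
(instrument response, noise, motion artifacts, matching calibration scans)
so the entire pipeline runs end to end with no external data.

Study conditions baked into the defaults: 18 adverse / 9 nonadverse
subjects; session durations 1-4 h (median ~3 h); start-to-end water-ratio
changes of +0.012 +/- 0.035 (adverse) vs -0.037 +/- 0.085 (nonadverse);
oxyhemoglobin rising ~15 uM in both groups; higher end-of-session
scattering amplitude in nonadverse subjects; hypotension episodes centred
near mid-session in the adverse group; 1% multiplicative measurement noise
and occasional motion transients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import STANDARD_GRID
from .chromophores import ChromophoreBasis, load_basis
from .optics import FDSample, MeasurementGeometry, _fd_complex

__all__ = [
    "CohortConfig",
    "GroundTruthSession",
    "InstrumentModel",
    "RawSessionBundle",
    "simulate_trajectories",
    "make_instrument",
    "render_measurements",
    "simulate_cohort",
    "write_session_bundle",
    "read_session_bundle",
]

BUNDLE_FORMAT_VERSION = 1

SUBJECTIVE_EVENT_TYPES = (
    "vomiting",
    "cramping",
    "dizziness",
    "headache",
    "shortness_of_breath",
    "sweating",
)


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Group-keyed entries are ``(mean, sd)`` pairs for per-subject draws.
    All defaults reproduce the cohort structure the analysis targets.
    """

    seed: int = 0
    n_adverse: int = 18
    n_nonadverse: int = 9

    # session durations, hours (triangular: min, mode, max)
    duration_hours: tuple = (1.0, 3.0, 4.0)

    # start-to-end effects per group
    delta_water_ratio: dict = field(default_factory=lambda: {
        "adverse": (0.012, 0.035), "nonadverse": (-0.037, 0.085)})
    delta_hbo2_uM: dict = field(default_factory=lambda: {
        "adverse": (14.52, 15.82), "nonadverse": (15.96, 12.21)})
    delta_hb_uM: dict = field(default_factory=lambda: {
        "adverse": (2.25, 6.49), "nonadverse": (1.57, 3.88)})

    # absolute scattering power-law parameters at end of dialysis
    scattering_a_end: dict = field(default_factory=lambda: {
        "adverse": (0.95, 0.15), "nonadverse": (1.09, 0.15)})
    scattering_b_end: dict = field(default_factory=lambda: {
        "adverse": (0.90, 0.20), "nonadverse": (1.05, 0.20)})
    scattering_a_change: tuple = (-0.05, 0.03)
    scattering_b_change: dict = field(default_factory=lambda: {
        "adverse": (0.0, 0.04), "nonadverse": (0.08, 0.04)})

    # baseline tissue composition
    hbo2_baseline_uM: tuple = (25.0, 5.0)
    hb_baseline_uM: tuple = (15.0, 3.0)
    water_baseline: tuple = (0.60, 0.04)
    lipid_baseline: tuple = (0.22, 0.03)
    melanin_fraction: tuple = (0.015, 0.005)
    background_mua: tuple = (0.001, 0.0005)

    # clinical covariates
    ultrafiltration_l: tuple = (1.6, 0.8)
    delta_bv_percent: dict = field(default_factory=lambda: {
        "adverse": (-6.5, 5.5), "nonadverse": (-7.0, 3.0)})
    critline_fraction: float = 19.0 / 27.0
    sbp_baseline: tuple = (140.0, 15.0)
    dbp_baseline: tuple = (80.0, 8.0)
    sbp_end_change: dict = field(default_factory=lambda: {
        "adverse": (-25.0, 15.0), "nonadverse": (-5.0, 8.0)})
    bp_interval_min: float = 15.0
    idh_probability_adverse: float = 16.0 / 18.0
    event_time_percent: tuple = (51.7, 24.8)

    # instrument
    fd_wavelengths: tuple = (730.0, 785.0, 830.0, 940.0)
    fd_frequencies_mhz: tuple = (120.0, 124.0, 128.0, 132.0)
    cw_resolution_fwhm_nm: float = 7.5
    cw_noise: float = 0.01
    fd_amplitude_noise: float = 0.01
    fd_phase_noise: float = 0.005
    calibration_noise: float = 0.0
    probe_coupling_scale: float = 0.01
    motion_rate_per_hour: float = 1.0

    def __post_init__(self) -> None:
        if self.n_adverse < 2 or self.n_nonadverse < 2:
            raise ValueError("group sizes must be at least 2")
        for d in (self.delta_water_ratio, self.delta_hbo2_uM, self.delta_hb_uM):
            for mean, sd in d.values():
                if sd < 0:
                    raise ValueError("standard deviations must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        kwargs = dict(data)
        for key in ("duration_hours", "scattering_a_change", "hbo2_baseline_uM",
                    "hb_baseline_uM", "water_baseline", "lipid_baseline",
                    "melanin_fraction", "background_mua", "ultrafiltration_l",
                    "sbp_baseline", "dbp_baseline", "event_time_percent",
                    "fd_wavelengths", "fd_frequencies_mhz"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        for key in ("delta_water_ratio", "delta_hbo2_uM", "delta_hb_uM",
                    "scattering_a_end", "scattering_b_end",
                    "scattering_b_change", "delta_bv_percent", "sbp_end_change"):
            if key in kwargs:
                kwargs[key] = {g: tuple(v) for g, v in kwargs[key].items()}
        return cls(**kwargs)


@dataclass
class GroundTruthSession:
    """Per-minute ground truth for one simulated session."""

    subject_id: str
    group: str  # 'adverse' | 'nonadverse'
    duration_minutes: int
    times: np.ndarray  # minutes, 0..duration
    hbo2: np.ndarray
    hb: np.ndarray
    water: np.ndarray
    lipid: np.ndarray
    melanin: float
    background: float
    scattering_a: np.ndarray
    scattering_b: np.ndarray
    events: list  # (time_min, type)
    bp_records: list  # (time_min, sbp, dbp, map)
    motion_times: list
    ultrafiltration_l: float
    delta_bv_percent: float | None
    true_deltas: dict = field(default_factory=dict)

    @property
    def water_ratio(self) -> np.ndarray:
        return self.water / (self.water + self.lipid)

    @property
    def adverse(self) -> bool:
        return self.group == "adverse"


def _logistic_ramp(times: np.ndarray, duration: float, steepness: float = 8.0):
    s = 1.0 / (1.0 + np.exp(-steepness * (times / duration - 0.5)))
    return (s - s[0]) / (s[-1] - s[0])


def _smooth_drift(rng, times, duration, scale):
    """Low-amplitude slow drift vanishing at both session endpoints."""
    a1, a2 = rng.normal(0.0, scale, size=2)
    x = times / duration
    return a1 * np.sin(np.pi * x) + a2 * np.sin(2.0 * np.pi * x)


def simulate_trajectories(config: CohortConfig) -> list[GroundTruthSession]:
    """Draw the ground-truth cohort (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    sessions = []
    groups = ["adverse"] * config.n_adverse + ["nonadverse"] * config.n_nonadverse
    for i, group in enumerate(groups):
        sessions.append(_simulate_subject(f"S{i:03d}", group, config, rng))
    return sessions


def _draw(rng, pair):
    return rng.normal(pair[0], pair[1])


def _simulate_subject(subject_id, group, config, rng) -> GroundTruthSession:
    lo, mode, hi = config.duration_hours
    duration = int(np.floor(rng.triangular(lo, mode, hi) * 60.0))
    times = np.arange(duration + 1, dtype=float)
    ramp = _logistic_ramp(times, duration)

    hbo2_0 = max(_draw(rng, config.hbo2_baseline_uM), 5.0)
    hb_0 = max(_draw(rng, config.hb_baseline_uM), 3.0)
    d_hbo2 = _draw(rng, config.delta_hbo2_uM[group])
    d_hb = _draw(rng, config.delta_hb_uM[group])
    hbo2 = hbo2_0 + d_hbo2 * ramp + _smooth_drift(rng, times, duration, 1.0)
    hb = hb_0 + d_hb * ramp + _smooth_drift(rng, times, duration, 0.5)
    hbo2 = np.maximum(hbo2, 1.0)
    hb = np.maximum(hb, 1.0)

    water_0 = np.clip(_draw(rng, config.water_baseline), 0.35, 0.8)
    lipid_0 = np.clip(_draw(rng, config.lipid_baseline), 0.08, 0.4)
    r0 = water_0 / (water_0 + lipid_0)
    d_ratio = _draw(rng, config.delta_water_ratio[group])
    # keep the final water fraction physical (<= 0.95 of tissue volume)
    r1_max = 0.95 / (0.95 + lipid_0)
    r1 = float(np.clip(r0 + d_ratio, 0.3, r1_max))
    d_ratio_eff = r1 - r0
    water_1 = lipid_0 * r1 / (1.0 - r1)
    water = water_0 + (water_1 - water_0) * ramp + _smooth_drift(
        rng, times, duration, 0.004
    )
    water = np.clip(water, 0.05, 0.95)
    lipid = np.full_like(times, lipid_0)

    melanin = max(_draw(rng, config.melanin_fraction), 0.0)
    background = max(_draw(rng, config.background_mua), 0.0)

    a_end = max(_draw(rng, config.scattering_a_end[group]), 0.4)
    b_end = max(_draw(rng, config.scattering_b_end[group]), 0.2)
    d_a = _draw(rng, config.scattering_a_change)
    d_b = _draw(rng, config.scattering_b_change[group])
    scat_a = (a_end - d_a) + d_a * ramp + _smooth_drift(rng, times, duration, 0.01)
    scat_b = (b_end - d_b) + d_b * ramp + _smooth_drift(rng, times, duration, 0.01)
    scat_a = np.maximum(scat_a, 0.35)
    scat_b = np.maximum(scat_b, 0.1)

    # adverse events
    events = []
    has_idh = False
    if group == "adverse":
        has_idh = rng.random() < config.idh_probability_adverse
        n_extra = rng.poisson(0.7)
        n_events = max(1, (1 if has_idh else 0) + n_extra)
        for k in range(n_events):
            frac = np.clip(
                rng.normal(*config.event_time_percent) / 100.0, 0.05, 0.95
            )
            t_ev = float(np.round(frac * duration))
            if k == 0 and has_idh:
                events.append((t_ev, "IDH"))
            else:
                events.append(
                    (t_ev, SUBJECTIVE_EVENT_TYPES[
                        rng.integers(len(SUBJECTIVE_EVENT_TYPES))])
                )
        events.sort()

    # blood pressure every 15 min
    sbp0 = _draw(rng, config.sbp_baseline)
    dbp0 = _draw(rng, config.dbp_baseline)
    d_sbp = _draw(rng, config.sbp_end_change[group])
    bp_times = np.arange(0.0, duration + 1e-9, config.bp_interval_min)
    bp_records = []
    idh_times = [t for t, e in events if e == "IDH"]
    for t in bp_times:
        sbp = sbp0 + d_sbp * (t / duration) + rng.normal(0.0, 3.0)
        dbp = dbp0 + 0.3 * d_sbp * (t / duration) + rng.normal(0.0, 2.0)
        if group == "nonadverse" and t > 0:
            # nonadverse subjects stay clear of the hypotension criteria
            sbp = max(sbp, sbp0 - 14.0)
            dbp = max(dbp, dbp0 - 6.0)
        bp_records.append([float(t), float(sbp), float(dbp)])
    if idh_times:
        for t_ev in idh_times:
            idx = int(np.argmin(np.abs(bp_times - t_ev)))
            if idx == 0:
                idx = 1
            drop = 22.0 + rng.exponential(8.0)
            bp_records[idx][1] = sbp0 - drop
            bp_records[idx][2] = dbp0 - 0.5 * drop
    bp_full = [
        (t, sbp, dbp, dbp + (sbp - dbp) / 3.0) for t, sbp, dbp in bp_records
    ]

    n_motion = rng.poisson(config.motion_rate_per_hour * duration / 60.0)
    motion_times = sorted(
        float(np.round(t)) for t in rng.uniform(2, max(duration - 2, 3), n_motion)
    )

    has_critline = rng.random() < config.critline_fraction
    delta_bv = float(_draw(rng, config.delta_bv_percent[group])) if has_critline else None

    return GroundTruthSession(
        subject_id=subject_id,
        group=group,
        duration_minutes=duration,
        times=times,
        hbo2=hbo2,
        hb=hb,
        water=water,
        lipid=lipid,
        melanin=melanin,
        background=background,
        scattering_a=scat_a,
        scattering_b=scat_b,
        events=events,
        bp_records=bp_full,
        motion_times=motion_times,
        ultrafiltration_l=float(max(_draw(rng, config.ultrafiltration_l), 0.2)),
        delta_bv_percent=delta_bv,
        true_deltas={
            "water_ratio": float(d_ratio_eff),
            "hbo2": float(hbo2[-1] - hbo2[0]),
            "hb": float(hb[-1] - hb[0]),
            "scattering_a": float(d_a),
            "scattering_b": float(d_b),
        },
    )


# ---------------------------------------------------------------------------
# instrument model and rendering
# ---------------------------------------------------------------------------


@dataclass
class InstrumentModel:
    """Spectral response of the simulated clinical system."""

    cw_gain: np.ndarray  # over STANDARD_GRID
    fd_gains: dict  # wavelength -> amplitude gain
    fd_phase_offsets: dict  # wavelength -> radians
    phantom_wavelengths: np.ndarray
    phantom_mua: np.ndarray
    phantom_musp: np.ndarray
    standard_reflectivity: np.ndarray  # over STANDARD_GRID


def make_instrument(
    config: CohortConfig,
    rng: np.random.Generator,
    identity: bool = False,
) -> InstrumentModel:
    """Draw a smooth random instrument response (or the identity response)."""
    wl = STANDARD_GRID
    x = (wl - wl.mean()) / (np.ptp(wl) / 2.0)
    if identity:
        cw_gain = np.ones_like(wl)
        fd_gains = {w: 1.0 for w in config.fd_wavelengths}
        fd_offsets = {w: 0.0 for w in config.fd_wavelengths}
    else:
        coeffs = rng.normal(0.0, 1.0, size=4) * np.array([0.5, 0.3, 0.2, 0.1])
        log_gain = np.polynomial.chebyshev.chebval(x, coeffs)
        cw_gain = 1.0e4 * np.exp(log_gain)
        fd_gains = {
            w: float(np.exp(rng.normal(np.log(1e3), 0.3)))
            for w in config.fd_wavelengths
        }
        fd_offsets = {
            w: float(rng.uniform(-0.5, 0.5)) for w in config.fd_wavelengths
        }
    phantom_wl = np.asarray(config.fd_wavelengths, dtype=float)
    phantom_mua = np.full(phantom_wl.shape, 0.0075)
    phantom_musp = 1.2 * (phantom_wl / 800.0) ** (-0.6)
    return InstrumentModel(
        cw_gain=cw_gain,
        fd_gains=fd_gains,
        fd_phase_offsets=fd_offsets,
        phantom_wavelengths=phantom_wl,
        phantom_mua=phantom_mua,
        phantom_musp=phantom_musp,
        standard_reflectivity=np.full(wl.shape, 0.99),
    )


@dataclass
class RawSessionBundle:
    """Raw rendered measurements for one session, plus calibration scans."""

    subject_id: str
    metadata: dict
    fd: pd.DataFrame  # time_min, wavelength_nm, freq_MHz, amplitude, phase
    cw: pd.DataFrame  # index time_min, columns wavelengths (nm)
    phantom_fd: pd.DataFrame  # wavelength_nm, freq_MHz, amplitude, phase
    phantom_props: dict  # wavelengths, mua, musp
    standard_cw: pd.DataFrame  # wavelength_nm, counts, reflectivity
    truth: GroundTruthSession | None = None

    def fd_samples(self, time_min: float) -> list[FDSample]:
        rows = self.fd[self.fd["time_min"] == time_min]
        return [
            FDSample(r.wavelength_nm, r.freq_MHz, r.amplitude, r.phase)
            for r in rows.itertuples()
        ]


def _gaussian_smooth_spectrum(values: np.ndarray, fwhm_nm: float,
                              step_nm: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    if fwhm_nm <= 0:
        return values
    return gaussian_filter1d(values, fwhm_nm / 2.3548 / step_nm, mode="nearest")


def render_measurements(
    truth: GroundTruthSession,
    instrument: InstrumentModel,
    config: CohortConfig,
    rng: np.random.Generator,
    geometry: MeasurementGeometry = MeasurementGeometry(),
    basis: ChromophoreBasis | None = None,
) -> RawSessionBundle:
    """Render one ground-truth session into raw FD/CW measurements.

    Per minute, the absorption spectrum is composed from the true
    chromophores by Beer's law and reduced scattering from the power law;
    both are pushed through the diffusion forward model, multiplied by the
    instrument response, degraded to the spectrometer's resolution and
    noise, and motion transients are injected on the raw channels.
    """
    basis = basis or load_basis(wavelengths=STANDARD_GRID)
    wl = STANDARD_GRID
    step = float(wl[1] - wl[0])
    freqs = list(config.fd_frequencies_mhz)
    fd_wl = list(config.fd_wavelengths)
    freq_of = {w: freqs[i % len(freqs)] for i, w in enumerate(fd_wl)}

    # session-specific smooth probe-coupling spectrum (not seen by the
    # reflectance standard; absorbed downstream by anchored scaling)
    x = (wl - wl.mean()) / (np.ptp(wl) / 2.0)
    s = config.probe_coupling_scale
    coupling = np.exp(
        np.polynomial.chebyshev.chebval(
            x, rng.normal(0.0, 1.0, size=3) * np.array([s, 0.6 * s, 0.4 * s])
        )
    )

    # motion windows: minute -> (fd factor, cw factor, phase kick)
    motion_effect = {}
    step_gain = 1.0
    step_changes = {}
    for tm in truth.motion_times:
        dur = int(rng.integers(1, 4))
        for dt in range(dur):
            motion_effect[tm + dt] = (
                float(np.exp(rng.normal(0.0, 0.15))),
                float(np.exp(rng.normal(0.0, 0.15))),
                float(rng.normal(0.0, 0.08)),
            )
        if rng.random() < 0.3:  # probe shift leaves a persistent small step
            step_changes[tm + dur] = float(np.exp(rng.normal(0.0, 0.02)))

    fd_rows = []
    cw_rows = np.empty((truth.times.size, wl.size))
    mua_all = (
        basis.eps_hbo2[None, :] * truth.hbo2[:, None]
        + basis.eps_hb[None, :] * truth.hb[:, None]
        + basis.mua_water[None, :] * truth.water[:, None]
        + basis.mua_lipid[None, :] * truth.lipid[:, None]
        + basis.mua_melanin[None, :] * truth.melanin
        + truth.background
    )
    if np.any(mua_all <= 0):
        bad = int(np.argwhere(mua_all <= 0)[0][0])
        raise ValueError(f"non-positive absorption at time sample {bad}")

    for it, t in enumerate(truth.times):
        if t in step_changes:
            step_gain *= step_changes[t]
        musp_spec = truth.scattering_a[it] * (wl / 800.0) ** (-truth.scattering_b[it])
        mua_spec = mua_all[it]
        fd_mot, cw_mot, ph_mot = motion_effect.get(t, (1.0, 1.0, 0.0))

        for w in fd_wl:
            mua_w = float(np.interp(w, wl, mua_spec))
            musp_w = float(np.interp(w, wl, musp_spec))
            r = _fd_complex(np.asarray(mua_w), np.asarray(musp_w), geometry,
                            freq_of[w])
            amp = float(np.abs(r)) * instrument.fd_gains[w] * fd_mot * step_gain
            ph = float(-np.angle(r)) + instrument.fd_phase_offsets[w] + ph_mot
            amp *= float(np.exp(rng.normal(0.0, config.fd_amplitude_noise)))
            ph += float(rng.normal(0.0, config.fd_phase_noise))
            fd_rows.append((float(t), w, freq_of[w], amp, ph))

        r_cw = np.abs(_fd_complex(mua_spec, musp_spec, geometry, 0.0))
        r_inst = _gaussian_smooth_spectrum(r_cw, config.cw_resolution_fwhm_nm, step)
        spec = (
            r_inst * instrument.cw_gain * coupling * cw_mot * step_gain
            * np.exp(rng.normal(0.0, config.cw_noise, size=wl.size))
        )
        cw_rows[it] = spec

    fd = pd.DataFrame(
        fd_rows, columns=["time_min", "wavelength_nm", "freq_MHz", "amplitude", "phase"]
    )
    cw = pd.DataFrame(cw_rows, index=truth.times, columns=wl)
    cw.index.name = "time_min"

    # calibration scans share the instrument response
    ph_rows = []
    for w in fd_wl:
        idx = int(np.argmin(np.abs(instrument.phantom_wavelengths - w)))
        r = _fd_complex(
            np.asarray(instrument.phantom_mua[idx]),
            np.asarray(instrument.phantom_musp[idx]),
            geometry,
            freq_of[w],
        )
        amp = float(np.abs(r)) * instrument.fd_gains[w]
        ph = float(-np.angle(r)) + instrument.fd_phase_offsets[w]
        if config.calibration_noise > 0:
            amp *= float(np.exp(rng.normal(0.0, config.calibration_noise)))
            ph += float(rng.normal(0.0, config.calibration_noise))
        ph_rows.append((w, freq_of[w], amp, ph))
    phantom_fd = pd.DataFrame(
        ph_rows, columns=["wavelength_nm", "freq_MHz", "amplitude", "phase"]
    )
    std_counts = instrument.standard_reflectivity * instrument.cw_gain
    if config.calibration_noise > 0:
        std_counts = std_counts * np.exp(
            rng.normal(0.0, config.calibration_noise, size=wl.size)
        )
    standard_cw = pd.DataFrame(
        {
            "wavelength_nm": wl,
            "counts": std_counts,
            "reflectivity": instrument.standard_reflectivity,
        }
    )

    metadata = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "subject_id": truth.subject_id,
        "group": truth.group,
        "duration_minutes": truth.duration_minutes,
        "ultrafiltration_l": truth.ultrafiltration_l,
        "delta_bv_percent": truth.delta_bv_percent,
        "events": [[t, e] for t, e in truth.events],
        "bp_records": [list(r) for r in truth.bp_records],
        "motion_times": list(truth.motion_times),
        "fd_wavelengths": fd_wl,
        "fd_frequencies_mhz": [freq_of[w] for w in fd_wl],
        "geometry": {
            "source_detector_separation": geometry.source_detector_separation,
            "refractive_index": geometry.refractive_index,
        },
    }
    return RawSessionBundle(
        subject_id=truth.subject_id,
        metadata=metadata,
        fd=fd,
        cw=cw,
        phantom_fd=phantom_fd,
        phantom_props={
            "wavelengths": instrument.phantom_wavelengths.tolist(),
            "mua": instrument.phantom_mua.tolist(),
            "musp": instrument.phantom_musp.tolist(),
        },
        standard_cw=standard_cw,
        truth=truth,
    )


def simulate_cohort(
    config: CohortConfig,
    geometry: MeasurementGeometry = MeasurementGeometry(),
    identity_instrument: bool = False,
) -> list[RawSessionBundle]:
    """Simulate trajectories and render every session (one instrument)."""
    truths = simulate_trajectories(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    instrument = make_instrument(config, rng, identity=identity_instrument)
    basis = load_basis(wavelengths=STANDARD_GRID)
    bundles = []
    for truth in truths:
        bundles.append(
            render_measurements(truth, instrument, config, rng, geometry, basis)
        )
    return bundles


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------


def write_session_bundle(bundle: RawSessionBundle, directory) -> Path:
    """Write one session bundle as a directory of CSV/JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "calibration").mkdir(exist_ok=True)
    with open(directory / "session.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=1)
    bundle.fd.to_csv(directory / "fd.csv", index=False, float_format="%.12g")
    cw = bundle.cw.copy()
    cw.columns = [f"{c:g}" for c in cw.columns]
    cw.to_csv(directory / "cw.csv", float_format="%.12g")
    bundle.phantom_fd.to_csv(
        directory / "calibration" / "phantom_fd.csv", index=False,
        float_format="%.12g",
    )
    with open(directory / "calibration" / "phantom_reference.json", "w") as fh:
        json.dump(bundle.phantom_props, fh, indent=1)
    bundle.standard_cw.to_csv(
        directory / "calibration" / "standard_cw.csv", index=False,
        float_format="%.12g",
    )
    if bundle.truth is not None:
        tr = bundle.truth
        with open(directory / "truth.json", "w") as fh:
            json.dump(
                {
                    "subject_id": tr.subject_id,
                    "group": tr.group,
                    "duration_minutes": tr.duration_minutes,
                    "times": tr.times.tolist(),
                    "hbo2": tr.hbo2.tolist(),
                    "hb": tr.hb.tolist(),
                    "water": tr.water.tolist(),
                    "lipid": tr.lipid.tolist(),
                    "melanin": tr.melanin,
                    "background": tr.background,
                    "scattering_a": tr.scattering_a.tolist(),
                    "scattering_b": tr.scattering_b.tolist(),
                    "events": [[t, e] for t, e in tr.events],
                    "bp_records": [list(r) for r in tr.bp_records],
                    "motion_times": list(tr.motion_times),
                    "ultrafiltration_l": tr.ultrafiltration_l,
                    "delta_bv_percent": tr.delta_bv_percent,
                    "true_deltas": tr.true_deltas,
                },
                fh,
                indent=1,
            )
    return directory


_REQUIRED_FILES = (
    "session.json",
    "fd.csv",
    "cw.csv",
    "calibration/phantom_fd.csv",
    "calibration/phantom_reference.json",
    "calibration/standard_cw.csv",
)


def read_session_bundle(directory) -> RawSessionBundle:
    """Read a session bundle; validates schema and version."""
    directory = Path(directory)
    missing = [f for f in _REQUIRED_FILES if not (directory / f).is_file()]
    if missing:
        raise FileNotFoundError(
            f"bundle {directory} missing required files: {missing}"
        )
    with open(directory / "session.json") as fh:
        metadata = json.load(fh)
    required_keys = {"format_version", "subject_id", "group", "duration_minutes"}
    absent = required_keys - metadata.keys()
    if absent:
        raise ValueError(f"session.json missing fields: {sorted(absent)}")
    fd = pd.read_csv(directory / "fd.csv")
    cw = pd.read_csv(directory / "cw.csv", index_col=0)
    cw.columns = cw.columns.astype(float)
    phantom_fd = pd.read_csv(directory / "calibration" / "phantom_fd.csv")
    with open(directory / "calibration" / "phantom_reference.json") as fh:
        phantom_props = json.load(fh)
    standard_cw = pd.read_csv(directory / "calibration" / "standard_cw.csv")

    truth = None
    if (directory / "truth.json").is_file():
        with open(directory / "truth.json") as fh:
            td = json.load(fh)
        truth = GroundTruthSession(
            subject_id=td["subject_id"],
            group=td["group"],
            duration_minutes=td["duration_minutes"],
            times=np.asarray(td["times"]),
            hbo2=np.asarray(td["hbo2"]),
            hb=np.asarray(td["hb"]),
            water=np.asarray(td["water"]),
            lipid=np.asarray(td["lipid"]),
            melanin=td["melanin"],
            background=td["background"],
            scattering_a=np.asarray(td["scattering_a"]),
            scattering_b=np.asarray(td["scattering_b"]),
            events=[(t, e) for t, e in td["events"]],
            bp_records=[tuple(r) for r in td["bp_records"]],
            motion_times=list(td["motion_times"]),
            ultrafiltration_l=td["ultrafiltration_l"],
            delta_bv_percent=td["delta_bv_percent"],
            true_deltas=td.get("true_deltas", {}),
        )
    return RawSessionBundle(
        subject_id=metadata["subject_id"],
        metadata=metadata,
        fd=fd,
        cw=cw,
        phantom_fd=phantom_fd,
        phantom_props=phantom_props,
        standard_cw=standard_cw,
        truth=truth,
    )
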