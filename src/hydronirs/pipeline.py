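"""End-to-end orchestration: raw session bundles to cohort statistics.

``process_session`` runs the optical chain for one subject:
calibrate FD/CW -> invert FD per wavelength -> fit the scattering power law
-> scale CW to absolute units -> recover broadband absorption -> estimate
baseline melanin -> unmix chromophores per minute -> artifact reduction and
robust smoothing.

``analyze_cohort`` aggregates processed sessions: start-to-end deltas,
short-session exclusion, time-normalized group traces, two-sample t-tests,
discriminant-analysis feature search with ROC/AUC, and the AUC-versus-
completion curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import cohort as co
from . import timeseries as ts
from .chromophores import (
    estimate_baseline_melanin,
    fit_chromophores,
    load_basis,
)
from .optics import (
    FDSample,
    LookupTable,
    MeasurementGeometry,
    OpticalProperties,
    build_lut,
    invert_fd,
)
from .timeseries import PERCENT_GRID, TaraParams, TimeCourse

__all__ = [
    "RunConfig",
    "ProcessedSession",
    "CohortAnalysisResult",
    "process_session",
    "analyze_cohort",
]

METRICS = ("hbo2", "hb", "hbt", "sto2", "water_ratio", "scattering_a", "scattering_b")

DELTA_METRICS = ("hbo2", "hb", "hbt", "sto2", "water_ratio")


@dataclass
class RunConfig:
    """Stage parameters for one reproducible pipeline run."""

    seed: int = 0
    baseline_window: int = 5  # samples used for the melanin estimate
    scaling_mode: str = "anchored_smooth"
    basis_resolution_fwhm_nm: float | None = 7.5
    loess_span: float = 0.05
    mad_threshold: float = 6.0
    delta_window_min: float = 5.0
    delta_source: str = "clean"  # 'clean' (artifact-reduced) or 'smooth'
    min_longitudinal_duration: float = 114.0
    lda_validation: str = "loocv"
    max_subset_size: int = 3
    equal_var_ttest: bool = True
    tara: TaraParams = field(default_factory=TaraParams)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tara"] = dict(self.tara.__dict__)
        return d


@dataclass
class ProcessedSession:
    """Per-subject tables produced by the optical processing chain."""

    subject_id: str
    duration_minutes: float
    metadata: dict
    times: np.ndarray
    raw: pd.DataFrame  # per-minute metrics straight from the unmixer
    clean: pd.DataFrame  # after transient-artifact reduction
    smooth: pd.DataFrame  # after robust LOESS
    optical: pd.DataFrame  # per-minute per-FD-wavelength mua/musp and (a, b)
    melanin_fraction: float
    dropped_samples: list
    valid: bool

    @property
    def adverse_event(self) -> bool:
        return len(self.metadata.get("events", [])) > 0


def process_session(
    bundle,
    run_config: RunConfig | None = None,
    lut: LookupTable | None = None,
) -> ProcessedSession:
    """Run the full optical chain on one raw session bundle."""
    rc = run_config or RunConfig()
    geometry = MeasurementGeometry(
        **{
            k: v
            for k, v in bundle.metadata.get("geometry", {}).items()
            if k in ("source_detector_separation", "refractive_index")
        }
    )
    if lut is None:
        lut = build_lut(geometry=geometry, check_interpolation=False)

    wl_grid = cal.STANDARD_GRID
    basis = load_basis(
        wavelengths=wl_grid,
        resolution_fwhm_nm=rc.basis_resolution_fwhm_nm,
    )

    # calibrations
    phantom = bundle.phantom_props
    phantom_props = OpticalProperties(
        wavelengths=np.asarray(phantom["wavelengths"], dtype=float),
        mua=np.asarray(phantom["mua"], dtype=float),
        musp=np.asarray(phantom["musp"], dtype=float),
    )
    phantom_samples = [
        FDSample(r.wavelength_nm, r.freq_MHz, r.amplitude, r.phase)
        for r in bundle.phantom_fd.itertuples()
    ]
    fd_cal = cal.calibrate_fd(phantom_samples, phantom_props, geometry)
    std_wl = bundle.standard_cw["wavelength_nm"].to_numpy(dtype=float)
    std_counts = np.interp(wl_grid, std_wl, bundle.standard_cw["counts"].to_numpy())
    std_refl = np.interp(
        wl_grid, std_wl, bundle.standard_cw["reflectivity"].to_numpy()
    )

    times = np.asarray(sorted(bundle.fd["time_min"].unique()), dtype=float)
    fd_by_time = dict(tuple(bundle.fd.groupby("time_min")))
    cw_wl = bundle.cw.columns.to_numpy(dtype=float)

    dropped = []
    mua_spectra = np.full((times.size, wl_grid.size), np.nan)
    opt_rows = []
    warm: dict[float, tuple[float, float]] = {}
    for it, t in enumerate(times):
        try:
            rows = fd_by_time[t]
            samples = fd_cal.apply(
                FDSample(r.wavelength_nm, r.freq_MHz, r.amplitude, r.phase)
                for r in rows.itertuples()
            )
            fd_wl, fd_mua, fd_musp = [], [], []
            any_oor = False
            for s in samples:
                res = invert_fd([s], geometry, x0=warm.get(s.wavelength))
                if res.out_of_range:
                    any_oor = True
                else:
                    warm[s.wavelength] = (res.mua, res.musp)
                fd_wl.append(s.wavelength)
                fd_mua.append(res.mua)
                fd_musp.append(res.musp)
                opt_rows.append(
                    (t, s.wavelength, res.mua, res.musp, res.out_of_range)
                )
            if any_oor:
                raise ValueError("FD inversion out of range")
            law = cal.fit_power_law(fd_wl, fd_musp)
            musp_spec = cal.extrapolate_musp(law, wl_grid)

            raw_spec = np.interp(
                wl_grid, cw_wl, bundle.cw.loc[t].to_numpy(dtype=float)
            )
            cw_calibrated, _mask = cal.calibrate_cw(
                raw_spec, std_counts, std_refl, wl_grid
            )
            fd_props = OpticalProperties(
                wavelengths=np.asarray(fd_wl),
                mua=np.asarray(fd_mua),
                musp=np.asarray(fd_musp),
            )
            scaled, _gain, _res = cal.scale_cw_to_absolute(
                cw_calibrated, wl_grid, fd_props, law, lut, mode=rc.scaling_mode
            )
            recovery = cal.recover_broadband_mua(scaled, musp_spec, lut, wl_grid)
            if not recovery.valid:
                raise ValueError("broadband recovery out of range")
            mua_spectra[it] = recovery.mua
        except (ValueError, KeyError) as exc:
            dropped.append((float(t), str(exc)))
            opt_rows.append((t, np.nan, np.nan, np.nan, True))

    valid_rows = np.isfinite(mua_spectra).sum(axis=1) > 0
    if valid_rows.sum() < max(rc.baseline_window, 2):
        raise ValueError(
            f"session {bundle.subject_id}: too few valid samples "
            f"({valid_rows.sum()})"
        )

    # baseline melanin from the first valid samples, then fixed for the rest
    baseline_idx = np.nonzero(valid_rows)[0][: rc.baseline_window]
    melanin = estimate_baseline_melanin(
        [mua_spectra[i] for i in baseline_idx], basis
    )

    optical = pd.DataFrame(
        opt_rows,
        columns=["time_min", "wavelength_nm", "mua", "musp", "out_of_range"],
    )
    scat = (
        optical.dropna()
        .groupby("time_min")
        .apply(
            lambda g: pd.Series(
                {
                    "scattering_a": cal.fit_power_law(
                        g["wavelength_nm"], g["musp"]
                    ).amplitude_a,
                    "scattering_b": cal.fit_power_law(
                        g["wavelength_nm"], g["musp"]
                    ).power_b,
                }
            ),
            include_groups=False,
        )
        if len(optical.dropna())
        else pd.DataFrame(columns=["scattering_a", "scattering_b"])
    )

    records = []
    for it, t in enumerate(times):
        if not valid_rows[it]:
            records.append({m: np.nan for m in METRICS} | {"time_min": t})
            continue
        state = fit_chromophores(
            mua_spectra[it], basis, melanin_mode=("fixed", melanin)
        )
        records.append(
            {
                "time_min": t,
                "hbo2": state.hbo2,
                "hb": state.hb,
                "hbt": state.hbt,
                "sto2": state.sto2,
                "water_ratio": state.water_ratio,
                "scattering_a": scat["scattering_a"].get(t, np.nan),
                "scattering_b": scat["scattering_b"].get(t, np.nan),
            }
        )
    raw = pd.DataFrame(records).set_index("time_min")

    clean = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    smooth = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for m in METRICS:
        tc = TimeCourse(times=times, values=raw[m].to_numpy(), metric_tag=m)
        try:
            clean_tc, _art = ts.reduce_transient_artifacts(tc, rc.tara)
        except ValueError:
            clean_tc = tc
        clean[m] = clean_tc.values
        smooth[m] = ts.robust_loess(
            clean_tc, span_fraction=rc.loess_span, mad_threshold=rc.mad_threshold
        ).values

    duration = float(bundle.metadata.get("duration_minutes", times[-1]))
    return ProcessedSession(
        subject_id=bundle.subject_id,
        duration_minutes=duration,
        metadata=bundle.metadata,
        times=times,
        raw=raw,
        clean=clean,
        smooth=smooth,
        optical=optical,
        melanin_fraction=melanin,
        dropped_samples=dropped,
        valid=len(dropped) <= 0.5 * times.size,
    )


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortAnalysisResult:
    """Cohort-level outputs: deltas, group statistics, classification."""

    deltas: pd.DataFrame  # per subject: delta metrics + covariates + label
    group_stats: pd.DataFrame  # per metric: means, SDs, t, p
    traces: dict  # metric -> DataFrame (subjects x percent grid)
    trace_stats: dict  # metric -> DataFrame (percent, mean/se per group)
    subset_ranking: pd.DataFrame
    best_classification: co.ClassificationResult | None
    auc_vs_completion: pd.DataFrame
    exclusion_log: list

    def summary_dict(self) -> dict:
        out = {
            "n_subjects": int(len(self.deltas)),
            "n_adverse": int(self.deltas["adverse_event"].sum()),
            "group_stats": self.group_stats.reset_index().to_dict("records"),
            "excluded_longitudinal": self.exclusion_log,
        }
        if self.best_classification is not None:
            bc = self.best_classification
            out["best_subset"] = list(bc.features)
            out["best_auc"] = bc.auc
            out["confusion"] = {
                "tp": bc.tp, "tn": bc.tn, "fp": bc.fp, "fn": bc.fn,
            }
            out["validation"] = bc.validation_tag
        return out

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.deltas.to_csv(directory / "deltas.csv")
        self.group_stats.to_csv(directory / "group_stats.csv")
        self.subset_ranking.to_csv(directory / "subset_ranking.csv", index=False)
        self.auc_vs_completion.to_csv(
            directory / "auc_vs_completion.csv", index=False
        )
        for m, df in self.trace_stats.items():
            df.to_csv(directory / f"trace_{m}.csv", index=False)
        if self.best_classification is not None:
            np.savetxt(
                directory / "roc_points.csv",
                self.best_classification.roc_points,
                delimiter=",",
                header="fpr,tpr",
                comments="",
            )
        with open(directory / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1)


def _session_delta_sbp(metadata) -> float:
    bp = metadata.get("bp_records") or []
    if len(bp) < 2:
        return float("nan")
    return float(bp[-1][1] - bp[0][1])


def analyze_cohort(
    processed: list[ProcessedSession],
    run_config: RunConfig | None = None,
) -> CohortAnalysisResult:
    """Aggregate processed sessions into the cohort-level analysis."""
    rc = run_config or RunConfig()
    if sum(p.adverse_event for p in processed) < 2 or sum(
        not p.adverse_event for p in processed
    ) < 2:
        raise ValueError("need at least two subjects per group")

    # --- per-subject delta metrics and covariates
    rows = {}
    for p in processed:
        source = p.clean if rc.delta_source == "clean" else p.smooth
        row = {}
        for m in DELTA_METRICS:
            tc = TimeCourse(times=p.times, values=source[m].to_numpy(), metric_tag=m)
            try:
                row[f"delta_{m}"] = ts.compute_delta(tc, rc.delta_window_min)
            except ValueError:
                row[f"delta_{m}"] = np.nan
        for m in ("scattering_a", "scattering_b"):
            vals = source[m].to_numpy()
            tail = vals[p.times >= p.times[-1] - rc.delta_window_min]
            row[m] = float(np.nanmean(tail)) if np.isfinite(tail).any() else np.nan
        row["delta_bv"] = (
            p.metadata.get("delta_bv_percent")
            if p.metadata.get("delta_bv_percent") is not None
            else np.nan
        )
        row["delta_sbp"] = _session_delta_sbp(p.metadata)
        row["duration_minutes"] = p.duration_minutes
        row["adverse_event"] = p.adverse_event
        rows[p.subject_id] = row
    deltas = pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject")

    # --- group comparisons
    stats_rows = {}
    for colname in [f"delta_{m}" for m in DELTA_METRICS] + [
        "scattering_a", "scattering_b", "delta_bv", "delta_sbp",
    ]:
        try:
            g = co.group_compare(
                deltas[colname], deltas["adverse_event"],
                equal_var=rc.equal_var_ttest,
            )
            stats_rows[colname] = {
                "mean_adverse": g.mean_pos,
                "sd_adverse": g.sd_pos,
                "n_adverse": g.n_pos,
                "mean_nonadverse": g.mean_neg,
                "sd_nonadverse": g.sd_neg,
                "n_nonadverse": g.n_neg,
                "t": g.t_statistic,
                "p": g.p_value,
            }
        except ValueError as exc:
            stats_rows[colname] = {"error": str(exc)}
    group_stats = pd.DataFrame.from_dict(stats_rows, orient="index").rename_axis(
        "metric"
    )

    # --- longitudinal traces (short sessions excluded)
    included, exclusion_log = ts.filter_sessions(
        processed, min_duration=rc.min_longitudinal_duration,
        purpose="longitudinal",
    )
    traces = {}
    for m in METRICS:
        per_subject = {}
        for p in included:
            tc = TimeCourse(times=p.times, values=p.smooth[m].to_numpy(),
                            metric_tag=m)
            try:
                tr = ts.normalize_time(tc, p.duration_minutes)
            except ValueError:
                continue
            per_subject[p.subject_id] = tr.values
        traces[m] = pd.DataFrame.from_dict(
            per_subject, orient="index", columns=PERCENT_GRID
        ).rename_axis("subject")

    labels_included = pd.Series(
        {p.subject_id: p.adverse_event for p in included}, name="adverse_event"
    )
    trace_stats = {}
    for m in METRICS:
        df = traces[m]
        out = {"percent": PERCENT_GRID}
        for grp, flag in (("adverse", True), ("nonadverse", False)):
            sub = df.loc[labels_included.reindex(df.index) == flag]
            if len(sub):
                vals = sub.to_numpy()
                n = np.isfinite(vals).sum(axis=0)
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", RuntimeWarning)
                    out[f"mean_{grp}"] = np.nanmean(vals, axis=0)
                    out[f"se_{grp}"] = np.nanstd(vals, axis=0, ddof=1) / np.sqrt(
                        np.maximum(n, 1)
                    )
        trace_stats[m] = pd.DataFrame(out)

    # --- classification
    feature_cols = [f"delta_{m}" for m in DELTA_METRICS] + [
        "scattering_a", "scattering_b", "delta_bv", "delta_sbp",
    ]
    subset_ranking = co.feature_subset_search(
        deltas, feature_cols, max_subset_size=rc.max_subset_size,
        validation=rc.lda_validation,
    )
    best = None
    top = subset_ranking.dropna(subset=["auc"])
    if len(top):
        best = co.lda_fit_score(
            deltas, top.iloc[0]["subset"], validation=rc.lda_validation
        )

    # --- AUC over dialysis completion for the headline feature set
    wr = traces["water_ratio"]
    auc_inputs = {
        "delta_water_ratio": wr.sub(wr.iloc[:, 0], axis=0),
        "scattering_a": traces["scattering_a"],
        "scattering_b": traces["scattering_b"],
    }
    auc_vs_completion = co.auc_timecourse(
        auc_inputs,
        labels_included,
        ("delta_water_ratio", "scattering_a", "scattering_b"),
        validation=rc.lda_validation,
    )

    return CohortAnalysisResult(
        deltas=deltas,
        group_stats=group_stats,
        traces=traces,
        trace_stats=trace_stats,
        subset_ranking=subset_ranking,
        best_classification=best,
        auc_vs_completion=auc_vs_completion,
        exclusion_log=exclusion_log,
    )
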