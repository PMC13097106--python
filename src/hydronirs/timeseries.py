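"""Cleaning and summarising per-subject chromophore time courses.

Stages, in pipeline order:

1. transient-artifact reduction (TARA): a sparse decomposition that splits
   the series into a smooth physiological component, sparse spikes, and
   sparse steps (motion and probe-shift artifacts);
2. robust LOESS smoothing: local quadratic regression with tricube weights
   and zero weight for samples beyond 6 mean absolute deviations;
3. time normalization to percent dialysis completion and start-to-end
   delta metrics on endpoint windows.

All stages are missing-aware (NaN propagates, never silently becomes 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, medfilt
from skimage.restoration import denoise_tv_chambolle

__all__ = [
    "TimeCourse",
    "NormalizedTrace",
    "TaraParams",
    "reduce_transient_artifacts",
    "robust_loess",
    "normalize_time",
    "compute_delta",
    "filter_sessions",
    "group_trace_stats",
    "PERCENT_GRID",
]

PERCENT_GRID = np.linspace(0.0, 100.0, 101)
"""Cohort-wide percent-completion grid (101 points)."""


@dataclass
class TimeCourse:
    """One metric sampled over a dialysis session."""

    times: np.ndarray  # minutes from dialysis start, strictly increasing
    values: np.ndarray
    weights: np.ndarray | None = None  # 0-1 per sample
    metric_tag: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if not (self.times.shape == self.values.shape == self.weights.shape):
            raise ValueError("times, values, weights must share a shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class NormalizedTrace:
    """A metric resampled onto the percent-completion grid."""

    percent: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    metric_tag: str = ""


@dataclass
class TaraParams:
    """Tuning of the sparse artifact decomposition.

    Thresholds are multiples of the MAD of the high-frequency residual;
    ``lowpass_cutoff`` is in cycles per sample.
    """

    lowpass_cutoff: float = 0.04
    spike_weight: float = 3.0
    step_weight: float = 4.0
    n_iterations: int = 12
    min_samples: int = 20


def _lowpass(y: np.ndarray, cutoff: float) -> np.ndarray:
    b, a = butter(2, 2.0 * cutoff)
    padlen = min(3 * max(len(a), len(b)), y.size - 1)
    return filtfilt(b, a, y, padlen=padlen)


def _soft(x: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


def reduce_transient_artifacts(
    tc: TimeCourse, params: TaraParams | None = None
) -> tuple[TimeCourse, TimeCourse]:
    """Split a time course into a clean component and a sparse artifact.

    Alternates three estimates until stable: a low-pass trend (Butterworth,
    zero phase), a sparse spike component (soft thresholding of the
    residual), and a piecewise-constant step component (1-D total-variation
    denoising of the residual). The decomposition is conservative:
    ``clean + artifact == input`` exactly, and on artifact-free smooth
    input the artifact component is numerically negligible.

    NaN samples are interpolated internally and returned as NaN.
    """
    params = params or TaraParams()
    y_raw = np.asarray(tc.values, dtype=float)
    if y_raw.size < params.min_samples:
        warnings.warn("series too short for artifact reduction; passing through",
                      stacklevel=2)
        artifact = replace(tc, values=np.zeros_like(y_raw))
        return tc, artifact

    nan_mask = ~np.isfinite(y_raw)
    y = y_raw.copy()
    if nan_mask.any():
        if nan_mask.all():
            raise ValueError("all samples missing")
        y[nan_mask] = np.interp(
            tc.times[nan_mask], tc.times[~nan_mask], y_raw[~nan_mask]
        )

    # noise scale from the first-difference MAD (robust to trend + artifacts)
    diff = np.diff(y)
    sigma = float(np.median(np.abs(diff - np.median(diff)))) / 0.6745 / np.sqrt(2.0)
    sigma = max(sigma, 1e-12 * max(np.ptp(y), 1.0))

    # sparse step component: thresholded de-trended first differences
    d = np.diff(y)
    d_resid = d - medfilt(d, 9)
    jumps = np.where(np.abs(d_resid) > params.step_weight * sigma, d_resid, 0.0)
    steps = np.concatenate([[0.0], np.cumsum(jumps)])
    steps -= np.median(steps)  # constant offsets belong to the trend
    # refine the piecewise-constant estimate by total-variation denoising of
    # the step-corrected residual around a robust smooth trend
    base = medfilt(y - steps, 9)
    tv = denoise_tv_chambolle(y - steps - base, weight=params.step_weight * sigma)
    tv[np.abs(tv) < 2.0 * sigma] = 0.0
    steps = steps + tv - np.median(tv)

    # sparse spike component, iterated against the low-pass trend
    spikes = np.zeros_like(y)
    r0 = y - steps - medfilt(y - steps, 7)
    spikes = np.where(np.abs(r0) > params.spike_weight * sigma, r0, 0.0)
    for _ in range(params.n_iterations):
        trend = _lowpass(y - spikes - steps, params.lowpass_cutoff)
        resid = y - trend - steps
        new_spikes = np.where(
            np.abs(resid) > params.spike_weight * sigma,
            _soft(resid, params.spike_weight * sigma),
            0.0,
        )
        if np.allclose(new_spikes, spikes, atol=1e-12):
            spikes = new_spikes
            break
        spikes = new_spikes

    artifact_vals = spikes + steps
    clean_vals = y - artifact_vals
    clean_vals[nan_mask] = np.nan
    artifact_vals[nan_mask] = np.nan
    clean = replace(tc, values=clean_vals)
    artifact = replace(tc, values=artifact_vals, metric_tag=tc.metric_tag + "_artifact")
    return clean, artifact


def robust_loess(
    tc: TimeCourse,
    span_fraction: float = 0.05,
    degree: int = 2,
    mad_threshold: float = 6.0,
    robust_iterations: int = 1,
) -> TimeCourse:
    """Local polynomial regression with tricube weights and MAD rejection.

    Each point is fitted by weighted least squares over the nearest
    ``span_fraction`` of the data with tricube distance weights. After the
    first pass, samples whose residual exceeds ``mad_threshold`` mean
    absolute deviations (of the global residuals) receive weight zero and
    the fit is re-run -- at least one robustness pass.

    A window whose weights all vanish yields NaN at that point.
    """
    t = tc.times
    y = tc.values
    n = y.size
    k = max(int(np.ceil(span_fraction * n)), degree + 2)
    k = min(k, n)
    base_w = tc.weights * np.isfinite(y)

    def one_pass(extra_w: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        w_all = base_w * extra_w
        for i in range(n):
            d = np.abs(t - t[i])
            idx = np.argpartition(d, k - 1)[:k]
            h = d[idx].max() * 1.0001  # keep the farthest neighbor usable
            if h == 0:
                h = 1.0
            tri = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
            w = tri * w_all[idx]
            ok = w > 0
            if ok.sum() < degree + 1:
                continue
            tt = t[idx][ok] - t[i]
            try:
                coeffs = np.polyfit(tt, y[idx][ok], degree, w=np.sqrt(w[ok]))
            except np.linalg.LinAlgError:
                continue
            out[i] = np.polyval(coeffs, 0.0)
        return out

    from scipy.ndimage import median_filter

    extra = np.ones(n)
    fitted = one_pass(extra)
    # robust reference guards against rejection cascades: a lone outlier
    # contaminates the local fits of its neighbors, so a neighbor is only
    # down-weighted if it is also an outlier against the running median
    ref = median_filter(np.nan_to_num(y, nan=np.nanmedian(y)),
                        size=min(2 * k + 1, 15), mode="nearest")
    for _ in range(max(robust_iterations, 1)):
        resid = y - fitted
        ok = np.isfinite(resid)
        if not ok.any():
            break
        mad = float(np.mean(np.abs(resid[ok] - np.mean(resid[ok]))))
        if mad <= 0:
            break
        outlier = (np.abs(np.nan_to_num(resid)) > mad_threshold * mad) & (
            np.abs(np.nan_to_num(y - ref)) > mad_threshold * mad
        )
        extra = np.where(outlier, 0.0, 1.0)
        fitted = one_pass(extra)
    return replace(tc, values=fitted, weights=base_w * extra)


def normalize_time(
    tc: TimeCourse,
    session_duration: float,
    grid: np.ndarray = PERCENT_GRID,
) -> NormalizedTrace:
    """Resample a time course onto the percent-dialysis-completion grid.

    Linear interpolation; beyond the sampled range the first/last valid
    values are held, so the grid endpoints equal the series endpoints.
    """
    if session_duration <= 0:
        raise ValueError("session duration must be positive")
    ok = np.isfinite(tc.values)
    if not ok.any():
        raise ValueError("empty (all-missing) series")
    pct = tc.times[ok] / session_duration * 100.0
    vals = np.interp(grid, pct, tc.values[ok])
    return NormalizedTrace(percent=np.asarray(grid, dtype=float), values=vals,
                           metric_tag=tc.metric_tag)


def compute_delta(tc: TimeCourse, window: float = 5.0) -> float:
    """Start-to-end change: mean over the last window minus the first.

    Windows are in minutes; a window with no valid samples makes the delta
    missing (NaN).
    """
    t = tc.times
    if t[-1] - t[0] < 2.0 * window:
        raise ValueError("series must span at least twice the window")
    first = (t <= t[0] + window) & np.isfinite(tc.values)
    last = (t >= t[-1] - window) & np.isfinite(tc.values)
    if not first.any() or not last.any():
        return float("nan")
    return float(np.mean(tc.values[last]) - np.mean(tc.values[first]))


def filter_sessions(
    sessions,
    min_duration: float = 114.0,
    purpose: str = "longitudinal",
):
    """Short-session exclusion for longitudinal analyses.

    ``purpose='longitudinal'`` drops sessions with duration <= min_duration
    minutes (boundary excluded too); ``purpose='delta'`` keeps all. Sessions
    may be any objects exposing ``duration_minutes`` and ``subject_id``.

    Returns ``(included, exclusion_log)``.
    """
    if purpose not in ("longitudinal", "delta"):
        raise ValueError("purpose must be 'longitudinal' or 'delta'")
    included = []
    log = []
    for s in sessions:
        if purpose == "longitudinal" and s.duration_minutes <= min_duration:
            log.append(
                f"excluded {s.subject_id}: duration {s.duration_minutes:.0f} min "
                f"<= {min_duration:.0f} min"
            )
        else:
            included.append(s)
    return included, log


def group_trace_stats(traces) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and standard error over NormalizedTraces, per grid point.

    Returns ``(mean, standard_error, n_valid)`` arrays on the shared grid.
    """
    traces = list(traces)
    vals = np.vstack([tr.values for tr in traces])
    n = np.sum(np.isfinite(vals), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(n, 1))
    return mean, se, n
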