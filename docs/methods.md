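# Methods

This note records the models implemented in `hydronirs`, their
assumptions, the defaults and why, and what the synthetic data do and do
not establish.

## Forward model of diffuse reflectance

Light transport in the probed tissue is modelled as photon diffusion in a
homogeneous semi-infinite medium. For absorption μa, reduced scattering
μs′ (both mm⁻¹), refractive index n = 1.4 and source–detector separation
ρ = 20 mm, the complex photon-density-wave reflectance at angular
modulation frequency ω is the extrapolated-boundary dipole solution: an
isotropic source at depth z₀ = 1/(μa+μs′), an image source mirrored about
the extrapolated boundary z = −2AD (A from the Fresnel-moment integrals;
A = 2.95 for n = 1.4), complex attenuation coefficient
k = sqrt((μa + iωn/c)/D) with D = 1/(3(μa+μs′)). Detected reflectance
combines fluence and flux with the standard partial-current weights
(0.118, 0.306 at n = 1.4). Amplitude is |R|, phase is the lag −arg R,
zero at ω = 0 and increasing with frequency.

Assumptions: homogeneous tissue (no skin/adipose/muscle layering),
point-like source/detector, index-matched coupling at the fiber tips.
The homogeneity assumption is the dominant approximation for real limb
measurements; it is shared by the simulator, so round trips quantify
pipeline fidelity, not anatomical truth.

A seeded white Monte Carlo engine provides the independent reference: one
absorption-free simulation at μs′ = 1 mm⁻¹ (isotropic scattering,
Fresnel boundary with weight splitting) records exit radius and path
length; similarity scaling then yields reflectance at any (μa, μs′, ρ, f).
Truncation limits (path ≤ 5000 mm, radius ≤ 150 mm in the scaled frame)
sit far into the attenuated tail for the tabulated property range. A
frozen 2×10⁷-photon reference (probe grid over μa 0.001–0.06, μs′
0.3–2.5 mm⁻¹) ships with the test suite.

Measured against that reference, the diffusion amplitude agrees to
0.1–3% over the diffusive core of the grid, defined by two
transport-theory conditions: ρμs′ ≥ 15 (enough scattering events) and a
predicted decay-constant amplitude error μeff·ρ·(2/5)(μa/μt) ≤ 5% (the
exact transport eigenvalue for isotropic scattering satisfies
κ₀/μeff ≈ 1 − (2/5)(μa/μt)). Outside it the model
departs for understood reasons: at μeff·ρ ≳ 12 the exact transport
asymptotic decay eigenvalue differs from the diffusion μeff by ~1.5–2%
and the exponential amplifies this to 10–16% amplitude deficit; at
ρμs′ ≲ 10 the absolute reflectance is overestimated by 5–18%
(near-field limit of the fluence+flux expression). One acceptance test
asserts a blanket 5% bound over the whole default grid and fails by
design, documenting this limit; no standard semi-infinite diffusion
expression meets it. The look-up table defaults to the diffusion builder
(fast, smooth); the Monte Carlo builder is available where its fidelity
is worth the cost, and samples inverted outside the validity domain are
flagged by the μs′ < 10 μa warning.

One consequence of the 20 mm separation worth stating: reflectance is
*decreasing* in μs′ there (the far-field attenuation e^(−μ_eff ρ)
dominates the source-strength prefactor), while near-source reflectance
would increase with scattering. The inversion relies only on smooth
monotone structure, not on the sign.

## Inversion

FD inversion solves for (log μa, log μs′) by bounded least squares over
log-amplitude and phase residuals, weighted 1/σ per channel (σ = 1%
amplitude, 5 mrad phase), multi-started from a coarse objective scan; the
per-minute pipeline warm-starts from the previous minute. Optima pinned
at the parameter bounds are flagged out-of-range and the sample dropped.

Broadband recovery inverts the LUT per wavelength at fixed μs′(λ) from
the power law: the CW reflectance curve versus μa is strictly monotone,
so a dense-sampled interpolation inverts it to ~0.1%. The calibrated CW
spectrum is first scaled onto the model's absolute units with the
"anchored smooth gain": log-gain computed exactly at the four FD
wavelengths and interpolated linearly in between (constant outside). The
smooth mode absorbs residual spectral instrument response such as probe
coupling; a single-scalar mode is the conservative alternative. Scaling
is applied per time sample, so slow coupling drifts do not leak into the
recovered spectra.

## Chromophores

Beer's law with nonnegative concentrations for HbO₂/Hb (μM), water and
lipid (volume fractions of pure-component absorption) and a melanin
shape, plus a spectrally constant background bounded below at
−0.005 mm⁻¹ (it absorbs heterogeneity and basis mismatch, which can have
either sign). The bounded problem is transformed by shifting the
background floor and solved exactly with the Lawson–Hanson NNLS
active-set algorithm — noiseless in-span spectra unmix to machine
precision. Melanin is estimated as the median of free fits over the
first 5 samples (median for robustness to a corrupted baseline spectrum)
and held fixed thereafter; epidermal melanin does not change over a
session, and fixing it removes a slowly varying degeneracy with the
background term.

The packaged basis spectra are a synthetic compilation: smooth PCHIP
interpolations of literature-informed anchor values (hemoglobin molar
extinction; water absorption peaking near 975 nm; lipid near 930 nm;
melanin as a λ^−3.48 power law). They have realistic shapes and
magnitudes but are not a verbatim copy of any published table. Because
simulator and unmixer share the basis, every self-consistency result in
the test suite is independent of basis accuracy; absolute concentrations
from real spectra would inherit basis error. When spectra are rendered
at the spectrometer's 7.5 nm resolution the unmixer uses the basis
convolved to the same resolution, the standard way to avoid
resolution-mismatch bias (residual bias ≤ ~0.5 μM HbO₂, ≤ 0.007 water
ratio in noiseless round trips).

## Time-series cleaning

Transient-artifact reduction decomposes each chromophore series into
trend + sparse spikes + sparse steps. Steps are detected from
median-detrended first differences thresholded at 4 robust σ (σ from the
first-difference MAD) and refined by 1-D total-variation denoising;
spikes by thresholding the residual around a zero-phase low-pass trend
(Butterworth, 0.04 cycles/sample), iterated to a fixed point. The
decomposition is exactly conservative (clean + artifact = input) and
returns a null artifact on smooth input. Thresholds (3σ spikes, 4σ
steps) were set against the simulator's motion model: 1-3-minute
transients of ~15% gain with occasional persistent ~2% steps.

Robust LOESS: local quadratic regression, tricube weights over the
nearest 5% of samples, with samples beyond 6 *mean* absolute deviations
(the configurable literal reading; median-based MAD available) given
weight zero and the fit re-run. A lone outlier contaminates its
neighbors' first-pass fits, so rejection additionally requires the point
to be an outlier against a running median — without this guard a single
large spike empties whole windows.

Δ metrics are means over 5-minute endpoint windows (single samples are
too noisy at 1/min sampling) computed from the artifact-reduced,
unsmoothed series; LOESS smoothing is applied for the longitudinal
traces. Both choices are configurable. Sessions lasting ≤ 114 min (half
the longest session) are excluded from longitudinal trace averaging but
retained for Δ metrics.

## Cohort statistics

Group comparisons use the pooled two-sample t-test (Welch optional); no
multiple-testing correction is applied across the Δ-metric family by
default (a Holm option exists). Classification is linear discriminant
analysis: shared covariance with a mild relative ridge (10⁻⁸ of the mean
eigenvalue — large enough to absorb exact collinearity, small enough
that duplicated features leave scores unchanged to 10⁻⁶), empirical
priors at the Gaussian decision threshold, features standardized.
Leave-one-out validation is the default report; resubstitution is also
available since small-cohort published confusion matrices often use it.
AUC is the Mann–Whitney concordance with ties at 0.5. The feature-subset
search enumerates all subsets up to size 3.

A calibration note on permutation nulls: re-fitting the LDA per permuted
labelling biases the mean AUC away from 0.5 at small n (optimistically
for resubstitution, pessimistically for pooled leave-one-out scores); the
exact chance-level property holds for scores from a single fit evaluated
against permuted labels, and that is what the tests assert.

## Synthetic cohort

The generator draws 18 adverse / 9 nonadverse sessions of 1–4 h
(triangular, mode 3 h). Start-to-end effects per group are the study
conditions: Δ water ratio +0.012 ± 0.035 (adverse) vs −0.037 ± 0.085
(nonadverse); Δ[HbO₂] 14.52 ± 15.82 vs 15.96 ± 12.21 μM; Δ[Hb]
2.25 ± 6.49 vs 1.57 ± 3.88 μM; end-of-session scattering amplitude
higher in nonadverse subjects (1.09 vs 0.95 mm⁻¹, SD 0.15) and slope
1.05 vs 0.90 (SD 0.20) — the scattering separations were chosen to give
single-feature AUCs near 0.75/0.70, the levels the analysis assumes.
Within-session shapes are a logistic ramp plus low-amplitude sinusoidal
drift vanishing at the endpoints, so the endpoint difference equals the
drawn effect exactly; true within-session dynamics are not identifiable
from endpoint summaries and are explicit configuration, not claims.
Baseline composition: water 0.60 ± 0.04, lipid 0.22 ± 0.03 (final water
fraction capped at 0.95 so extreme draws stay physical), HbO₂ 25 ± 5 μM,
Hb 15 ± 3 μM, melanin fraction 0.015 ± 0.005, background
0.001 mm⁻¹. Ultrafiltration 1.6 ± 0.8 L. Blood pressure every 15 min;
16/18 adverse subjects receive a hypotension episode (SBP drop ≥ 22 mmHg)
centred near 52 ± 25% completion; nonadverse subjects are kept clear of
the IDH thresholds. Crit-Line ΔBV is drawn directly as a per-group
numeric column for ~70% of subjects (device physics out of scope).

The instrument model is a smooth random spectral gain (Chebyshev
log-polynomial) for CW, per-wavelength gains and phase offsets for FD,
Gaussian 7.5 nm FWHM spectral response, multiplicative noise (1% CW, 1%
FD amplitude, 5 mrad phase), a ±1% smooth per-session probe-coupling
spectrum, and motion transients at ~1/h. Matching phantom and
reflectance-standard scans are rendered with the same response.

What passing tests show: the pipeline recovers what the forward model
encoded, at the stated noise, with median errors (cohort of 27) under
3 μM HbO₂, 0.02 water ratio, 5% scattering amplitude, 0.15 slope. What
they do not show: performance under layered anatomy, basis-spectrum
error, probe repositioning, or physiology outside the assumed trajectory
family.

## Numerical choices and edge cases

- Units: mm, mm⁻¹, MHz, radians; wavelengths nm; working CW grid 2 nm.
- LUT: 60×60 log-spaced grid, cubic splines in log space; node values are
  exact; off-node CW error < 0.5% (checked at build, warning if coarser).
- Inversion tolerances 10⁻¹²; bounds μa ∈ [5·10⁻⁴, 0.15],
  μs′ ∈ [0.1, 4] mm⁻¹.
- Undefined ratios (zero denominators) propagate as missing values,
  never as zeros; per-sample failures are logged and skipped; a session
  with > 50% failures or > 20% masked wavelengths in a sample is flagged.
- Ties in the subset ranking break toward smaller subsets, then lexical
  feature order.
- The CLI exposes `simulate`, `process`, `analyze` (classification and
  report tables are part of `analyze`'s outputs).

## Known limitations

- Homogeneous (single-layer) tissue model end to end.
- Synthetic basis spectra (see above); absolute concentrations from real
  instruments require a validated extinction compilation.
- The diffusion LUT is biased where μs′/μa is small; such samples are
  flagged rather than corrected (the Monte Carlo builder narrows, but
  does not remove, the gap at those corners).
- Group-level statistics at n = 27 carry the usual small-sample caveats;
  leave-one-out AUCs on 27 subjects have wide confidence bands.
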