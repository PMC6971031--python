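# Methods

This note documents the models implemented in `inirs`, their
assumptions, the parameter defaults and why they were chosen, what the
synthetic data generators emulate (and deliberately do not), and the
numerical choices that affect results.

## Signal model

The measurement object is the complex mutual coherence function
Γ_rs(τ_s, t_d) between sample and reference fields at time of flight
τ_s and laboratory (delay) time t_d.  All analysis operates on this
TOF-domain object; raw spectral fringes, sweep resampling and spectral
shaping are upstream of the toolkit's scope and are represented only
through their effect — the TOF-domain instrument response function
(IRF) that blurs every TOF profile by convolution.

The field autocorrelation per TOF bin,
G1(τ_s, τ_d) = ⟨Γ*(t)Γ(t+τ_d)⟩, is fitted with nested models:

| order | model | regime |
|---|---|---|
| 1 | e^(−ξτ_d) | normalized, late TOF (diffusing-wave) |
| 2 | I_f·e^(−ξτ_d) | unnormalized, late TOF |
| 3 | I_c + I_f·e^(−ξτ_d) | static + dynamic (DLS/DWS-founded) |
| 5 | I_c + I_slow·e^(−ξ_slow τ_d) + I_fast·e^(−ξ_fast τ_d) | empirical bi-exponential |

The static term absorbs anything that decorrelates on scales much
longer than the fit window (default 10 ms).  Fits are on unnormalized
autocorrelations, so amplitudes are in TPSF units; normalized versions
are available by dividing by the zero-lag slice.

## Mean-squared displacement laws

`MSDModel` supplies ⟨Δr²(τ_d)⟩ for Brownian motion (6·D_B·τ_d, D_B in
cm²/s), random (ballistic) flow (v²τ_d², v in cm/s = the standard
deviation of the velocity distribution), hydrodynamic diffusion
(6·D_B{τ_d − τ_C[1 − e^(−τ_d/τ_C)]}, τ_C the time to establish Brownian
motion), and a hybrid (6·D_B·τ_d + v²τ_d²).  The dynamic-scattering
probability α multiplies the diffusing-wave exponent; the product
BFI = α·D_B is the blood flow index in cm²/s.

## Time-domain diffusion TPSF

`tpsf_semi_infinite` implements the extrapolated-boundary semi-infinite
solution: isotropic point source at depth z₀ = 1/μ_s′, negative image
source mirrored about the extrapolated boundary at z_b = 2AD with
D = 1/(3μ_s′); the internal-reflectance factor A comes from the
Groenhuis polynomial in the refractive index.  This is the standard
time-domain NIRS choice; the exact expression is in the docstring.
Optical-property fits start at 100 ps, below which the diffusion
approximation is unreliable, and end where the TPSF falls below a
relative floor (default 10⁻⁴ of peak).  The forward model for fitting
is the IRF-convolved TPSF with a free amplitude and a free TOF offset,
fitted in log space by trust-region least squares on (log μ_a,
log μ_s′).

## Instrument response

The intensity IRF is |FT of the spectral apodization window|² across
the laser tuning range, normalized to unit sum, evaluated on a ≤ 1 ps
grid; FWHM is read off by linear interpolation of the half-maximum
crossings.  A rectangular window over the 64.7 GHz sweep gives
13.7 ps; the default Hann window gives 22.3 ps, matching the ~22 ps
class of resolution the analysis assumes.  The published instrument's
exact shaping window is not derivable from its stated sweep span alone,
so the window is an explicit parameter rather than a hard-coded choice;
a Gaussian IRF of arbitrary FWHM is provided for idealized studies.
At 2.998×10¹⁰ cm/s, 21.9 ps of TOF is 6.6 mm of vacuum path length.

## Correlation-transport Monte Carlo

Photons random-walk through index-matched plane layers: exponential
free paths with the current layer's μ_s (derived from μ_s′ and the
composite anisotropy g = f·g_dyn + (1−f)·g_stat, f the per-event
dynamic probability), Henyey–Greenstein deflections with the
event-type anisotropy, continuous absorption weighting e^(−μ_a·ℓ),
Russian roulette below weight 10⁻⁶ (survival 0.1), 2000 ps default TOF
cutoff, pencil-beam launch, detection through the top surface within a
circular aperture and acceptance cone.  Simplifications, on purpose: no
refraction or Fresnel reflection at internal boundaries, total internal
reflection at the top surface ignored, no voxelized anatomy, no
polarization.

Dynamic events record q² = 2k²(1 − cos θ) per layer.  Under the
independent-scatterer assumption a path's field decorrelation is
Π_i exp[−q_i²⟨Δr²(τ_d)⟩/6], so per-layer q² sums are sufficient
statistics; binning paths by TOF yields G1(τ_s, τ_d) with
G1(τ_s, 0) equal to the binned TPSF by construction.  Empty TOF bins
are NaN, never zero.  The hybrid-motion case applies the MSD kernel
per event rather than sampling per-particle displacements; for the
exponential-family MSDs used here the two coincide at the level of the
accumulated cumulant.

Validation inside the test suite: for a homogeneous all-dynamic
isotropic medium the binned autocorrelations agree pointwise with the
diffusing-wave closed form within Monte Carlo error, the decay-rate
slope agrees within 5%, and the TOF-axis intercept is within two 22 ps
bins of zero.  With sparse (2%), highly anisotropic (g = 0.975) dynamic
scattering, paths whose dynamic deflections are all small-angle
("dynamical snake paths") survive to intermediate TOF and produce the
bi-exponential autocorrelations that a uniformly dynamic, moderately
anisotropic (g = 0.6) phantom does not show.

## Stochastic synthesis

`synthesize_gamma` builds Γ per TOF bin as a frozen-phase static phasor
plus independent unit-variance circular complex AR(1) processes (exact
recursion u[n+1] = a·u[n] + √(1−a²)·w[n], a = e^(−ξΔτ_d)) scaled by
component amplitudes, plus circular complex white noise — Gaussian
field statistics (fully developed speckle) are assumed.  The ensemble
autocorrelation of the motion-free part therefore equals the
static + bi-exponential model exactly, which is what makes round-trip
parameter-recovery tests meaningful.  Bulk motion multiplies all bins
by a common phase factor e^(iθ_bps(t_d)) (rigid axial motion).

Acquisition defaults mirror the swept-source instrument class being
emulated: 100 kHz sweep rate (10 μs lag resolution), 2.5 s blocks of
250,000 delay-time points, 855 nm center wavelength, ~22 ps TOF grid.
Per-bin noise defaults to a 40 dB peak signal-to-noise ratio.  Seeds:
one master seed; per-bin substreams derived deterministically via
`SeedSequence.spawn`.

The motion generator uses a random-walk axial velocity.  The default
per-step velocity standard deviation in the tissue-like preset is
0.2 μm/s (at 10 μs steps), chosen so an unstabilized limb produces
Doppler shifts of a few hundred Hz and raw peak-TOF decorrelation
times of a fraction of a millisecond — the regime where correction
matters — while displacement excursions stay in the tens of
micrometres over 2.5 s.  The statistical form of real physiological
motion is not modeled beyond this (no pulse waveform, no lateral
motion by default); both scale and lateral terms are parameters.

What the synthesis does **not** emulate: detector afterpulsing, sweep
nonlinearity, ambient light, shot-noise-exact photon statistics, and
any non-exponential intrinsic decorrelation.  Passing round-trip tests
therefore demonstrates correctness of the estimators and fits under
Gaussian speckle with exponential components — not robustness to every
instrument artifact.

In the tissue-like preset the static component is an IRF-like peak at
the earliest TOF with total diffuse dynamic intensity 1% of the static
peak, reflecting backscattering-geometry dominance of the few-scattered
static return in a single mode.  This dominance is what makes the
peak-TOF trace a clean phase reference; the Doppler-estimation error
floor scales with the dynamic contamination of that bin.

## Motion estimation and correction

Sliding 2 ms windows (hop 1 ms, i.e. 50% overlap — the hop is a free
choice; overlap halves tracking lag) on the TPSF-peak trace (or the
TOF-integrated trace).  Each window's autocorrelation is
lag-normalized (divide by N−m, so a constant phasor gives a constant
autocorrelation); its Doppler frequency is the power-spectrum maximum
after 8× zero-padding with parabolic log-power interpolation, then
refined by a magnitude-weighted pulse-pair (mean lag-to-lag phase
increment) step after demodulation.  The refinement matters: the bare
interpolated peak carries a per-window bias of order 1% of the bin
spacing, which random-walks into a cumulative phase error of more than
a radian over 2.5 s; the phase-slope refinement brings the cumulative
RMS error to ~0.1 rad (a ~λ/100 axial-displacement equivalent) under
the default conditions.  Per-window increments Δθ = 2πΔf·Δτ_d are
branch-corrected into (−π, π], accumulated from θ(0) = 0, interpolated
to the sample grid, and removed as Γ·e^(−iθ).  Conversions:
Z = θλ₀/(4π), ΔV = Δf·λ₀/2.

After correction the intrinsic autocorrelation is taken as the real
part of the estimate (unbiased dynamics give a real G1); the imaginary
part is retained and checked against the noise floor.

## Autocorrelation estimation

Full-block estimates use the biased (divide-by-N) sample
autocovariance per TOF bin — lower variance at long lags at the cost
of an exact (N−m)/N taper, which is < 0.5% for 10 ms lags in a 2.5 s
block.  No mean is subtracted: the static component is part of the
model and is fitted explicitly.  (The short *windowed* autocorrelation
used for Doppler estimation divides by N−m instead, since there the
taper would masquerade as decorrelation over the 2 ms window.)
Confidence intervals, when requested, come from a moving-block
bootstrap over delay time (default 200 resamples, 50 ms blocks) — a
pragmatic choice where no standard method is prescribed.

TOF-dependent averaging replaces G1 at each τ_s by its mean over
[τ_s(1 − f/2), τ_s(1 + f/2)] (default f = 0.2, so 900–1100 ps at
1000 ps), clipped to the grid, recording the bin count.

The heterodyne (modified) Siegert relation implemented for a field
E = A + E_f with static intensity I_c = |A|² and circular Gaussian
dynamic part with autocorrelation G1f:

    G2(τ) = ⟨I⟩² + β[|G1f(τ)|² + 2·I_c·Re G1f(τ)],  ⟨I⟩ = I_c + G1f(0).

For a fully dynamic field this reduces to the classical Siegert form,
doubling the decay rate — hence a 10 μs field lag resolution is
equivalent to 5 μs in intensity.

## Fitting machinery

Trust-region nonlinear least squares (`scipy.optimize.least_squares`,
TRF) with nonnegativity bounds; 8 multi-starts with log-spaced rate
guesses spanning [1/window, 1/lag-step]; best SSE wins, ties go to the
solution found in fewer evaluations.  Parameter CIs from the Jacobian
covariance at the optimum (95%, t-distribution).  Order-5 results are
relabeled so ξ_fast ≥ ξ_slow with amplitude–rate pairing preserved.  A
degenerate bi-exponential — rates within 5%, or one dynamic amplitude
below 10⁻³ of the dynamic total — collapses to the order-3 refit with
a flag, which keeps component-wise TOF integration well defined on
effectively mono-exponential bins.  Non-convergence is flagged on the
result, not raised.

The early-lag fit restricts to the first quarter of the fast 1/e time
from a pilot order-3 fit (the window length is a parameter; no
standard value exists), with a floor of enough lags to constrain the
parameters.

The decay-rate regression is a weighted line fit (inverse CI variance
weights) of the primary rate vs TOF; BFI comes from the slope, and the
TOF-axis intercept τ_s,0 is reported as a diagnostic for superficial
low-flow layers.

## DCS bridge

`integrate_tof` sums G1 over TOF (Δτ_s-weighted); component surfaces
from fits can be integrated instead.  `fit_dcs` fits the normalized
TOF-integrated autocorrelation with the TPSF-weighted diffusing-wave
kernel Σ I(τ_s)·e^(−ξ(τ_s;BFI)τ_d) (decay line through the origin) and
a free amplitude bounded in [0.9, 1.1].  The kernel choice deliberately
uses the measured/modeled TOF distribution rather than a closed-form
correlation-diffusion solution: it is the exact TOF integral of the
per-TOF model and needs no extra geometry assumptions.  Consequence
demonstrated in tests and examples: fitting the full static+slow+fast
integral gives a fit-region-dependent BFI, while integrating the fast
component (or early-lag fits) restores region independence — and an
absorption error in the assumed TPSF biases the TOF-integrated fit,
whereas the TOF-resolved decay-rate regression never touches μ_a.

## Containers, CLI, reproducibility

Single-file HDF5 containers hold complex arrays natively
(`/gamma` at complex64, `/g1`, `/tpsf`, axes, and a JSON manifest with
stage name, SHA-256 config hash over canonical sorted-key JSON, seed,
software and format version, timestamp).  Every CLI stage is
deterministic given (config, seed).  Units at public interfaces: ps for
TOF, s for lag and delay time, cm⁻¹ for optical coefficients, cm²/s
for diffusion/BFI, nm for wavelength; internal conversions are
centralized in one constants module.

## Problem sizes

Defaults in tests and examples were chosen to resolve the physics with
comfortable statistical margin on a single CPU: 3–6×10⁵ photons for
Monte Carlo comparisons (slope agreement is ~0.3% at 6×10⁵, far inside
the 5% criterion), 2.5 s (250,000-point) blocks for synthetic
acquisitions, 22 ps TOF bins mirroring the instrument resolution.

## Known limitations

- Index-matched layer boundaries: no refractive mismatch inside the
  medium or at the surface beyond the extrapolated-boundary reflectance
  of the analytic TPSF.
- The per-event MSD-kernel treatment of advective motion ignores
  correlated (laminar-gradient) displacements between events.
- The empirical 5-parameter model is a description, not a theory, of
  the intermediate regime between single-scattering and diffusing-wave
  limits; the toolkit reproduces its behavior but offers no analytic
  form for that regime.
- Doppler tracking assumes one rigid axial velocity per 2 ms window;
  vibration faster than the window or TOF-dependent motion violates
  the common-phase assumption.
- BFI values scale with the assumed refractive index and μ_s′; neither
  is derivable from the autocorrelation itself (μ_s′ can be fitted
  from the TPSF).
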