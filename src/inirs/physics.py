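"""Closed-form optical physics models.

This module collects the analytic building blocks of TOF-resolved diffuse
optical flowmetry:

* mean-squared displacement (MSD) laws for scatterer motion — Brownian,
  random (ballistic) flow, hydrodynamic diffusion and a hybrid of
  advection and diffusion;
* normalized field autocorrelations in the single-scattering (DLS) and
  diffusing-wave (DWS) regimes;
* the linear relation between the TOF-resolved decay rate and time of
  flight whose slope carries the blood flow index (BFI);
* the time-domain diffusion-approximation reflectance (TPSF) for a
  semi-infinite medium with an extrapolated boundary;
* instrument response function (IRF) models obtained by Fourier
  transforming a spectral apodization window across the laser tuning
  range, and TOF-domain convolution with such an IRF.

Public interfaces use picoseconds for time of flight, seconds for lag
time, cm^-1 for optical coefficients, nm for wavelength and cm^2/s for
diffusion coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._constants import C_CM_S, NM_CM, PS

__all__ = [
    "OpticalProperties",
    "MSDModel",
    "IRFModel",
    "DecayLine",
    "msd",
    "g1_dls",
    "g1_dws",
    "decay_rate_line",
    "bfi_from_slope",
    "tpsf_semi_infinite",
    "irf_profile",
    "gaussian_irf",
    "irf_fwhm",
    "convolve_irf",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, 1/cm.
    mu_s_prime : float
        Reduced scattering coefficient ``mu_s * (1 - g)``, 1/cm.
    g : float
        Scattering anisotropy (mean cosine of the deflection angle).
    n_r : float
        Group refractive index (assumed equal to the phase index).
    lambda0 : float
        Free-space center wavelength, nm.
    mu_s : float, optional
        Scattering coefficient, 1/cm.  If given it must be consistent
        with ``mu_s_prime`` and ``g``.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.0
    n_r: float = 1.33
    lambda0: float = 855.0
    mu_s: float | None = None

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be > 0")
        if not -1 < self.g < 1:
            raise ValueError("|g| must be < 1")
        if self.n_r < 1:
            raise ValueError("n_r must be >= 1")
        if self.mu_s is not None:
            expected = self.mu_s * (1.0 - self.g)
            if not np.isclose(expected, self.mu_s_prime, rtol=1e-9):
                raise ValueError(
                    "inconsistent mu_s: mu_s*(1-g) = "
                    f"{expected} != mu_s_prime = {self.mu_s_prime}"
                )

    @property
    def k(self) -> float:
        """Medium wavenumber ``2*pi*n_r/lambda0`` in 1/cm."""
        return 2.0 * np.pi * self.n_r / (self.lambda0 * NM_CM)

    @property
    def mu_s_from_g(self) -> float:
        """Scattering coefficient implied by mu_s_prime and g, 1/cm."""
        return self.mu_s if self.mu_s is not None else self.mu_s_prime / (1.0 - self.g)


MSDKind = Literal["brownian", "random_flow", "hydrodynamic", "hybrid"]


@dataclass(frozen=True)
class MSDModel:
    """Mean-squared displacement law for dynamic scatterers.

    kind selects the functional form of ``<dr^2(tau_d)>``:

    * ``brownian``:       6 D_B tau_d
    * ``random_flow``:    v^2 tau_d^2
    * ``hydrodynamic``:   6 D_B {tau_d - tau_C [1 - exp(-tau_d/tau_C)]}
    * ``hybrid``:         6 D_B tau_d + v^2 tau_d^2

    D_B in cm^2/s, v in cm/s (standard deviation of the velocity
    distribution), tau_C in s (time scale to establish Brownian motion),
    alpha in [0, 1] is the probability that a scattering event is dynamic.
    """

    kind: MSDKind = "brownian"
    D_B: float = 0.0
    v: float = 0.0
    tau_C: float | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.D_B < 0:
            raise ValueError("D_B must be >= 0")
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.kind == "hydrodynamic" and (self.tau_C is None or self.tau_C <= 0):
            raise ValueError("hydrodynamic model requires tau_C > 0")
        if self.kind not in ("brownian", "random_flow", "hydrodynamic", "hybrid"):
            raise ValueError(f"unknown MSD kind {self.kind!r}")

    def msd(self, tau_d):
        return msd(self, tau_d)


@dataclass(frozen=True)
class IRFModel:
    """Intensity instrument response function on a TOF grid.

    ``profile`` is nonnegative and normalized to unit sum; ``tof_axis``
    (ps) is uniform and contains 0 (the undelayed bin).
    """

    tof_axis: np.ndarray
    profile: np.ndarray
    tuning_range_ghz: float | None = None
    apodization: str | None = None

    def __post_init__(self) -> None:
        tof = np.asarray(self.tof_axis, dtype=float)
        prof = np.asarray(self.profile, dtype=float)
        if tof.shape != prof.shape or tof.ndim != 1:
            raise ValueError("tof_axis and profile must be 1-D of equal length")
        if np.any(prof < -1e-15):
            raise ValueError("IRF profile must be nonnegative")
        s = prof.sum()
        if not np.isclose(s, 1.0, atol=1e-12, rtol=1e-9):
            raise ValueError("IRF profile must sum to 1")
        object.__setattr__(self, "tof_axis", tof)
        object.__setattr__(self, "profile", prof)

    @property
    def origin_index(self) -> int:
        """Index of the TOF = 0 bin."""
        i = int(np.argmin(np.abs(self.tof_axis)))
        if abs(self.tof_axis[i]) > 1e-9:
            raise ValueError("IRF tof_axis does not contain 0")
        return i

    @property
    def fwhm_ps(self) -> float:
        return irf_fwhm(self)


@dataclass(frozen=True)
class DecayLine:
    """Linear decay-rate-vs-TOF relation ``xi(tau_s) = slope*(tau_s - tau_s0)``.

    slope in 1/(s*ps); tau_s0 in ps; bfi = alpha*D_B in cm^2/s.
    """

    slope: float
    tau_s0: float
    bfi: float
    slope_stderr: float = np.nan
    tau_s0_stderr: float = np.nan

    def __post_init__(self) -> None:
        if self.bfi < 0:
            raise ValueError("bfi must be >= 0")


# --------------------------------------------------------------------------
# Mean-squared displacement & autocorrelation models
# --------------------------------------------------------------------------


def msd(model: MSDModel, tau_d):
    """Mean-squared displacement ``<dr^2(tau_d)>`` in cm^2.

    tau_d is a lag time (s), scalar or array, and must be nonnegative.
    """
    tau_d = np.asarray(tau_d, dtype=float)
    if np.any(tau_d < 0):
        raise ValueError("tau_d must be >= 0")
    if model.kind == "brownian":
        out = 6.0 * model.D_B * tau_d
    elif model.kind == "random_flow":
        out = model.v**2 * tau_d**2
    elif model.kind == "hydrodynamic":
        tc = model.tau_C
        out = 6.0 * model.D_B * (tau_d - tc * (-np.expm1(-tau_d / tc)))
    else:  # hybrid
        out = 6.0 * model.D_B * tau_d + model.v**2 * tau_d**2
    return out if out.ndim else float(out)


def g1_dls(eta_c: float, q: float, model: MSDModel, tau_d):
    """Single-scattering (DLS) normalized field autocorrelation.

    ``eta_c + (1 - eta_c) * exp(-q^2 <dr^2(tau_d)> / 6)`` for a fixed
    scattering vector of magnitude ``q`` (1/cm) and static fraction
    ``eta_c``.
    """
    if not 0.0 <= eta_c <= 1.0:
        raise ValueError("eta_c must be in [0, 1]")
    dr2 = msd(model, tau_d)
    return eta_c + (1.0 - eta_c) * np.exp(-(q**2) * np.asarray(dr2) / 6.0)


def g1_dws(tau_s_ps, tau_d, optics: OpticalProperties, model: MSDModel):
    """Diffusing-wave (DWS) normalized TOF-resolved field autocorrelation.

    ``exp[-(1/3) alpha k^2 <dr^2(tau_d)> mu_s' c tau_s / n_r]`` with
    tau_s in ps and tau_d in s.  The path length is ``c tau_s / n_r``.
    Broadcasting over both axes is supported.
    """
    tau_s = np.asarray(tau_s_ps, dtype=float) * PS
    if np.any(tau_s < 0):
        raise ValueError("tau_s must be >= 0")
    dr2 = np.asarray(msd(model, tau_d))
    exponent = (
        (1.0 / 3.0)
        * model.alpha
        * optics.k**2
        * dr2
        * optics.mu_s_prime
        * C_CM_S
        * tau_s
        / optics.n_r
    )
    return np.exp(-exponent)


def decay_rate_line(tau_s_ps, bfi: float, optics: OpticalProperties, tau_s0_ps: float = 0.0):
    """Decay rate ``xi(tau_s)`` (1/s) of the DWS Brownian exponential.

    ``xi = 2 k^2 BFI mu_s' c (tau_s - tau_s0) / n_r`` with TOF arguments
    in ps and BFI = alpha*D_B in cm^2/s.
    """
    tau_s = (np.asarray(tau_s_ps, dtype=float) - tau_s0_ps) * PS
    return 2.0 * optics.k**2 * bfi * optics.mu_s_prime * C_CM_S * tau_s / optics.n_r


def bfi_from_slope(slope_per_s_per_ps: float, optics: OpticalProperties) -> float:
    """BFI (cm^2/s) from the slope of xi vs TOF.

    slope is d(xi)/d(tau_s) in 1/(s*ps); the inverse of
    :func:`decay_rate_line`:
    ``BFI = lambda0^2 * slope / (8 pi^2 n_r mu_s' c)``.
    """
    if optics.mu_s_prime == 0:
        raise ZeroDivisionError("mu_s_prime must be nonzero")
    slope_si = slope_per_s_per_ps / PS  # 1/s per s of TOF
    lam_cm = optics.lambda0 * NM_CM
    return lam_cm**2 * slope_si / (8.0 * np.pi**2 * optics.n_r * optics.mu_s_prime * C_CM_S)


# --------------------------------------------------------------------------
# Time-domain diffusion TPSF
# --------------------------------------------------------------------------


def _boundary_A(n_r: float) -> float:
    # Internal-reflection parameter A = (1 + r_d)/(1 - r_d) with the
    # Groenhuis polynomial approximation of the effective reflection
    # coefficient for an air/medium interface.
    r_d = -1.440 / n_r**2 + 0.710 / n_r + 0.668 + 0.0636 * n_r
    return (1.0 + r_d) / (1.0 - r_d)


def tpsf_semi_infinite(tau_s_ps, rho_cm: float, optics: OpticalProperties):
    """Time-domain diffusion reflectance of a semi-infinite medium.

    Extrapolated-boundary solution with an isotropic point source buried
    at depth ``z0 = 1/mu_s'`` and a negative image source mirrored about
    the extrapolated boundary at ``-z0 - 2*zb`` with
    ``zb = 2*A*D``, ``D = 1/(3*mu_s')`` and A the internal-reflectance
    factor derived from ``n_r``:

        R(rho, t) = (1/2) (4 pi D v)^(-3/2) t^(-5/2)
                    exp(-mu_a v t - rho^2/(4 D v t))
                    [ z0 exp(-z0^2/(4 D v t))
                      + (z0 + 2 zb) exp(-(z0 + 2 zb)^2/(4 D v t)) ]

    with ``v = c/n_r``.  Output in arbitrary units (per unit time and
    area); tau_s in ps, rho in cm.
    """
    tau = np.asarray(tau_s_ps, dtype=float) * PS
    if np.any(tau <= 0):
        raise ValueError("tau_s must be > 0")
    if rho_cm < 0:
        raise ValueError("rho must be >= 0")
    v = C_CM_S / optics.n_r
    D = 1.0 / (3.0 * optics.mu_s_prime)
    z0 = 1.0 / optics.mu_s_prime
    zb = 2.0 * _boundary_A(optics.n_r) * D
    fourDvt = 4.0 * D * v * tau
    pref = 0.5 * (np.pi * fourDvt) ** -1.5 * tau**-1.0
    # (4 pi D v)^{-3/2} t^{-5/2} = (pi * 4 D v t)^{-3/2} / t
    atten = np.exp(-optics.mu_a * v * tau - rho_cm**2 / fourDvt)
    images = z0 * np.exp(-(z0**2) / fourDvt) + (z0 + 2 * zb) * np.exp(
        -((z0 + 2 * zb) ** 2) / fourDvt
    )
    out = pref * atten * images
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Instrument response function
# --------------------------------------------------------------------------

_WINDOWS = {
    "rect": lambda n: np.ones(n),
    "rectangular": lambda n: np.ones(n),
    "hann": lambda n: np.hanning(n),
    "hamming": lambda n: np.hamming(n),
    "blackman": lambda n: np.blackman(n),
}


def irf_profile(
    tuning_range_ghz: float,
    apodization: str = "hann",
    tof_span_ps: float = 400.0,
    tof_step_ps: float = 0.5,
) -> IRFModel:
    """Intensity IRF from a spectral apodization window.

    The optical frequency sweep spans ``tuning_range_ghz``; the intensity
    IRF is the squared magnitude of the Fourier transform of the chosen
    apodization window, evaluated on a symmetric TOF grid of half-width
    ``tof_span_ps`` with spacing ``tof_step_ps`` (<= 1 ps so the FWHM is
    well resolved) and normalized to unit sum.
    """
    if tuning_range_ghz <= 0:
        raise ValueError("tuning_range must be > 0")
    if apodization not in _WINDOWS:
        raise KeyError(
            f"unknown apodization window {apodization!r}; choose from {sorted(_WINDOWS)}"
        )
    dnu = tuning_range_ghz * 1e9  # Hz
    n_half = int(round(tof_span_ps / tof_step_ps))
    tof = np.arange(-n_half, n_half + 1) * tof_step_ps  # ps
    n_win = 4097
    nu = np.linspace(-dnu / 2, dnu / 2, n_win)
    w = _WINDOWS[apodization](n_win)
    # direct DFT onto the requested TOF grid (non-fft: grids are small)
    t_s = tof * PS
    phase = np.exp(-2j * np.pi * np.outer(t_s, nu))
    amp = phase @ w
    prof = np.abs(amp) ** 2
    prof /= prof.sum()
    return IRFModel(tof_axis=tof, profile=prof, tuning_range_ghz=tuning_range_ghz, apodization=apodization)


def gaussian_irf(fwhm_ps: float, tof_span_ps: float = 200.0, tof_step_ps: float = 0.5) -> IRFModel:
    """Gaussian intensity IRF of given FWHM (ps), for idealized studies."""
    if fwhm_ps <= 0:
        raise ValueError("fwhm must be > 0")
    n_half = int(round(tof_span_ps / tof_step_ps))
    tof = np.arange(-n_half, n_half + 1) * tof_step_ps
    sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    prof = np.exp(-0.5 * (tof / sigma) ** 2)
    prof /= prof.sum()
    return IRFModel(tof_axis=tof, profile=prof, apodization="gaussian")


def irf_fwhm(irf: IRFModel) -> float:
    """Full width at half maximum of the IRF (ps).

    Half-maximum crossings are located by linear interpolation between
    grid samples around the global peak.
    """
    prof = irf.profile
    tof = irf.tof_axis
    ipk = int(np.argmax(prof))
    half = prof[ipk] / 2.0

    def _cross(idx_range):
        for i in idx_range:
            lo, hi = sorted((prof[i], prof[i + 1]))
            if lo <= half <= hi and prof[i] != prof[i + 1]:
                frac = (half - prof[i]) / (prof[i + 1] - prof[i])
                return tof[i] + frac * (tof[i + 1] - tof[i])
        raise ValueError("half-maximum crossing not found on grid")

    left = _cross(range(ipk - 1, -1, -1))
    right = _cross(range(ipk, len(prof) - 1))
    fwhm = right - left
    if fwhm <= 0:
        raise ValueError("non-positive FWHM")
    return float(fwhm)


def convolve_irf(curve, curve_tof_ps, irf: IRFModel):
    """Convolve a TOF-domain curve with the intensity IRF.

    Both grids must share the same uniform spacing; the output is the
    discrete linear convolution restricted to the input TOF grid, with
    the IRF's TOF = 0 bin as the convolution origin (so a delta IRF at 0
    is the identity and shifting the IRF shifts the output).
    """
    curve = np.asarray(curve, dtype=float)
    tof = np.asarray(curve_tof_ps, dtype=float)
    dt = np.diff(tof)
    dt_irf = np.diff(irf.tof_axis)
    if not (np.allclose(dt, dt[0]) and np.allclose(dt_irf, dt_irf[0])):
        raise ValueError("TOF grids must be uniform")
    if not np.isclose(dt[0], dt_irf[0], rtol=1e-9):
        raise ValueError(
            f"grid mismatch: curve spacing {dt[0]} ps != IRF spacing {dt_irf[0]} ps"
        )
    full = np.convolve(curve, irf.profile, mode="full")
    start = irf.origin_index
    return full[start : start + curve.size]
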