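"""Direct stochastic synthesis of mutual coherence function time series.

Emulates the measurement object of a swept-source interferometric NIRS
acquisition: a complex mutual coherence function Gamma(tau_s, t_d) on a
TOF x delay-time grid.  Each TOF bin is a sum of

* a static component: a fixed-amplitude phasor with a random but frozen
  phase;
* one or two dynamic speckle components: unit-variance circular complex
  Ornstein-Uhlenbeck (AR(1)) processes whose ensemble autocorrelation
  is exactly ``exp(-xi * tau_d)`` (Gaussian field statistics);
* additive circular complex white noise.

A common bulk-motion phase factor ``exp(i theta_bps(t_d))`` multiplies
all TOF bins (rigid axial motion), so the full motion-estimation and
correction chain can be exercised against known ground truth.

Defaults mirror the acquisition they emulate: 100 kHz sweep rate
(10 us lag resolution), 2.5 s blocks of 250,000 delay-time points,
855 nm center wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from ._constants import UM_CM
from .physics import IRFModel, convolve_irf

__all__ = [
    "AcquisitionConfig",
    "ComponentSpec",
    "MotionTrace",
    "MutualCoherenceSeries",
    "synthesize_motion",
    "synthesize_gamma",
    "blur_with_irf",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition timing and geometry.

    sweep_rate in Hz sets the lag resolution (1/sweep_rate); a block of
    ``block_duration`` seconds holds ``n_time_points`` delay-time
    samples.  lambda0 in nm; alpha_SD is the angle between illumination
    and detection in rad.
    """

    sweep_rate: float = 1e5
    block_duration: float = 2.5
    tof_grid_ps: np.ndarray = field(default_factory=lambda: np.arange(0.0, 1000.0, 22.0))
    lambda0: float = 855.0
    alpha_SD: float = 0.0

    @property
    def lag_resolution(self) -> float:
        return 1.0 / self.sweep_rate

    @property
    def n_time_points(self) -> int:
        return int(round(self.block_duration * self.sweep_rate))

    @property
    def t_d(self) -> np.ndarray:
        return np.arange(self.n_time_points) * self.lag_resolution


@dataclass(frozen=True)
class ComponentSpec:
    """Static/slow/fast component amplitudes and rates per TOF bin.

    Amplitudes are intensities in TPSF units; rates in 1/s.  The
    noise variance per bin is the variance of the additive circular
    complex noise.
    """

    tof_grid_ps: np.ndarray
    static: np.ndarray
    slow: np.ndarray
    xi_slow: np.ndarray
    fast: np.ndarray
    xi_fast: np.ndarray
    noise_var: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.tof_grid_ps).size
        for name in ("static", "slow", "xi_slow", "fast", "xi_fast", "noise_var"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} must match the TOF grid length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "tof_grid_ps", np.asarray(self.tof_grid_ps, dtype=float))

    @classmethod
    def from_arrays(cls, tof_grid_ps, *, static=None, slow=None, xi_slow=None,
                    fast=None, xi_fast=None, noise_var=None) -> "ComponentSpec":
        tof = np.asarray(tof_grid_ps, dtype=float)
        z = np.zeros_like(tof)

        def _a(x):
            return z.copy() if x is None else np.broadcast_to(np.asarray(x, float), tof.shape).copy()

        return cls(tof, _a(static), _a(slow), _a(xi_slow), _a(fast), _a(xi_fast), _a(noise_var))

    def ensemble_g1(self, tau_d) -> np.ndarray:
        """Ground-truth field autocorrelation G1(tau_s, tau_d) of the
        motion-free synthesis (static + two exponentials)."""
        tau_d = np.asarray(tau_d, dtype=float)
        return (
            self.static[:, None]
            + self.slow[:, None] * np.exp(-np.outer(self.xi_slow, tau_d))
            + self.fast[:, None] * np.exp(-np.outer(self.xi_fast, tau_d))
        )


@dataclass(frozen=True)
class MotionTrace:
    """Bulk-motion ground truth / estimate vs delay time.

    t_d (s); axial dz and lateral dx displacement increments per step
    (um); theta_bps: cumulative unwrapped bulk phase (rad, starts at 0);
    dopp_freq: Doppler frequency shift (Hz); velocity: Doppler velocity
    ``dopp_freq * lambda0/2`` (um/s).
    """

    t_d: np.ndarray
    dz_um: np.ndarray
    dx_um: np.ndarray
    theta_bps: np.ndarray
    dopp_freq: np.ndarray
    velocity_um_s: np.ndarray


@dataclass
class MutualCoherenceSeries:
    """Complex mutual coherence function Gamma[tau_s, t_d]."""

    tof_ps: np.ndarray
    t_d: np.ndarray
    gamma: np.ndarray  # (n_tof, n_t) complex
    lambda0: float = 855.0
    alpha_SD: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma.shape != (np.asarray(self.tof_ps).size, np.asarray(self.t_d).size):
            raise ValueError("gamma must be (n_tof, n_time)")
        if not np.all(np.isfinite(self.gamma.real)) or not np.all(np.isfinite(self.gamma.imag)):
            raise ValueError("gamma must be finite")

    @property
    def dtau_d(self) -> float:
        return float(self.t_d[1] - self.t_d[0])


def synthesize_motion(
    velocity_rw_std_um_s: float,
    alpha_SD: float,
    config: AcquisitionConfig,
    seed: int = 0,
    lateral_velocity_rw_std_um_s: float = 0.0,
) -> MotionTrace:
    """Random-walk bulk-motion ground truth.

    The axial velocity performs a random walk with per-step standard
    deviation ``velocity_rw_std_um_s`` (um/s per step); displacement
    increments are ``v * dt``.  The per-step bulk phase increment is

        dtheta = (4 pi / lambda0) * [dz + dz cos(alpha_SD)
                                      + dx sin(alpha_SD)] / 2

    and theta_bps is its cumulative sum (theta_bps[0] = 0).  The
    Doppler frequency is dtheta/(2 pi dt) and the Doppler velocity is
    ``dopp_freq * lambda0 / 2``.
    """
    if velocity_rw_std_um_s < 0:
        raise ValueError("velocity_rw_std must be >= 0")
    rng = np.random.default_rng(seed)
    n = config.n_time_points
    dt = config.lag_resolution
    vz = np.cumsum(rng.normal(0.0, velocity_rw_std_um_s, n))
    vx = (
        np.cumsum(rng.normal(0.0, lateral_velocity_rw_std_um_s, n))
        if lateral_velocity_rw_std_um_s > 0
        else np.zeros(n)
    )
    dz = vz * dt  # um per step
    dx = vx * dt
    lam_um = config.lambda0 * 1e-3
    dtheta = (4.0 * np.pi / lam_um) * (dz + dz * np.cos(alpha_SD) + dx * np.sin(alpha_SD)) / 2.0
    theta = np.concatenate([[0.0], np.cumsum(dtheta[:-1])])
    dopp = dtheta / (2.0 * np.pi * dt)
    vel = dopp * lam_um / 2.0  # um/s
    return MotionTrace(config.t_d, dz, dx, theta, dopp, vel)


def _ar1_complex(xi: float, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance circular complex AR(1) with autocorr exp(-xi*tau).

    Exact recursion u[k+1] = a u[k] + sqrt(1-a^2) w[k], a = exp(-xi dt),
    w circular complex standard normal, u[0] stationary.
    """
    a = np.exp(-xi * dt)
    w = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2.0)
    if a <= 0.0 or xi * dt > 50:
        return w
    scale = np.sqrt(1.0 - a * a)
    # lfilter implements u[k] = scale*w[k] + a*u[k-1]; seed with the
    # stationary distribution via the initial condition.
    u0 = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
    u, _ = lfilter([scale], [1.0, -a], w, zi=np.array([a * u0]))
    return u


def synthesize_gamma(
    components: ComponentSpec,
    motion: MotionTrace | None,
    config: AcquisitionConfig,
    seed: int = 0,
) -> MutualCoherenceSeries:
    """Synthesize the complex mutual coherence series.

    Per TOF bin b:

        Gamma[b, k] = e^{i theta_bps[k]} ( sqrt(I_c) e^{i phi_c}
                       + sqrt(I_slow) u_slow[k] + sqrt(I_fast) u_fast[k] )
                       + noise[k]

    with independent AR(1) processes per bin and component (seeded
    substreams derived from the master seed), so the ensemble field
    autocorrelation of the motion-free part is exactly
    ``I_c + I_slow e^{-xi_slow tau} + I_fast e^{-xi_fast tau}``.
    """
    tof = components.tof_grid_ps
    n = config.n_time_points
    dt = config.lag_resolution
    if motion is not None and motion.theta_bps.size != n:
        raise ValueError("motion trace length must match the acquisition grid")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(tof.size)
    gamma = np.empty((tof.size, n), dtype=complex)
    for b in range(tof.size):
        rng = np.random.default_rng(streams[b])
        phi_c = rng.uniform(0.0, 2.0 * np.pi)
        sig = np.sqrt(components.static[b]) * np.exp(1j * phi_c) * np.ones(n)
        if components.slow[b] > 0:
            sig = sig + np.sqrt(components.slow[b]) * _ar1_complex(
                components.xi_slow[b], n, dt, rng
            )
        if components.fast[b] > 0:
            sig = sig + np.sqrt(components.fast[b]) * _ar1_complex(
                components.xi_fast[b], n, dt, rng
            )
        if components.noise_var[b] > 0:
            sig = sig + np.sqrt(components.noise_var[b] / 2.0) * (
                rng.standard_normal(n) + 1j * rng.standard_normal(n)
            )
        gamma[b] = sig
    if motion is not None:
        gamma *= np.exp(1j * motion.theta_bps)[None, :]
    return MutualCoherenceSeries(
        tof_ps=tof.copy(),
        t_d=config.t_d,
        gamma=gamma,
        lambda0=config.lambda0,
        alpha_SD=config.alpha_SD,
        meta={"seed": seed, "synthesis": "static+AR1 components"},
    )


def blur_with_irf(components: ComponentSpec, irf: IRFModel) -> ComponentSpec:
    """Convolve component amplitude profiles with the intensity IRF.

    Amplitude profiles are convolved on their (fine) TOF grid; decay
    rates are re-assigned as the amplitude-weighted mean of the input
    rates under the IRF kernel, so a spectrally pure component keeps
    its rate exactly.  Total amplitude per component is conserved for a
    unit-sum IRF whose support fits the grid.
    """
    tof = components.tof_grid_ps

    def _conv(a):
        return np.clip(convolve_irf(a, tof, irf), 0.0, None)

    static = _conv(components.static)
    slow = _conv(components.slow)
    fast = _conv(components.fast)
    with np.errstate(invalid="ignore", divide="ignore"):
        xi_slow = np.where(slow > 0, _conv(components.slow * components.xi_slow) / np.where(slow > 0, slow, 1.0), 0.0)
        xi_fast = np.where(fast > 0, _conv(components.fast * components.xi_fast) / np.where(fast > 0, fast, 1.0), 0.0)
    return ComponentSpec(
        tof_grid_ps=tof.copy(),
        static=static,
        slow=slow,
        xi_slow=xi_slow,
        fast=fast,
        xi_fast=xi_fast,
        noise_var=components.noise_var.copy(),
    )
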