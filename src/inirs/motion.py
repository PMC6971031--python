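"""Bulk-motion phase-drift estimation and correction.

Axial sample motion imparts a common phase drift to the mutual
coherence function at all TOFs.  Over a short window (default 2 ms)
the drift is well approximated by a uniform Doppler shift, which shows
up as a rotation of the windowed complex autocorrelation.  The
procedure:

1. take the complex trace at the TPSF-peak TOF (or the TOF-integrated
   trace), window it, and form the lag-normalized sample
   autocorrelation;
2. locate the peak of its power spectrum (zero-padded, refined by
   parabolic interpolation on log power) -> Doppler shift for that
   window;
3. slide the window (default hop 1 ms), accumulate phase increments
   ``2 pi df dt`` per sample, branch-correct, and obtain the
   cumulative unwrapped bulk phase theta_bps;
4. multiply the series by ``exp(-i theta_bps)``.

Conversions: axial shift Z = theta * lambda0/(4 pi), Doppler velocity
dV = df * lambda0/2.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .synth import MotionTrace, MutualCoherenceSeries

__all__ = [
    "window_autocorrelation",
    "doppler_estimate",
    "sliding_doppler",
    "cumulative_phase",
    "estimate_motion",
    "correct",
    "phase_to_displacement",
    "doppler_velocity",
]


def _select_trace(series: MutualCoherenceSeries, tof_select) -> np.ndarray:
    if isinstance(tof_select, str):
        if tof_select == "peak":
            tpsf = np.mean(np.abs(series.gamma) ** 2, axis=1)
            return series.gamma[int(np.argmax(tpsf))]
        if tof_select == "tof_integrated":
            return series.gamma.sum(axis=0)
        raise ValueError(f"unknown tof_select {tof_select!r}")
    idx = int(np.argmin(np.abs(series.tof_ps - float(tof_select))))
    return series.gamma[idx]


def window_autocorrelation(
    series: MutualCoherenceSeries,
    center_t: float,
    window: float = 2e-3,
    tof_select="peak",
    _trace: np.ndarray | None = None,
) -> np.ndarray:
    """Biased sample autocorrelation of a short windowed complex trace.

    Returns G1_w(tau_d) at lags 0..N-1 (lag step = the acquisition lag
    resolution), each lag normalized by its number of products.
    """
    dt = series.dtau_d
    if window < 10 * dt:
        raise ValueError("window must span at least 10 lag-resolution steps")
    trace = _select_trace(series, tof_select) if _trace is None else _trace
    n_w = int(round(window / dt))
    i0 = int(round(center_t / dt)) - n_w // 2
    if i0 < 0 or i0 + n_w > trace.size:
        raise ValueError("window exceeds the data extent")
    x = trace[i0 : i0 + n_w]
    # lag-normalized (unbiased) autocorrelation via FFT, so a constant
    # phasor gives a constant G1_w
    nfft = 2 * n_w
    X = np.fft.fft(x, nfft)
    r = np.fft.ifft(np.abs(X) ** 2)[:n_w] / (n_w - np.arange(n_w))
    return r


def doppler_estimate(G1_w: np.ndarray, dtau_d: float, zero_pad: int = 8) -> float:
    """Doppler frequency (Hz) of the windowed autocorrelation.

    A coarse estimate is the power-spectrum maximum of G1_w
    (zero-padded ``zero_pad`` times, parabolic interpolation on log
    power, ties preferring the lower |frequency|).  The coarse value is
    then refined by the autocorrelation phase slope: after demodulating
    at the coarse frequency, the magnitude-weighted mean lag-to-lag
    phase increment (pulse-pair estimator) gives the sub-bin offset.
    The refinement removes the interpolation bias of the bare spectral
    peak, which otherwise accumulates when windows are summed into a
    cumulative phase.  Bounded by the Nyquist frequency +-1/(2 dtau_d).
    """
    G1_w = np.asarray(G1_w)
    if G1_w.size < 8:
        raise ValueError("need at least 8 lags")
    if not np.any(np.abs(G1_w) > 0):
        raise ValueError("all-zero autocorrelation: Doppler shift undefined")
    n = G1_w.size
    nfft = int(2 ** np.ceil(np.log2(n * zero_pad)))
    spec = np.abs(np.fft.fft(G1_w, nfft)) ** 2
    freqs = np.fft.fftfreq(nfft, dtau_d)
    order = np.argsort(np.abs(freqs), kind="stable")  # lower |f| first on ties
    peak_val = spec.max()
    candidates = order[spec[order] >= peak_val * (1.0 - 1e-12)]
    ipk = int(candidates[0])
    im = (ipk - 1) % nfft
    ip = (ipk + 1) % nfft
    with np.errstate(divide="ignore"):
        y0, y1, y2 = np.log(spec[im]), np.log(spec[ipk]), np.log(spec[ip])
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 or not np.isfinite(denom) else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df_bin = freqs[1] - freqs[0]
    f0 = freqs[ipk] + delta * df_bin
    # phase-slope refinement: weight early lags where coherence is high
    k = max(int(n // 2), 2)
    demod = G1_w[:k] * np.exp(-2j * np.pi * f0 * dtau_d * np.arange(k))
    pair = np.sum(np.abs(demod[1:]) * demod[1:] * np.conj(demod[:-1]))
    if np.abs(pair) > 0:
        f0 = f0 + float(np.angle(pair)) / (2.0 * np.pi * dtau_d)
    nyq = 0.5 / dtau_d
    return float(np.clip(f0, -nyq, nyq))


def sliding_doppler(
    series: MutualCoherenceSeries,
    window: float = 2e-3,
    hop: float = 1e-3,
    tof_select="peak",
):
    """Doppler shift track: (window center times, df estimates)."""
    dt = series.dtau_d
    t_end = series.t_d[-1]
    trace = _select_trace(series, tof_select)
    centers = np.arange(window / 2, t_end - window / 2 + dt / 2, hop)
    df = np.empty(centers.size)
    for i, c in enumerate(centers):
        g = window_autocorrelation(series, c, window, tof_select, _trace=trace)
        df[i] = doppler_estimate(g, dt)
    return centers, df


def cumulative_phase(df_track: np.ndarray, dtau_d: float, n_steps_per_window: int = 1) -> np.ndarray:
    """Accumulate per-window Doppler shifts into an unwrapped phase.

    Each track entry contributes a phase increment ``2 pi df dtau_d``
    per delay-time step over its ``n_steps_per_window`` samples;
    increments are branch-corrected into (-pi, pi] before accumulation.
    theta[0] = 0.
    """
    df_track = np.asarray(df_track, dtype=float)
    if not np.all(np.isfinite(df_track)):
        raise ValueError("Doppler track contains gaps (non-finite values)")
    inc = 2.0 * np.pi * np.repeat(df_track, n_steps_per_window) * dtau_d
    inc = np.mod(inc + np.pi, 2.0 * np.pi) - np.pi
    theta = np.concatenate([[0.0], np.cumsum(inc)])[: inc.size + 1]
    return theta


def estimate_motion(
    series: MutualCoherenceSeries,
    window: float = 2e-3,
    hop: float = 1e-3,
    tof_select="peak",
) -> MotionTrace:
    """Full sliding-window motion estimate on the acquisition grid.

    The windowed Doppler track is interpolated onto the delay-time grid
    (nearest window, constant within a hop), converted to per-sample
    phase increments, and accumulated into theta_bps.
    """
    centers, df = sliding_doppler(series, window, hop, tof_select)
    dt = series.dtau_d
    t_d = series.t_d
    df_per_sample = np.interp(t_d, centers, df)
    inc = 2.0 * np.pi * df_per_sample * dt
    inc = np.mod(inc + np.pi, 2.0 * np.pi) - np.pi
    theta = np.concatenate([[0.0], np.cumsum(inc[:-1])])
    lam_um = series.lambda0 * 1e-3
    vel = df_per_sample * lam_um / 2.0
    return MotionTrace(
        t_d=t_d,
        dz_um=vel * dt,
        dx_um=np.zeros_like(vel),
        theta_bps=theta,
        dopp_freq=df_per_sample,
        velocity_um_s=vel,
    )


def correct(series: MutualCoherenceSeries, theta_bps: np.ndarray) -> MutualCoherenceSeries:
    """Remove the bulk phase: Gamma_corr = Gamma * exp(-i theta_bps).

    The same phase is applied to every TOF bin (rigid axial motion is
    TOF independent).
    """
    theta = np.asarray(theta_bps, dtype=float)
    if theta.size != series.t_d.size:
        raise ValueError("theta_bps must be defined on the delay-time grid")
    out = MutualCoherenceSeries(
        tof_ps=series.tof_ps.copy(),
        t_d=series.t_d.copy(),
        gamma=series.gamma * np.exp(-1j * theta)[None, :],
        lambda0=series.lambda0,
        alpha_SD=series.alpha_SD,
        meta={**series.meta, "motion_corrected": True},
    )
    return out


def phase_to_displacement(theta_bps, lambda0_nm: float):
    """Axial shift Z (um) from cumulative phase: Z = theta * lambda0/(4 pi)."""
    lam_um = lambda0_nm * 1e-3
    return np.asarray(theta_bps, dtype=float) * lam_um / (4.0 * np.pi)


def doppler_velocity(df_hz, lambda0_nm: float):
    """Doppler velocity dV (um/s) from frequency shift: dV = df * lambda0/2."""
    lam_um = lambda0_nm * 1e-3
    return np.asarray(df_hz, dtype=float) * lam_um / 2.0
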