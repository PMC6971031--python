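"""TOF-resolved autocorrelation estimation and Siegert checks.

Estimates the field autocorrelation ``G1(tau_s, tau_d) =
<Gamma*(tau_s, t) Gamma(tau_s, t + tau_d)>`` and the intensity
autocorrelation ``G2`` from a mutual coherence time series.  The
biased (divide-by-N) sample autocovariance is used: it has lower
variance at long lags at the cost of a small bias, and no mean is
subtracted — a static field component is part of the signal model and
is fitted explicitly downstream.

Also provides the TOF-dependent fractional averaging used to extend
the usable TOF range, and the heterodyne (modified) Siegert relation
linking G1 with a static component to the intensity autocorrelation
under Gaussian field statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import MutualCoherenceSeries

__all__ = [
    "TOFResolvedAutocorrelation",
    "estimate_g1",
    "estimate_g2",
    "siegert_predict",
    "tof_dependent_average",
    "bootstrap_ci",
]


@dataclass
class TOFResolvedAutocorrelation:
    """G1 (and optionally G2) on a TOF x lag grid.

    G1 is real after motion correction (``take_real``); the imaginary
    part is retained in ``imag`` for diagnostics.  ``tpsf`` is the
    lag-0 intensity per bin.  ``ci_low``/``ci_high`` hold bootstrap
    confidence bounds when computed.
    """

    tof_ps: np.ndarray
    tau_d: np.ndarray
    G1: np.ndarray  # (n_tof, n_lag), real or complex
    tpsf: np.ndarray
    imag: np.ndarray | None = None
    G2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def g1(self) -> np.ndarray:
        """Per-bin normalized autocorrelation G1/TPSF (g1(tau_s,0)=1)."""
        return self.G1 / self.tpsf[:, None]


def _autocov_biased(x: np.ndarray, n_lag: int) -> np.ndarray:
    """Biased complex autocovariance of each row up to n_lag lags."""
    n = x.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.fft(x, nfft, axis=-1)
    r = np.fft.ifft(np.abs(X) ** 2, axis=-1)[..., :n_lag] / n
    return r


def estimate_g1(
    series: MutualCoherenceSeries,
    tau_d_max: float = 10e-3,
    take_real: bool = True,
) -> TOFResolvedAutocorrelation:
    """TOF-resolved field autocorrelation over the full block.

    The estimator is the biased sample autocovariance per TOF bin.  If
    ``take_real`` the real part is the estimate (valid after motion
    correction, when unbiased dynamics make G1 real) and the imaginary
    part is kept for diagnostics.  The lag-0 slice is the TPSF
    ``mean(|Gamma|^2)``.
    """
    dt = series.dtau_d
    block = series.t_d[-1] - series.t_d[0]
    if tau_d_max > block / 10:
        import warnings

        warnings.warn(
            "tau_d_max exceeds a tenth of the block duration; the "
            "autocorrelation estimator variance grows at long lags",
            stacklevel=2,
        )
    n_lag = min(int(round(tau_d_max / dt)) + 1, series.t_d.size)
    r = _autocov_biased(series.gamma, n_lag)
    tau_d = np.arange(n_lag) * dt
    tpsf = r[:, 0].real
    if take_real:
        return TOFResolvedAutocorrelation(
            tof_ps=series.tof_ps.copy(),
            tau_d=tau_d,
            G1=r.real,
            tpsf=tpsf,
            imag=r.imag,
            meta={"take_real": True, "n_samples": series.t_d.size},
        )
    return TOFResolvedAutocorrelation(
        tof_ps=series.tof_ps.copy(),
        tau_d=tau_d,
        G1=r,
        tpsf=tpsf,
        meta={"take_real": False, "n_samples": series.t_d.size},
    )


def estimate_g2(series: MutualCoherenceSeries, tau_d_max: float = 10e-3) -> TOFResolvedAutocorrelation:
    """TOF-resolved intensity autocorrelation ``<I(t) I(t+tau_d)>``."""
    dt = series.dtau_d
    n_lag = min(int(round(tau_d_max / dt)) + 1, series.t_d.size)
    intens = np.abs(series.gamma) ** 2
    r = _autocov_biased(intens.astype(complex), n_lag).real
    tau_d = np.arange(n_lag) * dt
    tpsf = intens.mean(axis=1)
    return TOFResolvedAutocorrelation(
        tof_ps=series.tof_ps.copy(),
        tau_d=tau_d,
        G1=np.full_like(r, np.nan),
        tpsf=tpsf,
        G2=r,
        meta={"kind": "intensity", "n_samples": series.t_d.size},
    )


def siegert_predict(G1_total: np.ndarray, static_intensity, beta: float = 1.0) -> np.ndarray:
    """Intensity autocorrelation predicted by the heterodyne Siegert
    relation.

    For a field ``E = A + E_f(t)`` with a constant (static) component of
    intensity ``I_c = |A|^2`` and a circular Gaussian dynamic component
    with autocorrelation ``G1f(tau) = G1_total(tau) - I_c``:

        G2(tau) = <I>^2 + beta [ |G1f(tau)|^2 + 2 I_c Re G1f(tau) ]

    with ``<I> = I_c + G1f(0)``.  Row-wise over TOF bins; ``beta`` is
    the coherence factor.
    """
    G1_total = np.asarray(G1_total)
    I_c = np.atleast_1d(np.asarray(static_intensity, dtype=float))
    G1f = G1_total - I_c[:, None]
    mean_I = I_c + G1f[:, 0].real
    return (mean_I**2)[:, None] + beta * (np.abs(G1f) ** 2 + 2.0 * I_c[:, None] * G1f.real)


def tof_dependent_average(
    acf: TOFResolvedAutocorrelation, fraction: float = 0.2
) -> TOFResolvedAutocorrelation:
    """Average G1 over a fractional TOF window around each bin.

    At each tau_s the window is ``[tau_s (1 - fraction/2),
    tau_s (1 + fraction/2)]`` (e.g. 900-1100 ps at 1000 ps for the
    default 20% window), clipped to the grid.  fraction = 0 is the
    identity.  The number of bins averaged is recorded.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    tof = acf.tof_ps
    G1 = acf.G1
    out = np.empty_like(G1)
    tpsf_out = np.empty_like(acf.tpsf)
    n_samples = np.empty(tof.size, dtype=int)
    for i, ts in enumerate(tof):
        lo = ts * (1.0 - fraction / 2.0)
        hi = ts * (1.0 + fraction / 2.0)
        sel = (tof >= lo) & (tof <= hi)
        if not np.any(sel):
            sel = np.zeros_like(sel)
            sel[i] = True
        out[i] = G1[sel].mean(axis=0)
        tpsf_out[i] = acf.tpsf[sel].mean()
        n_samples[i] = int(sel.sum())
    return TOFResolvedAutocorrelation(
        tof_ps=tof.copy(),
        tau_d=acf.tau_d.copy(),
        G1=out,
        tpsf=tpsf_out,
        meta={**acf.meta, "avg_fraction": fraction, "avg_n_samples": n_samples},
    )


def bootstrap_ci(
    series: MutualCoherenceSeries,
    tau_d_max: float = 10e-3,
    n_boot: int = 200,
    block: float = 50e-3,
    level: float = 0.95,
    seed: int = 0,
) -> TOFResolvedAutocorrelation:
    """G1 with moving-block-bootstrap confidence intervals.

    Delay-time blocks of the given length are resampled with
    replacement ``n_boot`` times; per-resample autocorrelations give
    pointwise percentile intervals.
    """
    rng = np.random.default_rng(seed)
    base = estimate_g1(series, tau_d_max)
    dt = series.dtau_d
    blen = max(int(round(block / dt)), base.tau_d.size)
    n = series.t_d.size
    n_blocks = max(n // blen, 1)
    starts_max = n - blen
    samples = np.empty((n_boot,) + base.G1.shape)
    for ib in range(n_boot):
        starts = rng.integers(0, starts_max + 1, n_blocks)
        resampled = np.concatenate(
            [series.gamma[:, s : s + blen] for s in starts], axis=1
        )
        r = _autocov_biased(resampled, base.tau_d.size)
        samples[ib] = r.real
    alpha = (1.0 - level) / 2.0
    base.ci_low = np.quantile(samples, alpha, axis=0)
    base.ci_high = np.quantile(samples, 1.0 - alpha, axis=0)
    return base
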