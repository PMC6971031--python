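"""Decay-model fitting, decay-rate regression, and TPSF optics fitting.

The TOF-resolved field autocorrelation at a single TOF bin is fitted
with nested exponential models:

* 1-parameter: ``exp(-xi tau_d)`` (normalized, late-TOF DWS regime);
* 2-parameter: ``I_f exp(-xi tau_d)``;
* 3-parameter: ``I_c + I_f exp(-xi tau_d)`` (static + dynamic, the
  DLS/DWS-founded model);
* 5-parameter: ``I_c + I_slow exp(-xi_slow tau_d) +
  I_fast exp(-xi_fast tau_d)`` (empirical bi-exponential).

Fits are trust-region nonlinear least squares with nonnegativity
bounds and multi-start initialization over log-spaced rate guesses;
confidence intervals come from the Jacobian covariance at the optimum.
The decay rate vs TOF regression converts the fitted-slope into a
blood flow index, and the TPSF fit recovers absorption and reduced
scattering by forward-convolving the time-domain diffusion solution
with the instrument response function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._constants import PS
from .physics import (
    DecayLine,
    IRFModel,
    OpticalProperties,
    bfi_from_slope,
    convolve_irf,
    tpsf_semi_infinite,
)

__all__ = [
    "DecayFitResult",
    "fit_decay",
    "adjusted_r2",
    "early_lag_fit",
    "decay_rate_regression",
    "fit_tpsf_optics",
]


@dataclass
class DecayFitResult:
    """Result of a single-bin decay fit.

    Amplitudes in TPSF units, rates in 1/s.  For order-5 fits the
    fast/slow labels are assigned by sorting (xi_fast >= xi_slow).
    ``ci`` maps parameter name -> (low, high) 95% bounds.
    """

    order: int
    params: dict
    ci: dict
    adj_r2: float
    fit_window: float
    tof_ps: float = np.nan
    converged: bool = True
    degenerate: bool = False
    sse: float = np.nan

    @property
    def xi(self) -> float:
        """Primary decay rate: xi for orders 1-3, xi_fast for order 5."""
        return self.params["xi_fast"] if self.order == 5 else self.params["xi"]

    @property
    def xi_stderr(self) -> float:
        key = "xi_fast" if self.order == 5 else "xi"
        lo, hi = self.ci[key]
        return (hi - lo) / (2.0 * 1.959963984540054)


def adjusted_r2(residuals: np.ndarray, y: np.ndarray, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    residuals = np.asarray(residuals, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= p + 1:
        raise ValueError("need n > p + 1 data points")
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _model(order: int):
    if order == 1:
        names = ["xi"]

        def f(t, p):
            return np.exp(-p[0] * t)

    elif order == 2:
        names = ["I_f", "xi"]

        def f(t, p):
            return p[0] * np.exp(-p[1] * t)

    elif order == 3:
        names = ["I_c", "I_f", "xi"]

        def f(t, p):
            return p[0] + p[1] * np.exp(-p[2] * t)

    elif order == 5:
        names = ["I_c", "I_slow", "xi_slow", "I_fast", "xi_fast"]

        def f(t, p):
            return p[0] + p[1] * np.exp(-p[2] * t) + p[3] * np.exp(-p[4] * t)

    else:
        raise ValueError("model order must be one of 1, 2, 3, 5")
    return names, f


def _ci_from_jacobian(res, names, n) -> dict:
    p = len(res.x)
    dof = max(n - p, 1)
    sse = float(2 * res.cost)
    s2 = sse / dof
    JtJ = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(JtJ) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tval = stats.t.ppf(0.975, dof)
    return {nm: (res.x[i] - tval * se[i], res.x[i] + tval * se[i]) for i, nm in enumerate(names)}


def fit_decay(
    tau_d: np.ndarray,
    g1: np.ndarray,
    order: int = 3,
    fit_window: float = 10e-3,
    tof_ps: float = np.nan,
    n_starts: int = 8,
) -> DecayFitResult:
    """Fit one TOF bin's autocorrelation with the selected decay model.

    Lags within ``fit_window`` are used.  Rates are multi-started on a
    log grid spanning [1/window, 1/lag-step]; amplitudes start from
    linear estimates.  Components that decorrelate on scales much
    longer than the window are absorbed by the static term.
    Non-convergence is flagged on the result rather than raised.
    """
    tau_d = np.asarray(tau_d, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    sel = tau_d <= fit_window
    t = tau_d[sel]
    y = g1[sel]
    names, f = _model(order)
    p_count = len(names)
    if t.size < 3 * p_count:
        raise ValueError("need at least 3x the parameter count of lags in the window")
    dt = np.median(np.diff(t))
    rate_lo, rate_hi = 1.0 / fit_window, 1.0 / dt
    rate_starts = np.geomspace(rate_lo, rate_hi, n_starts)
    amp = max(float(y[0]), 1e-30)
    base = max(float(y[-1]), 0.0)

    def starts():
        for r in rate_starts:
            if order == 1:
                yield np.array([r])
            elif order == 2:
                yield np.array([amp, r])
            elif order == 3:
                yield np.array([base, max(amp - base, 1e-3 * amp), r])
            else:
                yield np.array(
                    [base, 0.3 * max(amp - base, 1e-3 * amp), r / 10.0,
                     0.7 * max(amp - base, 1e-3 * amp), r]
                )

    lb = np.zeros(p_count)
    ub = np.full(p_count, np.inf)
    best = None
    for x0 in starts():
        try:
            res = optimize.least_squares(
                lambda p: f(t, p) - y, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-30 or (
            np.isclose(res.cost, best.cost) and res.nfev < best.nfev
        ):
            best = res
    if best is None or not best.success:
        return DecayFitResult(
            order=order,
            params=dict(zip(names, best.x if best is not None else [np.nan] * p_count)),
            ci={nm: (np.nan, np.nan) for nm in names},
            adj_r2=np.nan,
            fit_window=fit_window,
            tof_ps=tof_ps,
            converged=False,
        )
    ci = _ci_from_jacobian(best, names, t.size)
    x = best.x.copy()
    degenerate = False
    if order == 5 and x[4] < x[2]:
        # enforce the xi_fast >= xi_slow labeling by swapping the
        # (amplitude, rate) pairs, keeping pairing intact
        x = np.array([x[0], x[3], x[4], x[1], x[2]])
        ci = {
            "I_c": ci["I_c"],
            "I_slow": ci["I_fast"],
            "xi_slow": ci["xi_fast"],
            "I_fast": ci["I_slow"],
            "xi_fast": ci["xi_slow"],
        }
    if order == 5:
        xs, xf = x[2], x[4]
        amp_tot = x[1] + x[3]
        rates_close = xf > 0 and abs(xf - xs) <= 0.05 * xf
        amp_negligible = amp_tot > 0 and min(x[1], x[3]) < 1e-3 * amp_tot
        if rates_close or amp_negligible:
            # effectively mono-exponential: collapse to the order-3
            # result, relabeling the dynamic term as the fast component
            f3 = fit_decay(tau_d, g1, 3, fit_window, tof_ps, n_starts)
            params = {
                "I_c": f3.params["I_c"],
                "I_slow": 0.0,
                "xi_slow": 0.0,
                "I_fast": f3.params["I_f"],
                "xi_fast": f3.params["xi"],
            }
            ci5 = {
                "I_c": f3.ci["I_c"],
                "I_slow": (0.0, 0.0),
                "xi_slow": (0.0, 0.0),
                "I_fast": f3.ci["I_f"],
                "xi_fast": f3.ci["xi"],
            }
            return DecayFitResult(
                order=5, params=params, ci=ci5, adj_r2=f3.adj_r2,
                fit_window=fit_window, tof_ps=tof_ps, converged=f3.converged,
                degenerate=True, sse=f3.sse,
            )
    resid = f(t, x) - y
    return DecayFitResult(
        order=order,
        params=dict(zip(names, x)),
        ci=ci,
        adj_r2=adjusted_r2(resid, y, p_count),
        fit_window=fit_window,
        tof_ps=tof_ps,
        degenerate=degenerate,
        sse=float(np.sum(resid**2)),
    )


def early_lag_fit(
    tau_d: np.ndarray,
    g1: np.ndarray,
    order: int = 3,
    lag_window: float | None = None,
    fit_window: float = 10e-3,
    tof_ps: float = np.nan,
    early_fraction: float = 0.25,
) -> DecayFitResult:
    """Restrict the fit to early lags where the cumulant expansion holds.

    If ``lag_window`` is not given, a pilot full-window order-3 fit
    estimates the fast 1/e time and the early window is
    ``early_fraction`` of it (clipped to at least 8 lag steps).
    """
    tau_d = np.asarray(tau_d, dtype=float)
    auto = lag_window is None
    if auto:
        pilot = fit_decay(tau_d, g1, 3, fit_window, tof_ps)
        xi = max(pilot.params["xi"], 1.0 / fit_window)
        lag_window = early_fraction / xi
    dt = np.median(np.diff(tau_d))
    lag_window = max(lag_window, (3 * len(_model(order)[0]) + 1) * dt)
    if auto:
        # a pilot-derived window is clamped to the available lags
        lag_window = min(lag_window, float(tau_d[-1]))
    else:
        if lag_window >= fit_window:
            raise ValueError("early-lag window must be shorter than the full window")
        if lag_window > tau_d[-1]:
            raise ValueError("early-lag window exceeds the available lags")
    return fit_decay(tau_d, g1, order, lag_window, tof_ps)


def decay_rate_regression(
    fits: list[DecayFitResult],
    optics: OpticalProperties,
    tof_range_ps: tuple[float, float] | None = None,
) -> DecayLine:
    """Weighted line fit of decay rate vs TOF -> slope, intercept, BFI.

    Uses the primary rate (xi, or xi_fast for order-5 fits) of each
    converged fit, weighted by inverse CI variance when available.
    Reports the TOF-axis intercept tau_s0 and the blood flow index
    from the slope.
    """
    pts = [
        f
        for f in fits
        if f.converged and np.isfinite(f.xi) and np.isfinite(f.tof_ps)
        and (
            tof_range_ps is None
            or (tof_range_ps[0] <= f.tof_ps <= tof_range_ps[1])
        )
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 converged fits in the TOF range")
    x = np.array([f.tof_ps for f in pts])
    y = np.array([f.xi for f in pts])
    se = np.array([f.xi_stderr for f in pts])
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(y)
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    # standard errors of the weighted regression
    resid = y - (intercept + slope * x)
    dof = max(len(pts) - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    slope_se = np.sqrt(s2 / sxx)
    tau_s0 = -intercept / slope if slope != 0 else np.nan
    tau_s0_se = (
        abs(tau_s0) * np.sqrt((slope_se / slope) ** 2 + s2 * (1.0 / W + xm**2 / sxx) / intercept**2)
        if slope != 0 and intercept != 0
        else np.nan
    )
    bfi = bfi_from_slope(max(slope, 0.0), optics)
    return DecayLine(
        slope=slope, tau_s0=tau_s0, bfi=bfi, slope_stderr=slope_se, tau_s0_stderr=tau_s0_se
    )


def fit_tpsf_optics(
    tof_ps: np.ndarray,
    tpsf: np.ndarray,
    irf: IRFModel,
    rho_cm: float,
    optics_init: OpticalProperties,
    fit_range_ps: tuple[float, float] | None = None,
    snr_floor: float = 1e-4,
) -> tuple[OpticalProperties, dict]:
    """Recover (mu_a, mu_s') by fitting the IRF-convolved diffusion TPSF.

    The forward model is ``A * [tpsf_semi_infinite(tau - t0) * IRF]``
    with free amplitude A and TOF offset t0.  The fit region starts at
    100 ps by default (diffusion-approximation validity) and ends where
    the TPSF falls below ``snr_floor`` of its peak.  Returns the
    recovered optics and a diagnostics dict (converged flag, adjusted
    R^2 in log space, the fitted amplitude and offset).
    """
    tof_ps = np.asarray(tof_ps, dtype=float)
    tpsf = np.asarray(tpsf, dtype=float)
    if fit_range_ps is None:
        peak = tpsf.max()
        hi_candidates = tof_ps[tpsf > snr_floor * peak]
        fit_range_ps = (100.0, float(hi_candidates.max()))
    sel = (tof_ps >= fit_range_ps[0]) & (tof_ps <= fit_range_ps[1])
    if not np.any(tpsf[sel] > 0):
        raise ValueError("TPSF must be positive over the fit range")
    t_fit = tof_ps[sel]
    y_fit = tpsf[sel]
    dt = np.median(np.diff(tof_ps))
    # forward model grid: cover fit range plus IRF support
    pad = irf.tof_axis[-1] - irf.tof_axis[0]
    grid = np.arange(max(dt, tof_ps[0] - pad), tof_ps[-1] + pad + dt, dt)

    def forward(mu_a, mu_sp, t0):
        curve = tpsf_semi_infinite(
            np.clip(grid, dt * 1e-3, None),
            rho_cm,
            OpticalProperties(
                mu_a=mu_a, mu_s_prime=mu_sp, n_r=optics_init.n_r, lambda0=optics_init.lambda0
            ),
        )
        blurred = convolve_irf(curve, grid, irf)
        return np.interp(t_fit - t0, grid, blurred)

    ylog = np.log(np.clip(y_fit, 1e-300, None))

    def resid(p):
        la, lsp, log_amp, t0 = p
        model = forward(np.exp(la), np.exp(lsp), t0)
        return np.log(np.clip(model, 1e-300, None)) + log_amp - ylog

    x0 = np.array([np.log(max(optics_init.mu_a, 1e-4)), np.log(optics_init.mu_s_prime), 0.0, 0.0])
    # rough amplitude init by matching peaks
    m0 = forward(np.exp(x0[0]), np.exp(x0[1]), 0.0)
    x0[2] = float(np.log(y_fit.max() / m0.max()))
    res = optimize.least_squares(resid, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu_a = float(np.exp(res.x[0]))
    mu_sp = float(np.exp(res.x[1]))
    out = OpticalProperties(
        mu_a=mu_a, mu_s_prime=mu_sp, n_r=optics_init.n_r, lambda0=optics_init.lambda0
    )
    diag = {
        "converged": bool(res.success),
        "adj_r2_log": adjusted_r2(res.fun, ylog, 4),
        "amplitude": float(np.exp(res.x[2])),
        "tof_offset_ps": float(res.x[3]),
        "fit_range_ps": fit_range_ps,
        "n_points": int(t_fit.size),
    }
    return out, diag
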