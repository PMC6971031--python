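"""Correlation-transport Monte Carlo in layered turbid media.

Photon random walks are simulated in a stack of index-matched plane
layers.  Each scattering event is either *dynamic* (moving scatterer,
e.g. a red blood cell) with per-layer probability ``dynamic_fraction``,
or *static* (tissue matrix).  Dynamic events record their squared
momentum transfer ``q^2 = 2 k^2 (1 - cos theta)``; under the
independent-scatterer assumption a path's field decorrelation is the
product of per-event factors ``exp(-q_i^2 <dr^2(tau_d)>/6)``, so the
per-layer sum of ``q_i^2`` is a sufficient statistic.  Binning paths by
time of flight yields the TOF-resolved field autocorrelation
``G1(tau_s, tau_d)`` and the TPSF without any diffusion-approximation
assumption.

Simplifications (documented design choices): layers are index matched
(no refraction or Fresnel reflection at internal boundaries), photons
launch as a pencil beam normal to the surface, detection is through the
top surface within a circular aperture and acceptance cone, and total
internal reflection at the top surface is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from ._constants import C_CM_S, PS
from .physics import MSDModel, OpticalProperties, msd

__all__ = [
    "MediumLayer",
    "DetectionGeometry",
    "PhotonPathEnsemble",
    "simulate_paths",
    "autocorrelation_from_paths",
    "filter_paths",
    "phase_function_variants",
    "HenyeyGreensteinSampler",
    "TwoTermHGSampler",
]

# Russian-roulette threshold and survival probability.
_WEIGHT_CUTOFF = 1e-6
_ROULETTE_SURVIVE = 0.1


@dataclass(frozen=True)
class MediumLayer:
    """One plane layer of the medium.

    thickness in cm (np.inf allowed for the last layer); optics carries
    mu_a, mu_s_prime, n_r, lambda0.  The scattering coefficient used for
    free-path sampling is derived from mu_s_prime and the composite
    anisotropy ``g = f*g_dynamic + (1-f)*g_static`` with
    ``f = dynamic_fraction``.  Dynamic events deflect with anisotropy
    g_dynamic, static events with g_static.
    """

    thickness: float
    optics: OpticalProperties
    dynamic_fraction: float = 0.0
    g_dynamic: float = 0.0
    g_static: float = 0.0
    msd_model: MSDModel | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        if not 0.0 <= self.dynamic_fraction <= 1.0:
            raise ValueError("dynamic_fraction must be in [0, 1]")
        for g in (self.g_dynamic, self.g_static):
            if not -1.0 < g < 1.0:
                raise ValueError("anisotropies must satisfy |g| < 1")

    @property
    def g_composite(self) -> float:
        f = self.dynamic_fraction
        return f * self.g_dynamic + (1.0 - f) * self.g_static

    @property
    def mu_s(self) -> float:
        """Scattering coefficient (1/cm) from mu_s' and the composite g."""
        return self.optics.mu_s_prime / (1.0 - self.g_composite)


@dataclass(frozen=True)
class DetectionGeometry:
    """Surface detection aperture.

    rho: source-detector separation in cm (0 = null SD separation);
    radius: detector radius in cm; acceptance: half-angle in rad.
    """

    rho: float = 0.0
    radius: float = 0.1
    acceptance: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.radius <= 0:
            raise ValueError("detector radius must be > 0")
        if not 0.0 < self.acceptance <= np.pi / 2:
            raise ValueError("acceptance must be in (0, pi/2]")


@dataclass
class PhotonPathEnsemble:
    """Sufficient statistics of detected photon paths.

    Arrays indexed by detected path: tof_ps, exit weight, per-layer
    squared-momentum-transfer sums (n_paths x n_layers, units 1/cm^2),
    per-layer geometric path length (cm), number of dynamic events and
    the maximum dynamic deflection angle (rad; 0 if no dynamic event).
    """

    tof_ps: np.ndarray
    weight: np.ndarray
    q2_sum: np.ndarray
    path_length: np.ndarray
    n_dynamic: np.ndarray
    max_dynamic_angle: np.ndarray
    n_launched: int
    seed: int | None = None
    layers: tuple = ()

    def __len__(self) -> int:
        return self.tof_ps.size


# --------------------------------------------------------------------------
# Phase-function samplers
# --------------------------------------------------------------------------


@njit(cache=True)
def _sample_hg(g: float, u: float) -> float:
    """Inverse-CDF sample of cos(theta) from the Henyey-Greenstein law."""
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - s * s) / (2.0 * g)


class HenyeyGreensteinSampler:
    """Henyey-Greenstein angular sampler with mean cosine g."""

    def __init__(self, g: float):
        if not -1.0 < g < 1.0:
            raise ValueError("|g| must be < 1")
        self.g = g

    @property
    def mean_cosine(self) -> float:
        return self.g

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        if abs(self.g) < 1e-8:
            return 2.0 * u - 1.0
        s = (1.0 - self.g**2) / (1.0 - self.g + 2.0 * self.g * u)
        return (1.0 + self.g**2 - s**2) / (2.0 * self.g)


class TwoTermHGSampler:
    """Mixture of a forward and a backward Henyey-Greenstein lobe.

    cos(theta) ~ w * HG(g_forward) + (1 - w) * HG(g_backward); the
    analytic mean cosine is ``w*g_forward + (1-w)*g_backward``.
    """

    def __init__(self, g_forward: float, g_backward: float, weight: float):
        for g in (g_forward, g_backward):
            if not -1.0 < g < 1.0:
                raise ValueError("|g| must be < 1")
        if not 0.0 <= weight <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")
        self.g_forward = g_forward
        self.g_backward = g_backward
        self.weight = weight

    @property
    def mean_cosine(self) -> float:
        return self.weight * self.g_forward + (1.0 - self.weight) * self.g_backward

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pick = rng.random(n) < self.weight
        out = np.empty(n)
        fwd = HenyeyGreensteinSampler(self.g_forward)
        bwd = HenyeyGreensteinSampler(self.g_backward)
        nf = int(pick.sum())
        out[pick] = fwd.sample(nf, rng)
        out[~pick] = bwd.sample(n - nf, rng)
        return out


def phase_function_variants(kind: str, g: float, **params):
    """Factory for angular samplers.

    kind = 'henyey_greenstein' (param g) or 'two_term_hg'
    (params g, g_backward, weight).
    """
    if kind == "henyey_greenstein":
        return HenyeyGreensteinSampler(g)
    if kind == "two_term_hg":
        return TwoTermHGSampler(g, params["g_backward"], params["weight"])
    raise ValueError(f"unknown phase function kind {kind!r}")


# --------------------------------------------------------------------------
# Core random walk (numba kernel)
# --------------------------------------------------------------------------


@njit(cache=True)
def _walk_kernel(
    n_photons,
    seed,
    z_bounds,  # (L+1,) cumulative layer boundaries, z_bounds[0] = 0
    mu_a,
    mu_s,
    dyn_frac,
    g_dyn,
    g_stat,
    k_med,
    n_r,
    det_rho,
    det_radius,
    det_cos_accept,
    max_tof_s,
    out_tof,
    out_weight,
    out_q2,
    out_plen,
    out_ndyn,
    out_maxang,
):
    np.random.seed(seed)
    L = mu_s.size
    n_det = 0
    max_path_cm = max_tof_s * C_CM_S / n_r
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 1e-12
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        layer = 0
        total_len = 0.0
        ndyn = 0
        maxang = 0.0
        q2 = np.zeros(L)
        plen = np.zeros(L)
        alive = True
        detected = False
        while alive:
            tau_opt = -np.log(np.random.random())
            # consume optical depth across layer boundaries
            while True:
                step = tau_opt / mu_s[layer]
                # distance to layer boundary along uz
                if uz > 1e-12:
                    d_b = (z_bounds[layer + 1] - z) / uz
                elif uz < -1e-12:
                    d_b = (z_bounds[layer] - z) / uz
                else:
                    d_b = 1e30
                if step < d_b:
                    # scatter inside this layer
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    w *= np.exp(-mu_a[layer] * step)
                    plen[layer] += step
                    total_len += step
                    break
                # cross boundary (or exit)
                x += ux * d_b
                y += uy * d_b
                z += uz * d_b
                w *= np.exp(-mu_a[layer] * d_b)
                plen[layer] += d_b
                total_len += d_b
                tau_opt -= mu_s[layer] * d_b
                if uz < 0.0 and layer == 0:
                    # exits top surface
                    alive = False
                    r = np.sqrt((x - det_rho) ** 2 + y * y)
                    if r <= det_radius and (-uz) >= det_cos_accept:
                        detected = True
                    break
                # reposition just inside the new layer (index matched)
                layer += 1 if uz > 0.0 else -1
                if uz > 0.0:
                    z = z_bounds[layer] + 1e-12
                else:
                    z = z_bounds[layer + 1] - 1e-12
            if not alive:
                break
            if total_len > max_path_cm:
                break
            # choose event type and deflect
            dynamic = np.random.random() < dyn_frac[layer]
            g = g_dyn[layer] if dynamic else g_stat[layer]
            ct = _sample_hg(g, np.random.random())
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            cp = np.cos(phi)
            sp = np.sin(phi)
            if abs(uz) > 0.99999:
                nx = st * cp
                ny = st * sp
                nz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
                ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nz = -st * cp * den + uz * ct
            ux, uy, uz = nx, ny, nz
            if dynamic:
                ndyn += 1
                q2[layer] += 2.0 * k_med * k_med * (1.0 - ct)
                ang = np.arccos(ct)
                if ang > maxang:
                    maxang = ang
            # roulette
            if w < _WEIGHT_CUTOFF:
                if np.random.random() < _ROULETTE_SURVIVE:
                    w /= _ROULETTE_SURVIVE
                else:
                    break
        if detected:
            tof_s = total_len * n_r / C_CM_S
            if tof_s <= max_tof_s:
                out_tof[n_det] = tof_s / PS
                out_weight[n_det] = w
                for l in range(L):
                    out_q2[n_det, l] = q2[l]
                    out_plen[n_det, l] = plen[l]
                out_ndyn[n_det] = ndyn
                out_maxang[n_det] = maxang
                n_det += 1
    return n_det


def simulate_paths(
    layers: Sequence[MediumLayer],
    geometry: DetectionGeometry,
    n_photons: int,
    seed: int = 0,
    max_tof_ps: float = 2000.0,
) -> PhotonPathEnsemble:
    """Run the layered correlation-transport random walk.

    Free paths are exponential with the current layer's mu_s; each
    scattering event is dynamic with probability ``dynamic_fraction``
    and deflects by Henyey-Greenstein with the event-type anisotropy;
    dynamic events accumulate ``q^2 = 2 k^2 (1 - cos theta)`` per layer.
    Absorption attenuates the path weight continuously.  Paths are kept
    when they exit the top surface inside the detection aperture.
    Reproducible for a fixed seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not layers:
        raise ValueError("at least one layer required")
    n_r = layers[0].optics.n_r
    lam = layers[0].optics.lambda0
    for ly in layers:
        if not np.isclose(ly.optics.n_r, n_r):
            raise ValueError("layers must share n_r (index matched)")
        if not np.isclose(ly.optics.lambda0, lam):
            raise ValueError("layers must share lambda0")
    L = len(layers)
    z_bounds = np.zeros(L + 1)
    for i, ly in enumerate(layers):
        z_bounds[i + 1] = z_bounds[i] + min(ly.thickness, 1e6)
    mu_a = np.array([ly.optics.mu_a for ly in layers])
    mu_s = np.array([ly.mu_s for ly in layers])
    dyn = np.array([ly.dynamic_fraction for ly in layers])
    g_d = np.array([ly.g_dynamic for ly in layers])
    g_s = np.array([ly.g_static for ly in layers])
    k_med = layers[0].optics.k

    out_tof = np.empty(n_photons)
    out_weight = np.empty(n_photons)
    out_q2 = np.empty((n_photons, L))
    out_plen = np.empty((n_photons, L))
    out_ndyn = np.empty(n_photons, dtype=np.int64)
    out_maxang = np.empty(n_photons)
    n_det = _walk_kernel(
        n_photons,
        seed,
        z_bounds,
        mu_a,
        mu_s,
        dyn,
        g_d,
        g_s,
        k_med,
        n_r,
        geometry.rho,
        geometry.radius,
        np.cos(geometry.acceptance),
        max_tof_ps * PS,
        out_tof,
        out_weight,
        out_q2,
        out_plen,
        out_ndyn,
        out_maxang,
    )
    return PhotonPathEnsemble(
        tof_ps=out_tof[:n_det].copy(),
        weight=out_weight[:n_det].copy(),
        q2_sum=out_q2[:n_det].copy(),
        path_length=out_plen[:n_det].copy(),
        n_dynamic=out_ndyn[:n_det].copy(),
        max_dynamic_angle=out_maxang[:n_det].copy(),
        n_launched=n_photons,
        seed=seed,
        layers=tuple(layers),
    )


# --------------------------------------------------------------------------
# TOF-binned autocorrelation from path statistics
# --------------------------------------------------------------------------


def autocorrelation_from_paths(
    ensemble: PhotonPathEnsemble,
    msd_models: Sequence[MSDModel],
    tau_d: np.ndarray,
    tof_bin_edges: np.ndarray,
):
    """Bin paths in TOF and evaluate G1(tau_s, tau_d) and the TPSF.

    Each path contributes ``w * prod_l exp(-q2_sum[l] * <dr^2>_l / 6)``;
    G1 in a bin is the weighted sum of these factors so that
    ``G1(tau_s, 0)`` equals the binned TPSF exactly.  Returns
    ``(tof_centers_ps, G1[nbin, nlag], tpsf[nbin])`` with NaN rows for
    empty bins.
    """
    tau_d = np.asarray(tau_d, dtype=float)
    edges = np.asarray(tof_bin_edges, dtype=float)
    if edges[0] > ensemble.tof_ps.min() or edges[-1] < ensemble.tof_ps.max():
        raise ValueError("tof_bin_edges must cover the ensemble TOF range")
    L = ensemble.q2_sum.shape[1]
    if len(msd_models) != L:
        raise ValueError("need one MSD model per layer")
    # per-layer MSD on the lag grid: (L, M)
    dr2 = np.stack([np.asarray(msd(m, tau_d)) for m in msd_models])
    # path decay exponents: (n, M)
    expo = ensemble.q2_sum @ dr2 / 6.0
    factors = np.exp(-expo)  # (n, M)
    nbin = edges.size - 1
    idx = np.clip(np.digitize(ensemble.tof_ps, edges) - 1, 0, nbin - 1)
    w = ensemble.weight
    tpsf = np.bincount(idx, weights=w, minlength=nbin)
    G1 = np.empty((nbin, tau_d.size))
    for m in range(tau_d.size):
        G1[:, m] = np.bincount(idx, weights=w * factors[:, m], minlength=nbin)
    empty = tpsf == 0
    G1[empty, :] = np.nan
    tpsf = tpsf.astype(float)
    tpsf[empty] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, G1, tpsf


def filter_paths(ensemble: PhotonPathEnsemble, max_dynamic_angle: float) -> PhotonPathEnsemble:
    """Keep only paths whose every dynamic deflection is <= the threshold.

    Paths with no dynamic events are always retained; static deflections
    are unrestricted.  Threshold pi is the identity.
    """
    if not 0.0 <= max_dynamic_angle <= np.pi:
        raise ValueError("max_dynamic_angle must be in [0, pi]")
    keep = ensemble.max_dynamic_angle <= max_dynamic_angle
    return PhotonPathEnsemble(
        tof_ps=ensemble.tof_ps[keep],
        weight=ensemble.weight[keep],
        q2_sum=ensemble.q2_sum[keep],
        path_length=ensemble.path_length[keep],
        n_dynamic=ensemble.n_dynamic[keep],
        max_dynamic_angle=ensemble.max_dynamic_angle[keep],
        n_launched=ensemble.n_launched,
        seed=ensemble.seed,
        layers=ensemble.layers,
    )
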