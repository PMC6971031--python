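"""HDF5 container format, run manifests, and fixture presets.

Every pipeline stage reads and writes a single-file hierarchical
container.  Layout (datasets present depend on the stored object):

    /gamma            complex64 [n_tof x n_time]   mutual coherence
    /g1, /g2          float/complex [n_tof x n_lag] autocorrelations
    /tpsf             float [n_tof]
    /paths/*          Monte Carlo path statistics
    /axes/tof_ps, /axes/taud_s, /axes/td_s
    /manifest         JSON string: stage, config hash, seed, software
                      version, timestamp, input identities

Complex arrays are stored natively.  The config hash is a SHA-256 of
the canonical (sorted-key) JSON encoding, so it is stable under key
reordering.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .autocorr import TOFResolvedAutocorrelation
from .montecarlo import PhotonPathEnsemble
from .synth import MutualCoherenceSeries

__all__ = [
    "SchemaError",
    "intralipid_components",
    "forearm_components",
    "config_hash",
    "make_manifest",
    "write_container",
    "read_container",
    "make_fixture",
    "PRESETS",
]

_FORMAT_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when a container is missing datasets or has a bad version."""


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON encoding (sorted keys)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o).__name__)

    blob = json.dumps(config, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def make_manifest(stage: str, config: dict | None = None, seed: int | None = None,
                  inputs: list[str] | None = None) -> dict:
    return {
        "stage": stage,
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "inputs": inputs or [],
        "software_version": __version__,
        "format_version": _FORMAT_VERSION,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def _write_manifest(f: h5py.File, manifest: dict | None) -> None:
    f.create_dataset("manifest", data=json.dumps(manifest or {}))
    f.attrs["format_version"] = _FORMAT_VERSION


def _read_manifest(f: h5py.File) -> dict:
    if "manifest" not in f:
        raise SchemaError("missing dataset: manifest")
    ver = f.attrs.get("format_version")
    if ver != _FORMAT_VERSION:
        raise SchemaError(f"unsupported container format version {ver!r}")
    return json.loads(f["manifest"][()])


def write_container(obj, path, manifest: dict | None = None) -> None:
    """Write a typed object to an HDF5 container (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ax = f.create_group("axes")
        if isinstance(obj, MutualCoherenceSeries):
            f.attrs["kind"] = "gamma"
            f.create_dataset("gamma", data=obj.gamma.astype(np.complex64))
            ax.create_dataset("tof_ps", data=obj.tof_ps)
            ax.create_dataset("td_s", data=obj.t_d)
            f.attrs["lambda0"] = obj.lambda0
            f.attrs["alpha_SD"] = obj.alpha_SD
            manifest = manifest or {}
            manifest.setdefault("meta", {}).update(
                {k: v for k, v in obj.meta.items() if isinstance(v, (int, float, str, bool))}
            )
        elif isinstance(obj, TOFResolvedAutocorrelation):
            f.attrs["kind"] = "autocorr"
            f.create_dataset("g1", data=obj.G1)
            f.create_dataset("tpsf", data=obj.tpsf)
            if obj.imag is not None:
                f.create_dataset("g1_imag", data=obj.imag)
            if obj.G2 is not None:
                f.create_dataset("g2", data=obj.G2)
            if obj.ci_low is not None:
                f.create_dataset("ci_low", data=obj.ci_low)
                f.create_dataset("ci_high", data=obj.ci_high)
            ax.create_dataset("tof_ps", data=obj.tof_ps)
            ax.create_dataset("taud_s", data=obj.tau_d)
        elif isinstance(obj, PhotonPathEnsemble):
            f.attrs["kind"] = "paths"
            g = f.create_group("paths")
            g.create_dataset("tof_ps", data=obj.tof_ps)
            g.create_dataset("weight", data=obj.weight)
            g.create_dataset("q2_sum", data=obj.q2_sum)
            g.create_dataset("path_length", data=obj.path_length)
            g.create_dataset("n_dynamic", data=obj.n_dynamic)
            g.create_dataset("max_dynamic_angle", data=obj.max_dynamic_angle)
            f.attrs["n_launched"] = obj.n_launched
            f.attrs["seed"] = -1 if obj.seed is None else obj.seed
        else:
            raise TypeError(f"cannot store object of type {type(obj).__name__}")
        _write_manifest(f, manifest)


def _require(f, name):
    if name not in f:
        raise SchemaError(f"missing dataset: {name}")
    return f[name]


def read_container(path):
    """Read a container back into its typed object.

    Returns (object, manifest).  Missing datasets raise SchemaError
    naming the dataset.
    """
    with h5py.File(path, "r") as f:
        manifest = _read_manifest(f)
        kind = f.attrs.get("kind")
        if kind == "gamma":
            obj = MutualCoherenceSeries(
                tof_ps=_require(f, "axes/tof_ps")[:],
                t_d=_require(f, "axes/td_s")[:],
                gamma=_require(f, "gamma")[:].astype(complex),
                lambda0=float(f.attrs["lambda0"]),
                alpha_SD=float(f.attrs["alpha_SD"]),
                meta=dict(manifest.get("meta", {})),
            )
        elif kind == "autocorr":
            obj = TOFResolvedAutocorrelation(
                tof_ps=_require(f, "axes/tof_ps")[:],
                tau_d=_require(f, "axes/taud_s")[:],
                G1=_require(f, "g1")[:],
                tpsf=_require(f, "tpsf")[:],
                imag=f["g1_imag"][:] if "g1_imag" in f else None,
                G2=f["g2"][:] if "g2" in f else None,
                ci_low=f["ci_low"][:] if "ci_low" in f else None,
                ci_high=f["ci_high"][:] if "ci_high" in f else None,
            )
        elif kind == "paths":
            g = _require(f, "paths")
            obj = PhotonPathEnsemble(
                tof_ps=g["tof_ps"][:],
                weight=g["weight"][:],
                q2_sum=g["q2_sum"][:],
                path_length=g["path_length"][:],
                n_dynamic=g["n_dynamic"][:],
                max_dynamic_angle=g["max_dynamic_angle"][:],
                n_launched=int(f.attrs["n_launched"]),
                seed=int(f.attrs["seed"]),
            )
        else:
            raise SchemaError(f"unknown container kind {kind!r}")
    return obj, manifest


# --------------------------------------------------------------------------
# Fixture presets
# --------------------------------------------------------------------------


def intralipid_components(tof, optics, bfi, snr_db=40.0):
    """Single dynamic component, no static term; rates on the Brownian
    DWS decay-rate line through the origin."""
    from .physics import decay_rate_line, tpsf_semi_infinite

    from .synth import ComponentSpec

    intensity = tpsf_semi_infinite(np.clip(tof, 1.0, None), 0.1, optics)
    intensity = intensity / intensity.max()
    xi = decay_rate_line(tof, bfi, optics, 0.0)
    noise = intensity.max() / 10 ** (snr_db / 10.0)
    return ComponentSpec.from_arrays(
        tof, fast=intensity, xi_fast=xi, noise_var=np.full_like(tof, noise)
    )


def forearm_components(tof, optics, bfi, snr_db=40.0, diffuse_fraction=0.01):
    """Static + slow + fast structure typical of vascularized tissue at
    null SD separation.

    The static component is an IRF-like peak at the earliest TOF with
    unit amplitude: in a backscattering geometry the few-scattered
    static return in the detection mode is orders of magnitude brighter
    than the diffuse dynamic light, whose TPSF-shaped profile peaks
    later in TOF (``diffuse_fraction`` of the static peak in total).
    Fast rates follow the Brownian decay-rate line; the slow component
    carries 30% of the dynamic amplitude at a tenth of the rate.
    """
    from .physics import decay_rate_line, tpsf_semi_infinite

    from .synth import ComponentSpec

    dyn = tpsf_semi_infinite(np.clip(tof, 1.0, None), 0.1, optics)
    dyn = dyn / dyn.max() * diffuse_fraction
    static = np.exp(-0.5 * ((tof - tof[0] - 11.0) / 16.0) ** 2)
    xi = decay_rate_line(tof, bfi, optics, 0.0)
    noise = 1.0 / 10 ** (snr_db / 10.0)
    return ComponentSpec.from_arrays(
        tof,
        static=static,
        slow=0.3 * dyn,
        xi_slow=np.clip(0.1 * xi, 5.0, None),
        fast=dyn,
        xi_fast=np.clip(xi, 50.0, None),
        noise_var=np.full_like(tof, noise),
    )


def make_fixture(preset: str, seed: int = 0, out: str | Path | None = None,
                 n_photons: int = 200_000):
    """Generate a small seeded end-to-end test input.

    Presets:

    * ``intralipid`` — homogeneous dynamic phantom (mu_s' = 10 /cm,
      mu_a = 0.045 /cm, BFI = 1.18e-8 cm^2/s); no static component.
    * ``forearm_like`` — static + slow + fast components with bulk
      motion, null SD geometry.
    * ``two_layer_head`` — Monte Carlo two-layer medium with low
      superficial and high deep blood flow index.
    * ``mc_homogeneous`` — Monte Carlo homogeneous all-dynamic
      isotropic medium.

    Returns the in-memory object; if ``out`` is given the container is
    also written there.  Same seed -> identical fixture.
    """
    from .montecarlo import DetectionGeometry, MediumLayer, simulate_paths
    from .physics import MSDModel, OpticalProperties
    from .synth import AcquisitionConfig, synthesize_gamma, synthesize_motion

    tof = np.arange(44.0, 880.0, 22.0)
    optics = OpticalProperties(mu_a=0.045, mu_s_prime=10.0, n_r=1.33, lambda0=855.0)
    if preset == "intralipid":
        cfg = AcquisitionConfig(tof_grid_ps=tof)
        comp = intralipid_components(tof, optics, 1.18e-8)
        obj = synthesize_gamma(comp, None, cfg, seed=seed)
    elif preset == "forearm_like":
        cfg = AcquisitionConfig(tof_grid_ps=tof, alpha_SD=np.deg2rad(10.0))
        comp = forearm_components(tof, optics, 6e-9)
        motion = synthesize_motion(0.2, cfg.alpha_SD, cfg, seed=seed + 1)
        obj = synthesize_gamma(comp, motion, cfg, seed=seed)
    elif preset == "two_layer_head":
        top = MediumLayer(
            thickness=1.0,
            optics=optics,
            dynamic_fraction=0.02,
            g_dynamic=0.975,
            g_static=0.0,
            msd_model=MSDModel(kind="brownian", D_B=1e-9 / 0.02),
        )
        deep = MediumLayer(
            thickness=np.inf,
            optics=optics,
            dynamic_fraction=0.02,
            g_dynamic=0.975,
            g_static=0.0,
            msd_model=MSDModel(kind="brownian", D_B=8e-9 / 0.02),
        )
        obj = simulate_paths(
            [top, deep], DetectionGeometry(rho=0.0, radius=0.3), n_photons, seed=seed
        )
    elif preset == "mc_homogeneous":
        layer = MediumLayer(
            thickness=np.inf,
            optics=optics,
            dynamic_fraction=1.0,
            g_dynamic=0.0,
            g_static=0.0,
            msd_model=MSDModel(kind="brownian", D_B=1.18e-8),
        )
        obj = simulate_paths(
            [layer], DetectionGeometry(rho=0.0, radius=0.3), n_photons, seed=seed
        )
    else:
        raise KeyError(f"unknown preset {preset!r}")
    if out is not None:
        manifest = make_manifest("make_fixture", {"preset": preset}, seed)
        write_container(obj, out, manifest)
    return obj


PRESETS = ("intralipid", "forearm_like", "two_layer_head", "mc_homogeneous")
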