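"""Shared fixtures: small Monte Carlo ensembles and synthetic series.

Session-scoped so the expensive photon walks and 2.5 s syntheses run
once per test session.
"""

import numpy as np
import pytest

from inirs import montecarlo as mc
from inirs.physics import MSDModel, OpticalProperties
from inirs.synth import AcquisitionConfig, ComponentSpec, synthesize_gamma, synthesize_motion

INTRALIPID_BFI = 1.18e-8  # cm^2/s, Brownian flow index of the phantom
MU_S_PRIME = 10.0  # 1/cm
MU_A = 0.045  # 1/cm


@pytest.fixture(scope="session")
def optics():
    return OpticalProperties(mu_a=MU_A, mu_s_prime=MU_S_PRIME, n_r=1.33, lambda0=855.0)


@pytest.fixture(scope="session")
def ens_homogeneous(optics):
    """Homogeneous, all-dynamic, isotropic Brownian medium (DWS oracle)."""
    layer = mc.MediumLayer(
        thickness=np.inf,
        optics=optics,
        dynamic_fraction=1.0,
        g_dynamic=0.0,
        g_static=0.0,
        msd_model=MSDModel(kind="brownian", D_B=INTRALIPID_BFI),
    )
    geo = mc.DetectionGeometry(rho=0.0, radius=0.3)
    ens = mc.simulate_paths([layer], geo, 600_000, seed=11, max_tof_ps=1500.0)
    return ens


@pytest.fixture(scope="session")
def ens_tissue_like(optics):
    """Sparse, highly anisotropic dynamic scattering (RBC-like)."""
    layer = mc.MediumLayer(
        thickness=np.inf,
        optics=optics,
        dynamic_fraction=0.02,
        g_dynamic=0.975,
        g_static=0.0,
        msd_model=MSDModel(kind="brownian", D_B=6e-9 / 0.02),
    )
    geo = mc.DetectionGeometry(rho=0.0, radius=0.3)
    return mc.simulate_paths([layer], geo, 300_000, seed=5, max_tof_ps=1000.0)


@pytest.fixture(scope="session")
def ens_intralipid_like(optics):
    """All-dynamic, moderately anisotropic phantom medium."""
    layer = mc.MediumLayer(
        thickness=np.inf,
        optics=optics,
        dynamic_fraction=1.0,
        g_dynamic=0.6,
        g_static=0.0,
        msd_model=MSDModel(kind="brownian", D_B=INTRALIPID_BFI),
    )
    geo = mc.DetectionGeometry(rho=0.0, radius=0.3)
    return mc.simulate_paths([layer], geo, 300_000, seed=5, max_tof_ps=1000.0)


def motion_validation_components():
    """TOF profile with a bright static (backscatter) bin for Doppler
    estimation and static-dominated but dynamically active bins for
    decay validation."""
    tof = np.arange(44.0, 220.0, 22.0)
    n = tof.size
    return ComponentSpec.from_arrays(
        tof,
        static=np.array([1.0, 0.7, 0.5, 0.35, 0.2, 0.1, 0.05, 0.02]),
        slow=np.array([0.005, 0.1, 0.15, 0.15, 0.12, 0.08, 0.05, 0.03]),
        xi_slow=np.full(n, 100.0),
        fast=np.array([0.0, 0.15, 0.25, 0.3, 0.3, 0.3, 0.3, 0.3]),
        xi_fast=2000.0 + 10.0 * (tof - 44.0),
        noise_var=np.full(n, 1e-4),
    )


@pytest.fixture(scope="session")
def motion_dataset():
    """Matched motion-free / motion-corrupted synthesis with ground truth."""
    comp = motion_validation_components()
    cfg = AcquisitionConfig(tof_grid_ps=comp.tof_grid_ps, alpha_SD=np.deg2rad(10.0))
    motion = synthesize_motion(0.2, cfg.alpha_SD, cfg, seed=101)
    free = synthesize_gamma(comp, None, cfg, seed=1)
    moving = synthesize_gamma(comp, motion, cfg, seed=1)
    return {"config": cfg, "components": comp, "motion": motion, "free": free, "moving": moving}
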