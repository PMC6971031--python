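"""Bulk-motion phase correction on a synthetic acquisition.

Synthesizes a 2.5 s mutual coherence series with micrometre-scale
random-walk axial motion riding on static + dynamic speckle, estimates
the Doppler track from 2 ms sliding windows at the TPSF-peak TOF, and
removes the cumulative bulk phase.  Prints how well the Doppler track
matches ground truth and how the corrected autocorrelation recovers
the motion-free decay.
"""

import numpy as np

from inirs.autocorr import estimate_g1
from inirs.io import forearm_components
from inirs.motion import correct, doppler_velocity, estimate_motion, sliding_doppler
from inirs.physics import OpticalProperties
from inirs.synth import AcquisitionConfig, synthesize_gamma, synthesize_motion

optics = OpticalProperties(mu_a=0.045, mu_s_prime=10.0, n_r=1.33, lambda0=855.0)
tof = np.arange(44.0, 880.0, 22.0)
cfg = AcquisitionConfig(tof_grid_ps=tof, alpha_SD=np.deg2rad(10.0))
components = forearm_components(tof, optics, bfi=6e-9)

motion = synthesize_motion(0.2, cfg.alpha_SD, cfg, seed=42)
free = synthesize_gamma(components, None, cfg, seed=7)
moving = synthesize_gamma(components, motion, cfg, seed=7)

centers, df = sliding_doppler(moving, window=2e-3, hop=1e-3)
v_est = doppler_velocity(df, moving.lambda0)
dt = cfg.lag_resolution
v_true = np.array([
    motion.velocity_um_s[int(round((c - 1e-3) / dt)) : int(round((c + 1e-3) / dt))].mean()
    for c in centers
])
r2 = 1 - np.sum((v_est - v_true) ** 2) / np.sum((v_true - v_true.mean()) ** 2)
print(f"Doppler velocity track vs ground truth: R^2 = {r2:.3f} "
      f"(velocities up to {np.abs(v_true).max():.0f} um/s)")

est = estimate_motion(moving, window=2e-3, hop=1e-3)
corrected = correct(moving, est.theta_bps)
rms = np.sqrt(np.mean((est.theta_bps - motion.theta_bps) ** 2))
print(f"cumulative phase recovered with {rms:.2f} rad RMS error "
      f"over {moving.t_d[-1]:.1f} s")

g_free = estimate_g1(free, 10e-3)
g_corr = estimate_g1(corrected, 10e-3)
g_raw = estimate_g1(moving, 10e-3, take_real=False)
b = 0  # static-dominated peak-TOF bin
m = np.argmin(np.abs(g_free.tau_d - 5e-3))
print(f"normalized static-bin autocorrelation at 5 ms lag: "
      f"raw {np.abs(g_raw.g1[b, m]):.3f}, corrected {g_corr.g1[b, m]:.3f}, "
      f"motion-free truth {g_free.g1[b, m]:.3f}")
# Motion makes the static bin appear to decorrelate within a fraction of
# a millisecond; the correction restores the near-flat intrinsic
# autocorrelation of static tissue.
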