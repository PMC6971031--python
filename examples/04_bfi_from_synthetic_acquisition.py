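"""Blood flow index from a full synthetic acquisition.

Synthesizes a 2.5 s Intralipid-like mutual coherence series (single
dynamic component, rates on the Brownian decay-rate line), estimates
the TOF-resolved field autocorrelation, fits a static+exponential model
per TOF bin over a 10 ms window, and regresses decay rate against TOF
to recover the blood flow index without any absorption assumption.
"""

import numpy as np

from inirs.autocorr import estimate_g1
from inirs.fitting import decay_rate_regression, fit_decay
from inirs.io import intralipid_components
from inirs.physics import OpticalProperties, decay_rate_line
from inirs.synth import AcquisitionConfig, synthesize_gamma

optics = OpticalProperties(mu_a=0.045, mu_s_prime=10.0, n_r=1.33, lambda0=855.0)
bfi_true = 1.18e-8  # cm^2/s

tof = np.arange(110.0, 770.0, 22.0)
cfg = AcquisitionConfig(tof_grid_ps=tof)
components = intralipid_components(tof, optics, bfi_true)
series = synthesize_gamma(components, None, cfg, seed=23)
print(f"synthesized {series.gamma.shape[0]} TOF bins x {series.gamma.shape[1]} delay points "
      f"({cfg.block_duration} s at {cfg.sweep_rate:.0f} Hz)")

acf = estimate_g1(series, tau_d_max=10e-3)
fits = [fit_decay(acf.tau_d, acf.G1[i], 3, tof_ps=float(t)) for i, t in enumerate(tof)]

for i in (0, len(tof) // 2, len(tof) - 1):
    xi_true = decay_rate_line(tof[i], bfi_true, optics, 0.0)
    print(f"tau_s = {tof[i]:5.0f} ps: fitted xi = {fits[i].xi:8.0f} 1/s "
          f"(injected {xi_true:8.0f}), adj R^2 = {fits[i].adj_r2:.5f}")

line = decay_rate_regression(fits, optics)
err = 100 * abs(line.bfi - bfi_true) / bfi_true
print(f"BFI = {line.bfi:.3e} cm^2/s ({err:.1f}% from injected {bfi_true:.2e}); "
      f"tau_s0 = {line.tau_s0:.1f} ps")
# Per-bin rates come straight from the estimated field autocorrelation;
# the BFI follows from the slope of the rate-vs-TOF line alone.
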