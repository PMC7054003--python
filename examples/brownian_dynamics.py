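"""Brownian-dynamics cross-validation (scaled-down demonstration).

Integrates the coarse-grained bead-spring chain with the Langevin
engine: first a handful of diffusive-search trajectories that end in
binding (with an enlarged capture radius so the demonstration runs in
seconds), then an equilibrium ensemble whose z-x histogram shows the
same two-lobed structure as the analytic density.  Also estimates the
effective head-head exclusion length dV from explicit leg-leg excluded
volume.
"""

import numpy as np
from scipy.signal import find_peaks

from myovstep.bd import SimSettings, ensemble_contours, estimate_dV, simulate_step
from myovstep.params import KineticRates, MotorParams

params = MotorParams()
rates = KineticRates()
settings = SimSettings(max_time=0.5)

print("diffusive-search trajectories (capture radius enlarged to 2 nm):")
sites = []
for seed in range(6):
    out = simulate_step(params, rates, settings=settings, capture_radius=2.0,
                        gate_hydrolysis=False, allow_termination=False,
                        seed=seed)
    sites.append(out.site)
    print(f"  seed {seed}: {out.status} at site n = {out.site} "
          f"after {out.elapsed:.3f} ms")
print("  (forward sites near the half-helical n = 13 dominate)")

print("\nequilibrium ensemble, z-x histogram ridge:")
e1, _, H, pts = ensemble_contours(params, n_traj=10, t_traj=0.02,
                                  settings=SimSettings(), seed=3)
prof = H.max(axis=1)
peaks, _ = find_peaks(prof, prominence=0.15 * prof.max())
print(f"  {len(peaks)} lobe(s) at z = "
      f"{np.round(0.5 * (e1[:-1] + e1[1:])[peaks], 0)} nm "
      "(two lobes = constrained diffusion)")

dv = estimate_dV(params, SimSettings(), n_samples=20000, seed=0)
print(f"\neffective exclusion length from explicit leg-leg repulsion: "
      f"dV = {dv:.1f} nm (the wild-type model uses 27.5 nm)")
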