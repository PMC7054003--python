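"""Step-size distributions for lever-arm-length mutants.

Builds the convolved forward-step distributions for the 4IQ, 6IQ
(wild-type) and 8IQ constructs, adds 1 nm localization noise and 5 nm
binning as in single-fluorophore tracking, and reports the peak step
sizes: step size grows linearly with lever length, and the long 8IQ
arms reach full-helical actin sites, producing a multi-peaked
distribution.
"""

import numpy as np
from scipy.signal import find_peaks

from myovstep import StepModel, measurement_convolve, mutant_params

for label in ("4IQ", "6IQ", "8IQ"):
    model = StepModel(mutant_params(label))
    dist = model.step_distribution("forward-only")
    centers, hist = measurement_convolve(dist, sigma=1.0, bin_width=5.0)
    peaks, _ = find_peaks(hist, prominence=0.05 * hist.max())
    mean = float(np.sum(centers * hist) / hist.sum())
    print(f"{label}: mean forward step {mean:5.1f} nm, "
          f"sd {dist.std():4.1f} nm, peaks at {centers[peaks]} nm")

sep = StepModel(mutant_params("6IQ"))
raw = sep.step_distribution("trailing")
from myovstep import head_separation_distribution
d = head_separation_distribution(sep.pathways)
print(f"\nwild-type head-separation mode: n = {d.n[np.argmax(d.mass)]} "
      f"subunits (z = {d.z[np.argmax(d.mass)]:.0f} nm, the half-helical site)")
print("a ~72 nm step is two half-helical spans: detach 36 nm behind the")
print("bound head, rebind 36 nm ahead.")
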