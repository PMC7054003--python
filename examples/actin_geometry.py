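"""The actin double-helix binding-site lattice.

Builds the helical site lattice and prints the positions a stepping
myosin V cares about: the half-helical site (the wild type's favourite
target) and the full-helical site (reachable only by the long-legged
8IQ mutant), plus each site's outward normal azimuth that gates
binding orientation.
"""

import math

import numpy as np

from myovstep import ActinLattice

lattice = ActinLattice()

print("actin lattice: R = %.1f nm, subunit rise dz/2 = %.3f nm"
      % (lattice.R, lattice.dz / 2))
for n in (1, 13, 26, -13):
    x, y, z = lattice.site_position(n)
    phi = math.degrees(lattice.site_normal_azimuth(n))
    print(f"  site n={n:+3d}: position ({x:6.2f}, {y:6.2f}, {z:7.2f}) nm, "
          f"normal azimuth {phi:7.1f} deg")

print("\nA full helical repeat is 26 subunits:")
d = lattice.site_position(26) - lattice.site_position(0)
print("  r(26) - r(0) =", np.round(d, 6), "nm  (axial pitch 72 nm)")

# the azimuthal acceptance window: a head can only bind a site it
# approaches anti-parallel to the outward normal, within +-55.6 deg
delta = math.radians(55.6)
phi_13 = lattice.site_normal_azimuth(13)
probe_in = phi_13 - math.pi + math.radians(40)
probe_out = phi_13 - math.pi + math.radians(70)
print("\nacceptance at the half-helical site (window +-55.6 deg):")
print("  leg azimuth 40 deg off anti-parallel ->",
      bool(lattice.acceptance_test(probe_in, 13, delta)))
print("  leg azimuth 70 deg off anti-parallel ->",
      bool(lattice.acceptance_test(probe_out, 13, delta)))
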