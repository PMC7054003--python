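"""Double-helical actin binding-site lattice.

Filamentous actin is a double helix of two protofilaments with 13 subunits
per half-pitch; successive subunits advance dz/2 = 36/13 nm axially and
rotate by -12*pi/13.  Site n = 0 is the position of the bound head; even
and odd n lie on the two protofilaments.  Each site carries an outward
radial normal with azimuth phi_n; a detached head can only bind when its
leg approaches the site anti-parallel to that normal within an azimuthal
acceptance window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ActinLattice", "wrap_angle", "acceptance_test"]


def wrap_angle(phi):
    """Wrap angle(s) to the interval (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    out = -np.mod(-phi + np.pi, 2.0 * np.pi) + np.pi  # maps to (-pi, pi]
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ActinLattice:
    """Helical binding-site lattice.

    R: helix radius (nm); dz: subunit axial size (nm, advance per subunit
    is dz/2 because the two protofilaments interleave); n_max: largest
    |site index| represented (must cover a full helical repeat, 26).
    """

    R: float = 5.5
    dz: float = 72.0 / 13.0
    n_max: int = 39

    def __post_init__(self) -> None:
        if self.R <= 0 or self.dz <= 0:
            raise ValueError("R and dz must be positive")
        if self.n_max < 26:
            raise ValueError("n_max must be >= 26 (one full helical repeat)")

    @property
    def sites(self) -> np.ndarray:
        """All site indices -n_max..n_max (including the occupied n=0)."""
        return np.arange(-self.n_max, self.n_max + 1)

    def _check(self, n) -> np.ndarray:
        n = np.asarray(n)
        if np.any(np.abs(n) > self.n_max):
            raise IndexError(f"site index out of range |n| <= {self.n_max}")
        return n

    def site_azimuth(self, n):
        """Helical rotation angle phi_n = -12 pi n / 13 (unwrapped)."""
        n = self._check(n)
        return -12.0 * np.pi * n / 13.0

    def site_position(self, n) -> np.ndarray:
        """Position of site n relative to the bound head at the origin.

        r_n = (R (cos phi_n - 1), R sin phi_n, n dz / 2).
        """
        n = self._check(n)
        phi = -12.0 * np.pi * np.asarray(n, dtype=float) / 13.0
        pos = np.stack(
            [self.R * (np.cos(phi) - 1.0), self.R * np.sin(phi),
             np.asarray(n, dtype=float) / 2.0 * self.dz], axis=-1)
        return pos

    def site_normal_azimuth(self, n):
        """Outward radial normal azimuth phi_n wrapped to (-pi, pi]."""
        return wrap_angle(self.site_azimuth(n))

    def acceptance_test(self, phi_f, n, delta1: float, delta2: float | None = None):
        """Azimuthal binding criterion at site n.

        True iff the wrapped angle (phi_f + pi) - phi_n lies in
        (-delta2, delta1); the free leg must point anti-parallel to the
        site's outward normal.  ``delta2`` defaults to ``delta1``
        (symmetric window).
        """
        if delta2 is None:
            delta2 = delta1
        if not (0.0 <= delta1 <= np.pi and 0.0 <= delta2 <= np.pi):
            raise ValueError("acceptance half-widths must lie in [0, pi]")
        phi_n = self.site_normal_azimuth(n)
        diff = wrap_angle(np.asarray(phi_f) + np.pi - phi_n)
        return (diff < delta1) & (diff > -delta2)

    def table(self) -> np.ndarray:
        """Structured export: columns (n, x, y, z, phi_n)."""
        n = self.sites
        pos = self.site_position(n)
        phi = self.site_normal_azimuth(n)
        return np.column_stack([n.astype(float), pos, phi])

    def export(self, path) -> None:
        """Write the lattice as whitespace-delimited text."""
        np.savetxt(
            path, self.table(),
            header="n x_nm y_nm z_nm phi_n_rad", comments="# ",
            fmt=["%d", "%.6f", "%.6f", "%.6f", "%.6f"],
        )


def acceptance_test(phi_f, phi_n, delta1: float, delta2: float | None = None):
    """Standalone azimuthal acceptance window test (angles in radians)."""
    if delta2 is None:
        delta2 = delta1
    diff = wrap_angle(np.asarray(phi_f) + np.pi - phi_n)
    return (diff < delta1) & (diff > -delta2)
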