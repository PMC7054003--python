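"""Equilibrium spatial distribution of the detached myosin V head.

The bound head sits at the origin with its leg end-to-end direction u1
biased toward the power-stroke direction; the free leg extends from the
joint to the searching head.  In the stiff-leg mean field the joint
position is r_J = r1*u1 with r1 drawn from the worm-like-chain radial
distribution and u1 from a von Mises-Fisher factor exp(T' u1 . u_c') of
concentration equal to the (load-renormalized) power-stroke
effectiveness T'.  The free-leg end-to-end vector v = r - r_J carries
the same radial distribution with an a-priori isotropic direction,
reweighted by the inter-leg joint potential
H_J = mu_c kBT [1 - cos(theta_J - theta_p)] (theta_J is the angle
between the two leg vectors at the joint) and by the effective
head-head exclusion exp[-(dV/r)^6].

The load force enters only through the renormalized (T', u_c') pair;
pulling on the joint tilts and reweights the bound-leg direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss

from .lattice import ActinLattice, wrap_angle
from .params import (JointPotentialSpec, LoadForce, MotorParams, PowerStroke,
                     effective_constraint)
from .wlc import WormLikeLeg

__all__ = [
    "QuadratureSpec", "DensityGrid", "DensityModel",
    "free_head_density", "joint_density_at_site", "project_density",
    "kl_divergence",
]


@dataclass(frozen=True)
class QuadratureSpec:
    """Deterministic quadrature resolution for the density integrals.

    n_r: Gauss points for each leg's radial distribution; n_alpha /
    n_psi: polar x azimuthal points for the bound-leg direction sphere;
    n_theta_norm: points for the 1-D inter-leg angle integral in the
    normalization; prune: relative weight floor below which bound-leg
    nodes are dropped.
    """

    n_r: int = 14
    n_alpha: int = 160
    n_psi: int = 60
    n_theta_norm: int = 512
    prune: float = 1e-16

    def scaled(self, factor: float) -> "QuadratureSpec":
        return replace(
            self,
            n_r=max(4, int(round(self.n_r * factor))),
            n_alpha=max(16, int(round(self.n_alpha * factor))),
            n_psi=max(8, int(round(self.n_psi * factor))),
            n_theta_norm=max(64, int(round(self.n_theta_norm * factor))),
        )


#: Coarser default used for full 3-D grids (visualization / validation).
GRID_QUAD = QuadratureSpec(n_r=8, n_alpha=96, n_psi=32, prune=1e-12)


@dataclass
class DensityGrid:
    """Free-head density sampled on a rectangular grid (nm, nm^-3)."""

    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def integral(self) -> float:
        v = self.values
        for ax in reversed(self.axes):
            v = np.trapezoid(v, ax, axis=-1)
        return float(v)

    def save(self, path) -> None:
        """Compressed array container; metadata in a JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path, x=self.axes[0], y=self.axes[1],
                            z=self.axes[2], values=self.values)
        meta = {k: (v if isinstance(v, (int, float, str, list)) else str(v))
                for k, v in self.metadata.items()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _rotation_to(target: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z to the unit vector ``target``."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, target)
    c = float(z @ target)
    if np.linalg.norm(v) < 1e-14:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


class DensityModel:
    """Mean-field free-head density for one (parameters, load) state.

    Precomputes quadrature nodes for the bound-leg configuration and the
    overall normalization (including the exclusion weight) so that site
    densities and grids can be evaluated cheaply.
    """

    def __init__(self, params: MotorParams, force: LoadForce = LoadForce(),
                 joint_spec: Optional[JointPotentialSpec] = None,
                 quad: QuadratureSpec = QuadratureSpec()):
        self.params = params
        self.force = force
        self.quad = quad
        self.joint_spec = joint_spec or JointPotentialSpec(
            mu_c=params.mu_c, theta_p=params.theta_p)
        self.stroke: PowerStroke = effective_constraint(params, force)
        self.leg = WormLikeLeg(params.L, params.lp)
        self._build_nodes()
        self._Z = self._normalization()

    # -- node construction -------------------------------------------------
    def _build_nodes(self) -> None:
        q = self.quad
        T = self.stroke.T_eff
        r1, wr = self.leg.radial_nodes(q.n_r)

        xg, wg = leggauss(q.n_alpha)          # cos(alpha) in [-1, 1]
        cosa = xg
        sina = np.sqrt(np.clip(1.0 - cosa**2, 0.0, None))
        # von Mises-Fisher weight about u_c'; self-normalized below
        wa = wg * np.exp(T * (cosa - 1.0))
        psi = 2.0 * np.pi * np.arange(q.n_psi) / q.n_psi
        # directions in the constraint frame, then rotate +z -> u_c'
        dirs = np.stack([
            np.outer(sina, np.cos(psi)),
            np.outer(sina, np.sin(psi)),
            np.broadcast_to(cosa[:, None], (q.n_alpha, q.n_psi)),
        ], axis=-1).reshape(-1, 3)
        wdir = np.repeat(wa / q.n_psi, q.n_psi)
        wdir /= wdir.sum()
        rot = _rotation_to(self.stroke.u_c_prime)
        dirs = dirs @ rot.T

        # outer product with radial nodes, then prune negligible weights
        u1 = np.repeat(dirs, len(r1), axis=0)
        w = (wdir[:, None] * wr[None, :]).reshape(-1)
        rj = (np.repeat(dirs, len(r1), axis=0)
              * np.tile(r1, len(dirs))[:, None])
        keep = w > q.prune * w.max()
        self._u1 = np.ascontiguousarray(u1[keep])
        self._rj = np.ascontiguousarray(rj[keep])
        self._w = np.ascontiguousarray(w[keep])

    # -- normalization -----------------------------------------------------
    def _normalization(self) -> float:
        """Z = int W(r) rho_tilde(r) d^3r by exact angular reduction.

        The unnormalized density integrates, for each bound-leg
        direction, over the free-leg length and the inter-leg angle
        only, because both the joint energy and the head-head distance
        depend on the two leg vectors solely through that angle.
        """
        q = self.quad
        r1, w1 = self.leg.radial_nodes(max(q.n_r, 24))
        r2, w2 = r1, w1
        xg, wg = leggauss(q.n_theta_norm)
        theta = 0.5 * np.pi * (xg + 1.0)
        wth = 0.5 * np.pi * wg * 0.5 * np.sin(theta)
        ej = np.exp(-self.joint_spec.energy(theta))
        # head-head distance d(r1, r2, theta)
        R1 = r1[:, None, None]
        R2 = r2[None, :, None]
        ct = np.cos(theta)[None, None, :]
        d2 = R1**2 + R2**2 - 2.0 * R1 * R2 * ct
        d2 = np.clip(d2, 1e-12, None)
        excl = np.exp(-(self.params.dV**2 / d2) ** 3)
        W = (w1[:, None, None] * w2[None, :, None]
             * (wth * ej)[None, None, :])
        return float(np.sum(W * excl))

    @property
    def normalization(self) -> float:
        return self._Z

    # -- evaluation --------------------------------------------------------
    def _accumulate(self, points: np.ndarray, lattice: Optional[ActinLattice],
                    site_idx: Optional[np.ndarray],
                    delta1: float, delta2: float):
        """Shared kernel: for each point, sum the bound-leg node weights
        times the free-leg vector density and joint Boltzmann factor;
        optionally also the sum restricted to the azimuthal window."""
        L = self.params.L
        rj, u1, w = self._rj, self._u1, self._w
        want_window = site_idx is not None
        marg = np.zeros(len(points))
        joint = np.zeros(len(points)) if want_window else None
        if want_window:
            phi_n = lattice.site_normal_azimuth(site_idx)
        # chunked over points; transcendentals only on reachable pairs
        B = max(1, int(2e6 // max(1, len(w))))
        full_window = want_window and delta1 >= np.pi and delta2 >= np.pi
        empty_window = want_window and delta1 <= 0.0 and delta2 <= 0.0
        for i0 in range(0, len(points), B):
            P = points[i0:i0 + B]
            v = P[:, None, :] - rj[None, :, :]           # (B, N, 3)
            d2 = np.einsum("bnk,bnk->bn", v, v)
            ok = (d2 < L * L) & (d2 > 1e-12)
            ipt, ind = np.nonzero(ok)
            if len(ipt) == 0:
                continue
            vv = v[ipt, ind]
            d = np.sqrt(d2[ipt, ind])
            q2 = self.leg.vector_density(d)
            cosj = np.clip(-np.einsum("mk,mk->m", vv, u1[ind]) / d,
                           -1.0, 1.0)
            contrib = (w[ind] * q2
                       * np.exp(-self.joint_spec.energy(np.arccos(cosj))))
            nb = len(P)
            marg[i0:i0 + nb] = np.bincount(ipt, weights=contrib,
                                           minlength=nb)
            if want_window:
                if full_window:
                    joint[i0:i0 + nb] = marg[i0:i0 + nb]
                elif empty_window:
                    joint[i0:i0 + nb] = 0.0
                else:
                    phi_f = np.arctan2(vv[:, 1], vv[:, 0])
                    diff = wrap_angle(phi_f + np.pi - phi_n[i0 + ipt])
                    inwin = (diff < delta1) & (diff > -delta2)
                    joint[i0:i0 + nb] = np.bincount(
                        ipt, weights=contrib * inwin, minlength=nb)
        return marg, joint

    def _exclusion(self, r: np.ndarray) -> np.ndarray:
        r2 = np.einsum("ij,ij->i", r, r)
        r2 = np.clip(r2, 1e-12, None)
        return np.exp(-(self.params.dV**2 / r2) ** 3)

    def density_at(self, points) -> np.ndarray:
        """Normalized free-head density P(r) (nm^-3) at the given points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        marg, _ = self._accumulate(points, None, None, 0.0, 0.0)
        return marg * self._exclusion(points) / self._Z

    def site_densities(self, lattice: ActinLattice,
                       delta1: Optional[float] = None,
                       delta2: Optional[float] = None):
        """Marginal and azimuthal-window joint densities at every site.

        Returns (n, P_marginal, P_window) arrays over n != 0.  With the
        full window (half-widths >= pi) the joint density equals the
        marginal; with a zero window it vanishes.
        """
        if delta1 is None:
            delta1 = self.params.dphi_ac
        if delta2 is None:
            delta2 = delta1
        n = lattice.sites
        n = n[n != 0]
        pts = lattice.site_position(n)
        marg, joint = self._accumulate(pts, lattice, n, delta1, delta2)
        excl = self._exclusion(pts) / self._Z
        return n, marg * excl, joint * excl

    def grid(self, spacing: float = 2.5, extent: Optional[float] = None,
             quad: Optional[QuadratureSpec] = None) -> DensityGrid:
        """Evaluate the density on a cubic grid (visualization grade)."""
        model = self
        if quad is not None:
            model = DensityModel(self.params, self.force, self.joint_spec, quad)
        if extent is None:
            extent = 2.0 * self.params.L + 5.0
        ax = np.arange(-extent, extent + 0.5 * spacing, spacing)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        vals = np.empty(len(pts))
        chunk = 2048
        for i in range(0, len(pts), chunk):
            vals[i:i + chunk] = model.density_at(pts[i:i + chunk])
        grid = DensityGrid(
            axes=(ax.copy(), ax.copy(), ax.copy()),
            values=vals.reshape(X.shape),
            metadata={
                "spacing_nm": spacing, "extent_nm": float(extent),
                "F_pN": self.force.F, "theta_F": self.force.theta_F,
                "phi_F": self.force.phi_F, "mu_c": self.params.mu_c,
                "L": self.params.L,
            },
        )
        cov = grid.integral()
        if not 0.9 < cov < 1.1:
            raise ValueError(
                f"grid too coarse or too small to normalize: coverage {cov:.3f}"
            )
        return grid


# ---------------------------------------------------------------------------
# module-level convenience operations


def free_head_density(params: MotorParams, force: LoadForce = LoadForce(),
                      spacing: float = 2.5, extent: Optional[float] = None,
                      quad: QuadratureSpec = GRID_QUAD,
                      joint_spec: Optional[JointPotentialSpec] = None
                      ) -> DensityGrid:
    """Normalized 3-D density of the detached head on a cubic grid."""
    model = DensityModel(params, force, joint_spec, quad)
    return model.grid(spacing=spacing, extent=extent)


def joint_density_at_site(params: MotorParams, force: LoadForce, n: int,
                          lattice: Optional[ActinLattice] = None,
                          quad: QuadratureSpec = QuadratureSpec()) -> float:
    """Joint density (nm^-3) of head position at site n with the free-leg
    azimuth inside the acceptance window."""
    lattice = lattice or ActinLattice()
    model = DensityModel(params, force, quad=quad)
    sites, _, joint = model.site_densities(lattice)
    return float(joint[sites == n][0])


_PLANES = {"z-x": (1, 2, 0), "z-y": (0, 2, 1), "y-x": (2, 1, 0)}


def project_density(grid: DensityGrid, plane: str):
    """Project the 3-D density to a named 2-D plane by marginalization.

    Returns (axis1, axis2, density) with density[i, j] on (plane axis 1,
    plane axis 2).  ``z-rho`` uses rho = sqrt(x^2 + y^2) with the
    cylindrical Jacobian folded in so the marginal still integrates to 1.
    """
    x, y, z = grid.axes
    if plane in _PLANES:
        integrate_axis, a1, a2 = _PLANES[plane]
        axes = [x, y, z]
        dens = np.trapezoid(grid.values, axes[integrate_axis],
                            axis=integrate_axis)
        # remaining axes keep original (x, y, z) order; all named planes
        # list the higher-index axis first, so transpose
        return axes[a1], axes[a2], dens.T
    if plane == "z-rho":
        X, Y = np.meshgrid(x, y, indexing="ij")
        rho = np.sqrt(X**2 + Y**2)
        drho = min(x[1] - x[0], y[1] - y[0])
        edges = np.arange(0.0, rho.max() + drho, drho)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = np.zeros((len(z), len(centers)))
        dx, dy = x[1] - x[0], y[1] - y[0]
        idx = np.clip(np.digitize(rho.ravel(), edges) - 1, 0, len(centers) - 1)
        for k in range(len(z)):
            dens[k] = np.bincount(idx, weights=grid.values[:, :, k].ravel(),
                                  minlength=len(centers)) * dx * dy / drho
        return z, centers, dens
    raise ValueError(f"unknown projection plane {plane!r}")


def kl_divergence(P, Q) -> float:
    """Kullback-Leibler divergence sum P log(P/Q) in nats.

    Both inputs are discrete distributions on the same support; they are
    renormalized, and Q must be positive wherever P is.
    """
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.shape != Q.shape:
        raise ValueError("distributions must share the same support")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("distributions must be nonnegative")
    P = P / P.sum()
    Q = Q / Q.sum()
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ValueError("Q must be positive wherever P is positive")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))
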