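"""Coarse-grained Brownian-dynamics engine for the two-leg chain.

Overdamped Langevin integration of the bead-spring chain under the full
energy model, with diffusive-search trajectories that attempt binding
when the free head enters the capture radius of a lattice site with the
free leg inside the conical acceptance region.  The hydrolysis gate
(trailing detachment only), the binding penalty for orientationally
disfavoured sites, and bound-head detachment (termination) are applied
stochastically.  Also provides ensemble contour histograms and the
effective head-head exclusion-length estimate from explicit leg-leg
excluded volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss

from .chain import (bd_trajectory, initial_configuration, metropolis_sample,
                    pack_chain_params)
from .lattice import ActinLattice
from .params import KineticRates, LoadForce, MotorParams
from .wlc import WormLikeLeg

__all__ = ["SimSettings", "StepOutcome", "simulate_step",
           "ensemble_contours", "estimate_dV"]


@dataclass(frozen=True)
class SimSettings:
    """Integration settings.

    dt is in ns; the default keeps the per-step RMS bead displacement
    (~0.08 nm) and the bond-relaxation stability product well inside the
    stable regime for the default bond stiffness.
    """

    dt: float = 0.05                 # ns
    n_beads_per_leg: int = 7         # bonds per leg (5 nm granularity)
    max_time: float = 5.0            # ms
    seed: int = 0
    coverslip: Optional[float] = None  # wall position (nm) on y, or None
    record_stride: int = 0           # steps between recorded head samples
    k_bond: float = 25.0             # kBT/nm^2
    check_stride: int = 8            # steps between binding checks
    D_bead: float = 5.7e4            # nm^2/ms (head diffusivity)

    @property
    def dt_ms(self) -> float:
        return self.dt * 1e-6


@dataclass
class StepOutcome:
    """Result of one diffusive-search trajectory."""

    status: str                      # bound | terminated | timeout
    site: Optional[int]
    elapsed: float                   # ms
    heads: np.ndarray = field(repr=False, default=None)  # recorded positions


def _site_array(lattice: ActinLattice) -> np.ndarray:
    n = lattice.sites
    n = n[n != 0]
    pos = lattice.site_position(n)
    phi = lattice.site_normal_azimuth(n)
    return np.column_stack([n.astype(float), pos, phi])


def simulate_step(params: MotorParams, rates: KineticRates,
                  lattice: Optional[ActinLattice] = None,
                  force: LoadForce = LoadForce(),
                  settings: SimSettings = SimSettings(),
                  detached: str = "trailing",
                  capture_radius: Optional[float] = None,
                  gate_hydrolysis: bool = True,
                  allow_termination: bool = True,
                  seed: Optional[int] = None,
                  init: str = "stroke") -> StepOutcome:
    """One diffusive-search trajectory from detachment to binding.

    With ``init="stroke"`` the trajectory starts with the freed leg
    pointing toward its old site (backward for a detached trailing leg,
    forward for a leading leg); the power stroke of the bound leg is
    already encoded in the anchor constraint, so the initial relaxation
    sweeps the free head forward before the slow search.
    ``init="equilibrium"`` starts from a Metropolis sample of the chain
    equilibrium instead — the quasi-equilibrium premise of the analytic
    first-passage expression, which removes the initial arc transit
    (useful for scaled-down comparisons).  Deterministic per seed.
    """
    lattice = lattice or ActinLattice()
    if detached not in ("trailing", "leading"):
        raise ValueError("detached must be 'trailing' or 'leading'")
    if init not in ("stroke", "equilibrium"):
        raise ValueError(f"unknown init mode {init!r}")
    m = settings.n_beads_per_leg
    par = pack_chain_params(params, force, m=m, k_bond=settings.k_bond,
                            coverslip=settings.coverslip)
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    if init == "equilibrium":
        _, _, _, cfgs = metropolis_sample(
            par, initial_configuration(params, m=m), 1, thin=1,
            burn=3000 + int(rng.integers(2000)),
            seed=int(rng.integers(2**31 - 1)), keep_configs=True)
        x0 = np.ascontiguousarray(cfgs[0])
    else:
        # initial free-leg direction: toward the previous binding site
        old = lattice.site_position(-13 if detached == "trailing" else 13)
        joint = params.L * params.u_c
        d = old - joint
        x0 = initial_configuration(params, m=m,
                                   free_dir=d / np.linalg.norm(d))
    t_h = rng.exponential(rates.th) if (gate_hydrolysis
                                        and detached == "trailing") else 0.0
    t_det = rng.exponential(rates.td1) if allow_termination else 1e18
    a = capture_radius if capture_radius is not None else params.a
    if detached == "trailing":
        pen_fwd, pen_bwd = 1.0, params.b
    else:
        pen_fwd, pen_bwd = params.b, 1.0
    n_steps = int(settings.max_time / settings.dt_ms)
    status, site, elapsed, heads, _ = bd_trajectory(
        par, x0, settings.dt_ms, n_steps,
        seed=int(rng.integers(2**31 - 1)), D_bead=settings.D_bead,
        record_stride=settings.record_stride, sites=_site_array(lattice),
        a_capture=a, cos_ac=math.cos(params.dphi_ac),
        penalty_fwd=pen_fwd, penalty_bwd=pen_bwd,
        t_hydrolysis=t_h, t_detach=t_det,
        check_stride=settings.check_stride)
    names = {0: "timeout", 1: "bound", 2: "terminated"}
    return StepOutcome(status=names[status],
                       site=site if status == 1 else None,
                       elapsed=elapsed, heads=heads)


def ensemble_contours(params: MotorParams, force: LoadForce = LoadForce(),
                      n_traj: int = 16, t_traj: float = 0.05,
                      settings: SimSettings = SimSettings(),
                      plane: str = "z-x", bins: Optional[np.ndarray] = None,
                      seed: int = 0, discard: float = 0.2,
                      init: str = "equilibrium"):
    """Time-weighted free-head position histogram from BD trajectories.

    ``init="equilibrium"`` seeds each walker from an independent
    Metropolis sample of the same harmonic-bond Hamiltonian, so the
    ensemble is stationary from the start (the global arc-swing mixing
    time, ~0.5 ms, exceeds affordable trajectory lengths).
    ``init="spread"`` starts walkers from straight configurations with
    isotropically distributed free-leg directions; ``init="stroke"``
    uses the post-power-stroke configuration for every walker.  The
    leading ``discard`` fraction of each record (the fast lever-arm
    relaxation, ~5 us) is dropped.  Returns (edges1, edges2, H, samples).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be positive")
    if init not in ("equilibrium", "spread", "stroke"):
        raise ValueError(f"unknown init mode {init!r}")
    m = settings.n_beads_per_leg
    par = pack_chain_params(params, force, m=m, k_bond=settings.k_bond,
                            coverslip=settings.coverslip)
    record = settings.record_stride or 200
    n_steps = int(t_traj / settings.dt_ms)
    rng = np.random.default_rng(seed)
    starts = []
    if init == "equilibrium":
        # rigid pivot sampling mixes across the arc far faster than
        # bead moves; heavy thinning decorrelates the walker seeds, and
        # the harmonic bonds re-equilibrate within the discarded burn-in
        x0 = initial_configuration(params, m=m)
        _, _, _, configs = metropolis_sample(
            par, x0, n_traj, thin=200, burn=4000,
            seed=int(rng.integers(2**31 - 1)), rigid=True,
            keep_configs=True)
        starts = list(configs)
    else:
        for k in range(n_traj):
            if init == "spread":
                v = rng.normal(size=3)
                starts.append(initial_configuration(
                    params, m=m, free_dir=v / np.linalg.norm(v)))
            else:
                starts.append(initial_configuration(params, m=m))
    samples = []
    for x0 in starts:
        status, _, _, heads, _ = bd_trajectory(
            par, np.ascontiguousarray(x0), settings.dt_ms, n_steps,
            seed=int(rng.integers(2**31 - 1)), D_bead=settings.D_bead,
            record_stride=record)
        samples.append(heads[int(len(heads) * discard):])
    pts = np.concatenate(samples, axis=0)
    axes = {"z-x": (2, 0), "z-y": (2, 1), "y-x": (1, 0)}
    if plane not in axes:
        raise ValueError(f"unknown plane {plane!r}")
    i, j = axes[plane]
    if bins is None:
        bins = np.arange(-80.0, 81.0, 8.0)
    H, e1, e2 = np.histogram2d(pts[:, i], pts[:, j], bins=(bins, bins))
    return e1, e2, H / H.sum(), pts


def _pair_distance_reference(params: MotorParams, n_theta: int = 256,
                             n_r: int = 24):
    """Analytic head-head distance density without any exclusion."""
    leg = WormLikeLeg(params.L, params.lp)
    r1, w1 = leg.radial_nodes(n_r)
    xg, wg = leggauss(n_theta)
    theta = 0.5 * np.pi * (xg + 1.0)
    wth = 0.5 * np.pi * wg * 0.5 * np.sin(theta)
    ej = np.exp(-params.mu_c * (1.0 - np.cos(theta - params.theta_p)))
    R1 = r1[:, None, None]
    R2 = r1[None, :, None]
    ct = np.cos(theta)[None, None, :]
    d = np.sqrt(np.clip(R1**2 + R2**2 - 2 * R1 * R2 * ct, 1e-12, None))
    W = w1[:, None, None] * w1[None, :, None] * (wth * ej)[None, None, :]
    return d.ravel(), W.ravel()


def estimate_dV(params: MotorParams, settings: SimSettings = SimSettings(),
                bead_excl_diam: float = 5.0, n_samples: int = 40000,
                seed: int = 0, warn_threshold: float = 0.2) -> float:
    """Effective head-head exclusion length from explicit leg-leg
    excluded volume.

    Samples the chain with pairwise inter-leg bead repulsion (and the
    effective (dV/r)^6 term off), histograms the head-head distance,
    and fits dV so that the exclusion-free analytic distance density
    reweighted by exp[-(dV/r)^6] matches.  Returns dV in nm; warns when
    the relative fit residual exceeds ``warn_threshold``.
    """
    import warnings

    from scipy.optimize import minimize_scalar

    m = settings.n_beads_per_leg
    par = pack_chain_params(params, m=m, head_head=False,
                            bead_excl_diam=bead_excl_diam,
                            bead_excl_strength=1.0)
    x0 = initial_configuration(params, m=m)
    heads, joints, _ = metropolis_sample(par, x0, n_samples, thin=8,
                                         burn=4000, seed=seed)
    r_sim = np.linalg.norm(heads, axis=1)
    edges = np.linspace(5.0, 2.0 * params.L, 40)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h_sim, _ = np.histogram(r_sim, bins=edges, density=True)
    d_ref, w_ref = _pair_distance_reference(params)

    def hist_model(dV):
        w = w_ref * np.exp(-(dV / np.clip(d_ref, 1e-6, None)) ** 6)
        h, _ = np.histogram(d_ref, bins=edges, weights=w)
        h /= (h.sum() * np.diff(edges))
        return h

    if bead_excl_diam <= 0:
        return 0.0

    def loss(dV):
        return float(np.sum((hist_model(dV) - h_sim) ** 2))

    res = minimize_scalar(loss, bounds=(1.0, 2.0 * params.L),
                          method="bounded")
    dv = float(res.x)
    scale = float(np.sum(h_sim**2))
    if res.fun / scale > warn_threshold**2:
        warnings.warn(
            f"(dV/r)^6 form fits the simulated exclusion poorly "
            f"(relative residual {math.sqrt(res.fun / scale):.2f})",
            RuntimeWarning)
    return dv
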