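"""Step/stomp distributions, run statistics, parameter scans, and a
kinetic Monte-Carlo run simulator.

Steps are resolved on the half-subunit axial grid z_n = n*dz/2.  The
head-separation distribution (probability of n subunits between bound
heads) follows from the per-site pathway probabilities; observed step
sizes are its convolution with the per-branch binding distributions.
Run length, run time and velocity follow from the termination
probability: a run takes on average 1/P_t detachment events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .density import DensityModel, QuadratureSpec
from .kinetics import (BindingTimes, PathwayProbabilities, SitePassage,
                       binding_times, first_passage_times,
                       pathway_probabilities)
from .lattice import ActinLattice
from .params import KineticRates, LoadForce, MotorParams

__all__ = [
    "StepDistribution", "RunObservables", "StepModel",
    "head_separation_distribution", "step_distribution",
    "measurement_convolve", "run_statistics", "stall_force",
    "offaxis_scan", "constraint_scan", "run_monte_carlo",
]


@dataclass
class StepDistribution:
    """Probability mass on the axial half-subunit grid z_n = n dz/2."""

    n: np.ndarray            # integer support indices
    mass: np.ndarray
    dz: float = 72.0 / 13.0
    kind: str = "combined"

    @property
    def z(self) -> np.ndarray:
        return self.n * self.dz / 2.0

    def total(self) -> float:
        return float(self.mass.sum())

    def normalized(self) -> "StepDistribution":
        return StepDistribution(self.n, self.mass / self.mass.sum(),
                                self.dz, self.kind)

    def mean(self) -> float:
        m = self.mass / self.mass.sum()
        return float(np.sum(self.z * m))

    def std(self) -> float:
        m = self.mass / self.mass.sum()
        mu = np.sum(self.z * m)
        return float(math.sqrt(np.sum((self.z - mu) ** 2 * m)))

    def trimmed(self, floor: float = 0.0) -> "StepDistribution":
        keep = self.mass > floor
        if not keep.any():
            return self
        i0, i1 = np.argmax(keep), len(keep) - np.argmax(keep[::-1])
        return StepDistribution(self.n[i0:i1], self.mass[i0:i1],
                                self.dz, self.kind)


@dataclass(frozen=True)
class RunObservables:
    """Aggregate observables of a processive run."""

    z_run: float             # mean run length, nm
    t_run: float             # mean run time, ms
    v_run: float             # mean velocity, nm/ms
    N_run: float             # mean number of detachment events, 1/Pt
    step_ratio: float        # Pb/Pf
    t_wait: float            # mean waiting time between detachments, ms


def _dense(n: np.ndarray, mass: np.ndarray, lo: int, hi: int) -> np.ndarray:
    out = np.zeros(hi - lo + 1)
    out[n - lo] = mass
    return out


def head_separation_distribution(pp: PathwayProbabilities,
                                 g: Optional[float] = None,
                                 max_sep: Optional[int] = None,
                                 dz: float = 72.0 / 13.0) -> StepDistribution:
    """Distribution of the number of subunits between bound heads (n > 0),
    renormalized to remove termination.

    ``max_sep`` truncates large separations (the 'small steps' variant
    used when an imaging method cannot resolve stretched-out motors).
    """
    if g is None:
        g = pp.g
    wT, wL = g / (1.0 + g), 1.0 / (1.0 + g)
    nmax = int(np.abs(pp.n).max())
    pT = _dense(pp.n, pp.pT, -nmax, nmax)
    pL = _dense(pp.n, pp.pL, -nmax, nmax)
    ns = np.arange(1, nmax + 1)
    c = nmax  # index of n=0 in the dense arrays
    mass = (wT * (pT[c + ns] + pT[c - ns])
            + wL * (pL[c + ns] + pL[c - ns]))
    if max_sep is not None:
        mass = np.where(ns <= max_sep, mass, 0.0)
    if mass.sum() <= 0:
        raise ValueError("no probability mass on positive separations")
    return StepDistribution(ns, mass / mass.sum(), dz, "raw-separation")


def step_distribution(pp: PathwayProbabilities, g: Optional[float] = None,
                      mode: str = "combined",
                      max_sep: Optional[int] = None,
                      dz: float = 72.0 / 13.0) -> StepDistribution:
    """Convolved step-size distribution.

    trailing:  (P_dist * P_T)[n]     (unnormalized, mass = sum pT)
    leading:   (P_-dist * P_L)[n]    (reversed separations)
    combined:  g/(1+g) trailing + 1/(1+g) leading (mass = 1 - Pt)
    forward-only: trailing with backward binding removed, normalized.
    """
    if g is None:
        g = pp.g
    if mode not in ("trailing", "leading", "combined", "forward-only"):
        raise ValueError(f"unknown step distribution mode {mode!r}")
    sep = head_separation_distribution(pp, g, max_sep=max_sep, dz=dz)
    nmax = int(np.abs(pp.n).max())
    lo = -nmax
    pT = _dense(pp.n, pp.pT, lo, nmax)
    pL = _dense(pp.n, pp.pL, lo, nmax)
    sep_dense = _dense(sep.n, sep.mass, 1, nmax)

    def conv(sep_arr, sep_lo, site_arr, site_lo):
        m = np.convolve(sep_arr, site_arr)
        n0 = sep_lo + site_lo
        return np.arange(n0, n0 + len(m)), m

    wT, wL = g / (1.0 + g), 1.0 / (1.0 + g)
    if mode == "trailing":
        n, m = conv(sep_dense, 1, pT, lo)
        return StepDistribution(n, m, dz, "trailing-step")
    if mode == "leading":
        n, m = conv(sep_dense[::-1], -nmax, pL, lo)
        return StepDistribution(n, m, dz, "leading-step")
    if mode == "forward-only":
        pT_fwd = pT.copy()
        pT_fwd[:nmax] = 0.0  # indices lo..-1
        n, m = conv(sep_dense, 1, pT_fwd, lo)
        if m.sum() <= 0:
            raise ValueError("forward stepping has zero probability")
        return StepDistribution(n, m / m.sum(), dz, "forward-only")
    nT, mT = conv(sep_dense, 1, pT, lo)
    nL, mL = conv(sep_dense[::-1], -nmax, pL, lo)
    lo2, hi2 = min(nT[0], nL[0]), max(nT[-1], nL[-1])
    m = np.zeros(hi2 - lo2 + 1)
    m[nT - lo2] += wT * mT
    m[nL - lo2] += wL * mL
    return StepDistribution(np.arange(lo2, hi2 + 1), m, dz, "combined")


def measurement_convolve(dist: StepDistribution, sigma: float = 1.0,
                         bin_width: float = 5.0):
    """Emulate finite measurement precision: Gaussian localization noise
    of width ``sigma`` followed by histogram binning.

    Returns (bin_centers, bin_mass); total mass is preserved.  Bin edges
    are aligned to multiples of the bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    z, mass = dist.z, dist.mass
    lo = math.floor((z.min() - 6.0 * sigma) / bin_width) * bin_width
    hi = math.ceil((z.max() + 6.0 * sigma) / bin_width) * bin_width
    if hi <= lo:  # degenerate support (point mass, no noise)
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    if sigma == 0.0:
        hist, _ = np.histogram(z, bins=edges, weights=mass)
    else:
        # CDF differences of each Gaussian kernel across all bin edges
        cdf = ndtr((edges[None, :] - z[:, None]) / sigma)
        hist = (mass[:, None] * np.diff(cdf, axis=1)).sum(axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist


def smoothed_profile(dist: StepDistribution, sigma: float = 1.0,
                     dz_grid: float = 0.1):
    """Continuous Gaussian-smoothed profile (for locating peaks)."""
    z, mass = dist.z, dist.mass
    grid = np.arange(z.min() - 4 * sigma, z.max() + 4 * sigma, dz_grid)
    prof = np.sum(
        mass[:, None] * np.exp(-0.5 * ((grid[None, :] - z[:, None]) / sigma) ** 2),
        axis=0) / (sigma * math.sqrt(2 * math.pi))
    return grid, prof


def run_statistics(pp: PathwayProbabilities, dist: StepDistribution,
                   bt: BindingTimes, rates: KineticRates) -> RunObservables:
    """Mean run length, time and velocity from the combined distribution.

    z_run = (1/2) sum_n z_n P(z_n) / [Pt (1 - Pt)]: the combined
    distribution carries mass 1 - Pt, a run averages 1/Pt events, and
    the center of mass moves half the head displacement.
    """
    Pt = pp.Pt
    if Pt <= 0:
        raise ValueError("termination probability is zero: infinite run")
    if Pt >= 1:
        raise ValueError("termination probability is one: no stepping")
    if dist.kind != "combined":
        raise ValueError("run statistics require the combined distribution")
    denom = Pt * (1.0 - Pt)
    z_run = 0.5 * float(np.sum(dist.z * dist.mass)) / denom
    g = rates.g
    wT, wL = g / (1.0 + g), 1.0 / (1.0 + g)
    tw = rates.t_wait
    t_run = (wT * pp.pT.sum() * (tw + bt.tT)
             + wL * pp.pL.sum() * (tw + bt.tL)) / denom
    return RunObservables(
        z_run=z_run, t_run=t_run, v_run=z_run / t_run, N_run=1.0 / Pt,
        step_ratio=pp.step_ratio, t_wait=tw,
    )


class StepModel:
    """Full analytic pipeline for one (parameters, rates, load) state."""

    def __init__(self, params: MotorParams,
                 rates: KineticRates = KineticRates(),
                 force: LoadForce = LoadForce(),
                 lattice: Optional[ActinLattice] = None,
                 quad: QuadratureSpec = QuadratureSpec()):
        self.params = params
        self.rates = rates
        self.force = force
        self.lattice = lattice or ActinLattice()
        self.quad = quad
        self.density = DensityModel(params, force, quad=quad)
        self.passage = first_passage_times(params, force, self.lattice,
                                           model=self.density)
        self.pathways = pathway_probabilities(self.passage, rates, params.b)
        self.times = binding_times(self.passage, rates)

    def step_distribution(self, mode: str = "combined",
                          max_sep: Optional[int] = None) -> StepDistribution:
        return step_distribution(self.pathways, self.rates.g, mode,
                                 max_sep=max_sep, dz=self.lattice.dz)

    def run_observables(self) -> RunObservables:
        return run_statistics(self.pathways, self.step_distribution(),
                              self.times, self.rates)

    def site_table(self) -> np.ndarray:
        """Columns (n, z_n, tfp, pT, pL) for export."""
        sp, pp = self.passage, self.pathways
        z = sp.n * self.lattice.dz / 2.0
        return np.column_stack([sp.n, z, sp.tfp, pp.pT, pp.pL])


def _zrun(params: MotorParams, rates: KineticRates, force: LoadForce,
          quad: QuadratureSpec) -> float:
    return StepModel(params, rates, force, quad=quad).run_observables().z_run


def stall_force(params: MotorParams, rates: KineticRates = KineticRates(),
                bracket: tuple[float, float] = (0.5, 3.0),
                quad: QuadratureSpec = QuadratureSpec(),
                xtol: float = 1e-3):
    """Backward force at which the mean run length crosses zero.

    Returns (F_stall, F_ratio1): the root of z_run(F) and, for
    comparison, the force at which the step ratio Pb/Pf equals one.
    """
    lo, hi = bracket
    f_lo = _zrun(params, rates, LoadForce(F=lo), quad)
    f_hi = _zrun(params, rates, LoadForce(F=hi), quad)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"run length does not change sign on [{lo}, {hi}] pN")
    F_stall = brentq(
        lambda F: _zrun(params, rates, LoadForce(F=F), quad), lo, hi,
        xtol=xtol)

    def log_ratio(F):
        m = StepModel(params, rates, LoadForce(F=F), quad=quad)
        return math.log(m.pathways.step_ratio)

    F_ratio = brentq(log_ratio, lo, hi, xtol=xtol)
    return float(F_stall), float(F_ratio)


def offaxis_scan(params: MotorParams, rates: KineticRates = KineticRates(),
                 F: float = 1.0,
                 theta_F_deg: Optional[np.ndarray] = None,
                 phi_F_deg: Optional[np.ndarray] = None,
                 quad: QuadratureSpec = QuadratureSpec()):
    """Percent change of run length over load directions at fixed |F|.

    Entry [i, j] is 100*(z_run(theta_i, phi_j)/z_run(0, 0) - 1).
    """
    if theta_F_deg is None:
        theta_F_deg = np.arange(0.0, 41.0, 5.0)
    if phi_F_deg is None:
        phi_F_deg = np.arange(-90.0, 91.0, 22.5)
    theta_F_deg = np.asarray(theta_F_deg, dtype=float)
    phi_F_deg = np.asarray(phi_F_deg, dtype=float)
    z0 = _zrun(params, rates, LoadForce(F=F), quad)
    out = np.empty((len(theta_F_deg), len(phi_F_deg)))
    for i, th in enumerate(theta_F_deg):
        for j, ph in enumerate(phi_F_deg):
            if th == 0.0 and ph == 0.0:
                out[i, j] = 0.0
                continue
            z = _zrun(params, rates,
                      LoadForce.from_degrees(F=F, theta_F=th, phi_F=ph),
                      quad)
            out[i, j] = 100.0 * (z / z0 - 1.0)
    return theta_F_deg, phi_F_deg, out


def constraint_scan(params: MotorParams, rates: KineticRates = KineticRates(),
                    mu_c_values: Optional[np.ndarray] = None,
                    theta_p_deg_values: Optional[np.ndarray] = None,
                    quad: QuadratureSpec = QuadratureSpec()):
    """Forward-step width and trailing binding time vs joint constraint.

    At zero load, returns (mu_c, theta_p_deg, sigma_step, tT) with
    sigma_step[i, j] the standard deviation of the forward-only step
    distribution and tT[i, j] the mean trailing binding time.
    """
    if mu_c_values is None:
        mu_c_values = np.arange(0.0, 10.5, 2.0)
    if theta_p_deg_values is None:
        theta_p_deg_values = np.array([83.0])
    mu_c_values = np.asarray(mu_c_values, dtype=float)
    theta_p_deg_values = np.asarray(theta_p_deg_values, dtype=float)
    sig = np.empty((len(mu_c_values), len(theta_p_deg_values)))
    tT = np.empty_like(sig)
    for j, tp in enumerate(theta_p_deg_values):
        for i, mu in enumerate(mu_c_values):
            p = params.with_(mu_c=mu, theta_p=math.radians(tp))
            m = StepModel(p, rates, quad=quad)
            sig[i, j] = m.step_distribution("forward-only").std()
            tT[i, j] = m.times.tT
    return mu_c_values, theta_p_deg_values, sig, tT


# ---------------------------------------------------------------------------
# kinetic Monte Carlo


@dataclass
class RunSample:
    """One simulated processive run."""

    length: float            # center-of-mass displacement, nm
    time: float              # ms
    steps: list = field(default_factory=list)  # head displacements (subunits)
    n_events: int = 0        # detachment events including the terminal one


def _sample_pathway(rng, pp: PathwayProbabilities, sp: SitePassage,
                    rates: KineticRates):
    """Draw one detachment event: branch, outcome site (or None for
    termination) and the elapsed time, following the competing Poisson
    processes of the kinetic network."""
    g = rates.g
    t = rng.exponential(rates.t_wait)
    trailing = rng.random() < g / (1.0 + g)
    td1 = rates.td1
    if trailing:
        # hydrolysis gate with bound-head detachment competing
        t_h = rng.exponential(rates.th)
        t_det = rng.exponential(td1)
        if t_det < t_h:
            return trailing, None, t + t_det
        t += t_h
        r, pen = sp.r_T, sp.penalty
    else:
        r, pen = sp.r_L, pen_b(sp)
    rate_tot = r + 1.0 / td1
    t += rng.exponential(1.0 / rate_tot)
    if rng.random() < (1.0 / td1) / rate_tot:
        return trailing, None, t
    w = pen / sp.tfp
    site = int(rng.choice(sp.n, p=w / w.sum()))
    return trailing, site, t


def pen_b(sp: SitePassage) -> np.ndarray:
    """Leading-branch penalties are the trailing ones mirrored in n."""
    b = sp.penalty[sp.n < 0]
    bval = float(b[0]) if len(b) else 1.0
    return np.where(sp.n < 0, 1.0, np.where(sp.n > 0, bval, 0.0))


def run_monte_carlo(params: MotorParams, rates: KineticRates = KineticRates(),
                    n_runs: int = 200, seed: int = 0,
                    force: LoadForce = LoadForce(),
                    force_rule: str = "constant",
                    trap_stiffness: float = 0.01,
                    trap_angles_deg: tuple[float, float] = (25.0, 0.0),
                    lattice: Optional[ActinLattice] = None,
                    quad: QuadratureSpec = QuadratureSpec(),
                    max_events: int = 10000) -> list[RunSample]:
    """Sample processive runs from the kinetic network.

    ``force_rule="constant"`` keeps the load fixed; ``"trap"`` emulates
    an optical trap: the magnitude grows linearly with the distance from
    the start (stiffness in pN/nm) and the pull rotates off-axis after
    the first two steps.  Deterministic for a given seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    lattice = lattice or ActinLattice()

    @lru_cache(maxsize=256)
    def state_for(Fq: float, th_deg: float, ph_deg: float):
        f = LoadForce.from_degrees(F=Fq, theta_F=th_deg, phi_F=ph_deg)
        sp = first_passage_times(params, f, lattice, quad=quad)
        pp = pathway_probabilities(sp, rates, params.b)
        return sp, pp

    runs = []
    dz2 = lattice.dz / 2.0
    for _ in range(n_runs):
        if force_rule == "constant":
            sp, pp = state_for(force.F, math.degrees(force.theta_F),
                               math.degrees(force.phi_F))
        sep_state = None
        z_head = 0.0
        t_tot = 0.0
        steps: list[int] = []
        n_events = 0
        while n_events < max_events:
            if force_rule == "trap":
                Fq = round(trap_stiffness * abs(z_head) / 0.05) * 0.05
                th, ph = (trap_angles_deg if len(steps) >= 2 else (0.0, 0.0))
                sp, pp = state_for(min(Fq, 3.0), th, ph)
            if sep_state is None:
                sep = head_separation_distribution(pp)
                sep_state = int(rng.choice(sep.n, p=sep.mass))
            n_events += 1
            trailing, site, t = _sample_pathway(rng, pp, sp, rates)
            t_tot += t
            if site is None:
                break
            if trailing:
                dn = sep_state + site
            else:
                dn = site - sep_state
            steps.append(dn)
            z_head += dn * dz2
            sep_state = abs(site)
        runs.append(RunSample(length=z_head / 2.0, time=t_tot,
                              steps=steps, n_events=n_events))
    return runs
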