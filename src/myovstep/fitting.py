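"""Fitting the stepping model to step-size histograms and force-response
constraints, plus a synthetic-histogram fixture generator.

Step histograms (two-column text: bin center in nm, count) are compared
to the model's forward-only step distribution after 1 nm localization
noise and identical binning, with the Kullback-Leibler divergence as
the objective.  Force-response fitting adjusts the binding penalty b
and capture radius a (optionally the power-stroke effectiveness T) so
the predicted stall force and zero-force run length match target
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares, minimize
from scipy.stats import qmc

from .density import QuadratureSpec, kl_divergence
from .observables import StepModel, measurement_convolve, stall_force
from .params import KineticRates, MotorParams, mutant_params

__all__ = [
    "FitSpec", "FitResult", "fit_step_distributions", "fit_force_response",
    "generate_fixture_histograms", "load_histogram", "nu_c_for_T",
]

#: Pseudo-mass added to empty histogram bins before the KL objective.
PSEUDO_MASS = 1e-6

#: Fast quadrature used inside optimization loops.
FIT_QUAD = QuadratureSpec(n_r=8, n_alpha=96, n_psi=32, prune=1e-14)

_ANGLES = ("theta_c", "dphi_ac", "theta_p")
_BOUNDS = {
    "theta_c": (30.0, 90.0),      # degrees
    "dphi_ac": (15.0, 120.0),     # degrees
    "theta_p": (40.0, 130.0),     # degrees
    "lp": (100.0, 375.0),         # nm
    "nu_c": (10.0, 2000.0),
    "b": (1e-3, 1.0),
    "a": (0.05, 2.0),
}


def nu_c_for_T(T: float, kappa: float) -> float:
    """Bound-leg constraint strength reproducing effectiveness T at L/lp
    = kappa (inverse of T = 1 + 20 nu/(20 + 7 kappa nu))."""
    denom = 20.0 - 7.0 * kappa * (T - 1.0)
    if denom <= 0:
        raise ValueError("requested T not attainable at this stiffness")
    return 20.0 * (T - 1.0) / denom


@dataclass
class FitSpec:
    """Specification of a fit.

    ``datasets`` maps mutant labels (4IQ/6IQ/8IQ) to histograms with
    rows (bin_center_nm, count).  ``free_params`` are varied; everything
    else is pinned at the values of ``base`` (per-mutant overrides come
    from the lever-arm length).  When ``fix_T`` is set, lp and nu_c
    moves are restricted to the constant-effectiveness curve.
    """

    datasets: list = field(default_factory=list)   # (label, ndarray)
    free_params: Sequence[str] = ("theta_c", "dphi_ac", "theta_p")
    base: MotorParams = field(default_factory=MotorParams)
    rates: KineticRates = field(default_factory=KineticRates)
    fix_T: Optional[float] = None
    stall_target: float = 1.9        # pN
    zrun_target: float = 1300.0      # nm
    noise_sigma: float = 1.0         # nm
    weights: Optional[Sequence[float]] = None
    quad: QuadratureSpec = FIT_QUAD

    def __post_init__(self) -> None:
        bad = [p for p in self.free_params if p not in _BOUNDS]
        if bad:
            raise ValueError(f"unknown free parameters {bad}")


@dataclass
class FitResult:
    params: dict
    objective: float
    per_dataset: dict
    converged: bool
    n_eval: int
    log: list


def load_histogram(path) -> np.ndarray:
    """Read a two-column (bin_center_nm, count) text histogram."""
    h = np.loadtxt(path, comments="#")
    if h.ndim != 2 or h.shape[1] < 2:
        raise ValueError("histogram must have two columns: center, count")
    return h[:, :2]


def _mutant_with(spec: FitSpec, label: str, values: dict) -> MotorParams:
    over = {}
    for key in ("b", "a"):
        if key in values:
            over[key] = values[key]
    for key in _ANGLES:
        if key in values:
            over[key] = math.radians(values[key])
        else:
            over[key] = getattr(spec.base, key)
    if "lp" in values:
        over["lp"] = values["lp"]
        if spec.fix_T is not None:
            kappa = mutant_params(label).L / values["lp"]
            over["nu_c"] = nu_c_for_T(spec.fix_T, kappa)
    if "nu_c" in values and spec.fix_T is None:
        over["nu_c"] = values["nu_c"]
    base_over = {k: getattr(spec.base, k)
                 for k in ("b", "a", "lp", "nu_c", "mu_c", "Dh", "kBT")
                 if k not in over}
    over.update(base_over)
    return mutant_params(label, **over)


def _model_histogram(params: MotorParams, rates: KineticRates,
                     centers: np.ndarray, sigma: float,
                     quad: QuadratureSpec) -> np.ndarray:
    model = StepModel(params, rates, quad=quad)
    dist = model.step_distribution("forward-only")
    bw = float(np.median(np.diff(centers)))
    c, h = measurement_convolve(dist, sigma=sigma, bin_width=bw)
    # align to requested centers
    out = np.zeros(len(centers))
    idx = np.round((centers - c[0]) / bw).astype(int)
    ok = (idx >= 0) & (idx < len(h))
    out[ok] = h[idx[ok]]
    return out


def _objective(spec: FitSpec, values: dict) -> tuple[float, dict]:
    per = {}
    weights = spec.weights or [1.0] * len(spec.datasets)
    total = 0.0
    for w, (label, hist) in zip(weights, spec.datasets):
        params = _mutant_with(spec, label, values)
        centers = hist[:, 0]
        emp = hist[:, 1].astype(float) + PSEUDO_MASS
        mod = _model_histogram(params, spec.rates, centers,
                               spec.noise_sigma, spec.quad) + PSEUDO_MASS
        kl = kl_divergence(emp, mod)
        per[label] = kl
        total += w * kl
    return total, per


def fit_step_distributions(spec: FitSpec, restarts: int = 5,
                           seed: int = 0, maxiter: int = 120,
                           x0: Optional[dict] = None,
                           polish: int = 3) -> FitResult:
    """Minimize the summed KL divergence over the free parameters.

    Bounded Nelder-Mead started from Latin-hypercube points (plus the
    optional ``x0`` start); each start is refined by ``polish``
    sequential simplex restarts (a fresh small simplex at the incumbent,
    which escapes the stagnation Nelder-Mead suffers in the curved,
    weakly identified (theta_c, theta_p) valley).  Angles in degrees.
    """
    if not spec.datasets:
        raise ValueError("no datasets to fit")
    names = list(spec.free_params)
    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])
    log = []
    n_eval = [0]

    def f(x):
        values = dict(zip(names, np.clip(x, lo, hi)))
        total, _ = _objective(spec, values)
        n_eval[0] += 1
        return total

    starts = []
    if x0 is not None:
        starts.append(np.array([x0[n] for n in names], dtype=float))
    n_lhs = max(0, restarts - len(starts))
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts.extend(lo + (hi - lo) * sampler.random(n_lhs))
    best_x, best_f, best_ok = None, np.inf, False
    # polish simplexes stay small (~1 degree for angles): large edges
    # wander along the weakly identified (theta_c, theta_p) valley
    scale = np.clip(0.02 * (hi - lo), 1e-3, 1.2)
    for s in starts:
        x = np.clip(np.asarray(s, dtype=float), lo, hi)
        ok = False
        for _ in range(max(1, polish)):
            sim = np.vstack([x] + [x + scale * e
                                   for e in np.eye(len(names))])
            res = minimize(f, x, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 0.03,
                                    "fatol": 1e-7,
                                    "initial_simplex": sim})
            x, ok = np.clip(res.x, lo, hi), bool(res.success)
        log.append((list(map(float, s)), float(res.fun), ok))
        if res.fun < best_f:
            best_x, best_f, best_ok = x, float(res.fun), ok
    values = dict(zip(names, best_x))
    total, per = _objective(spec, values)
    return FitResult(params={n: float(values[n]) for n in names},
                     objective=float(total), per_dataset=per,
                     converged=best_ok, n_eval=n_eval[0], log=log)


def fit_force_response(spec: FitSpec, fit_T: bool = False,
                       ratio_data: Optional[np.ndarray] = None,
                       bracket: tuple[float, float] = (0.5, 3.0)
                       ) -> dict:
    """Solve for the binding penalty b and capture radius a (optionally
    the power-stroke effectiveness T) matching the stall-force and
    zero-force run-length targets.

    With ``ratio_data`` (rows F_pN, Pb/Pf) the system is solved in a
    least-squares sense including the step-ratio curve; otherwise it is
    an exact 2-target root find at fixed T.
    """
    rates = spec.rates

    def observables_for(b, a, T=None):
        over = {"b": b, "a": a}
        if T is not None:
            over["nu_c"] = nu_c_for_T(T, spec.base.kappa)
        p = spec.base.with_(**over)
        Fs, _ = stall_force(p, rates, bracket=bracket, quad=spec.quad,
                            xtol=5e-3)
        z0 = StepModel(p, rates, quad=spec.quad).run_observables().z_run
        return p, Fs, z0

    def resid(x):
        b, a = 1.0 / (1.0 + math.exp(-x[0])), math.exp(x[1])
        T = math.exp(x[2]) if fit_T else None
        try:
            p, Fs, z0 = observables_for(b, a, T)
        except ValueError:
            return [10.0, 10.0] + ([10.0] * 0 if not fit_T else [10.0])
        r = [(Fs - spec.stall_target) / 0.1,
             (z0 - spec.zrun_target) / (0.05 * spec.zrun_target)]
        if ratio_data is not None:
            for F, target in ratio_data:
                from .params import LoadForce
                m = StepModel(p, rates, LoadForce(F=F), quad=spec.quad)
                r.append(math.log(m.pathways.step_ratio / target))
        return r

    x0 = [math.log(spec.base.b / (1.0 - spec.base.b)),
          math.log(spec.base.a)]
    if fit_T:
        x0.append(math.log(spec.base.T_eff))
    sol = least_squares(resid, x0, xtol=1e-6, ftol=1e-8, max_nfev=60)
    b = 1.0 / (1.0 + math.exp(-sol.x[0]))
    a = math.exp(sol.x[1])
    out = {"b": float(b), "a": float(a), "converged": bool(sol.success),
           "residual": float(np.linalg.norm(sol.fun))}
    if fit_T:
        out["T_eff"] = float(math.exp(sol.x[2]))
    return out


def alternate_refinement(spec: FitSpec, cycles: int = 3,
                         restarts: int = 1, seed: int = 0) -> dict:
    """Alternate step-distribution and force-response fits.

    Each cycle refits the structural angles against the histograms at
    the current (b, a), then recalibrates (b, a) to the stall-force and
    run-length targets at the refitted angles, feeding each result into
    the other.  Slow (every force-response solve embeds stall-force
    bisections); intended for offline calibration, not CI.
    """
    base = spec.base
    log = []
    last_fit = None
    for cycle in range(max(1, cycles)):
        step_res = fit_step_distributions(
            FitSpec(datasets=spec.datasets, free_params=spec.free_params,
                    base=base, rates=spec.rates, fix_T=spec.fix_T,
                    noise_sigma=spec.noise_sigma, weights=spec.weights,
                    quad=spec.quad),
            restarts=restarts, seed=seed + cycle)
        over = {k: math.radians(v) if k in _ANGLES else v
                for k, v in step_res.params.items()}
        base = base.with_(**over)
        force_res = fit_force_response(
            FitSpec(datasets=[], base=base, rates=spec.rates,
                    stall_target=spec.stall_target,
                    zrun_target=spec.zrun_target, quad=spec.quad))
        base = base.with_(b=force_res["b"], a=force_res["a"])
        log.append({"cycle": cycle, "step": step_res.params,
                    "step_objective": step_res.objective,
                    "force": force_res})
        last_fit = step_res
    return {"params": base, "history": log,
            "objective": last_fit.objective if last_fit else None}


def generate_fixture_histograms(mutants: Sequence[str] = ("4IQ", "6IQ", "8IQ"),
                                n_samples: int = 500, seed: int = 0,
                                noise_sigma: float = 1.0,
                                bin_width: float = 5.0,
                                base: Optional[MotorParams] = None,
                                rates: Optional[KineticRates] = None,
                                quad: QuadratureSpec = FIT_QUAD,
                                kind: str = "step") -> dict:
    """Synthetic histograms sampled from the model itself.

    For each mutant, draws ``n_samples`` events from the forward-only
    step distribution (``kind="step"``) or the bound-head separation
    distribution (``kind="separation"``, which peaks at the half-helical
    36 nm for the wild type), adds Gaussian localization noise, and
    bins.  Deterministic per seed.  Returns {label: array (center,
    count)}.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if kind not in ("step", "separation"):
        raise ValueError("kind must be 'step' or 'separation'")
    rng = np.random.default_rng(seed)
    rates = rates or KineticRates()
    out = {}
    for label in mutants:
        over = {}
        if base is not None:
            over = {k: getattr(base, k)
                    for k in ("lp", "nu_c", "theta_c", "theta_p", "mu_c",
                              "a", "b", "dphi_ac")}
        p = mutant_params(label, **over)
        model = StepModel(p, rates, quad=quad)
        if kind == "step":
            dist = model.step_distribution("forward-only")
        else:
            from .observables import head_separation_distribution
            dist = head_separation_distribution(model.pathways)
        z = rng.choice(dist.z, size=n_samples, p=dist.mass)
        if noise_sigma > 0:
            z = z + rng.normal(0.0, noise_sigma, size=n_samples)
        lo = math.floor(z.min() / bin_width) * bin_width
        hi = math.ceil(z.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, _ = np.histogram(z, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        out[label] = np.column_stack([centers, counts])
    return out
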