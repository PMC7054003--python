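"""Site-resolved first-passage kinetics and the five-pathway network.

The detached head's diffusive search is diffusion-limited onto each
binding site: the mean first-passage time to site n with the leg in the
azimuthal acceptance window is

    tfp_n = 1 / (4 pi a Dh * P(r_n, window)),

with a the capture radius, Dh the head diffusivity and P the joint
equilibrium density.  Competing Poisson processes (binding to each site,
bound-head detachment at 1/td1, hydrolysis at 1/th for the trailing
pathway) then give per-site step/stomp probabilities, the aggregate
forward/backward step, stomp and termination probabilities, and the
mean trailing/leading binding times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .density import DensityModel, QuadratureSpec
from .lattice import ActinLattice
from .params import KineticRates, LoadForce, MotorParams

__all__ = [
    "SitePassage", "PathwayProbabilities", "BindingTimes",
    "first_passage_times", "pathway_probabilities", "binding_times",
]

#: Joint densities below this floor (nm^-3) are treated as unreachable.
DENSITY_FLOOR = 1e-12


@dataclass
class SitePassage:
    """Mean first-passage times to each reachable site.

    ``n``/``tfp`` are aligned arrays over sites with density above the
    floor; ``penalty`` holds the recovery-stroke penalties b_n for the
    trailing pathway (1 forward, b backward).
    """

    n: np.ndarray
    tfp: np.ndarray          # ms
    penalty: np.ndarray      # b_n for the trailing pathway
    r_T: float               # sum b_n / tfp_n, 1/ms
    r_L: float               # sum b_-n / tfp_n, 1/ms
    t_diff: float            # [sum 1/tfp_n]^-1, ms

    def tfp_map(self) -> dict[int, float]:
        return dict(zip(self.n.tolist(), self.tfp.tolist()))


@dataclass
class PathwayProbabilities:
    """Per-site and aggregate probabilities of the kinetic pathways."""

    n: np.ndarray
    pT: np.ndarray           # trailing-detachment branch, per site
    pL: np.ndarray           # leading-detachment branch, per site
    g: float
    Pf: float = field(init=False)
    Pb: float = field(init=False)
    PTs: float = field(init=False)
    PLs: float = field(init=False)
    Pt: float = field(init=False)

    def __post_init__(self) -> None:
        g = self.g
        wT, wL = g / (1.0 + g), 1.0 / (1.0 + g)
        fwd = self.n > 0
        self.Pf = float(wT * self.pT[fwd].sum())
        self.PTs = float(wT * self.pT[~fwd].sum())
        self.Pb = float(wL * self.pL[~fwd].sum())
        self.PLs = float(wL * self.pL[fwd].sum())
        self.Pt = 1.0 - float(wT * self.pT.sum() + wL * self.pL.sum())

    @property
    def step_ratio(self) -> float:
        """Backward-to-forward step ratio Pb/Pf."""
        return self.Pb / self.Pf

    def pT_map(self) -> dict[int, float]:
        return dict(zip(self.n.tolist(), self.pT.tolist()))

    def pL_map(self) -> dict[int, float]:
        return dict(zip(self.n.tolist(), self.pL.tolist()))


@dataclass(frozen=True)
class BindingTimes:
    """Mean binding times after trailing / leading detachment (ms)."""

    tT: float
    tL: float


def first_passage_times(params: MotorParams,
                        force: LoadForce = LoadForce(),
                        lattice: Optional[ActinLattice] = None,
                        model: Optional[DensityModel] = None,
                        quad: QuadratureSpec = QuadratureSpec()
                        ) -> SitePassage:
    """Mean first-passage time to each binding site with orientation.

    Sites whose window joint density falls below the floor are dropped
    (effectively infinite passage time); the occupied site n=0 is never
    a target.
    """
    lattice = lattice or ActinLattice()
    if model is None:
        model = DensityModel(params, force, quad=quad)
    n, _, joint = model.site_densities(lattice)
    keep = joint > DENSITY_FLOOR
    if not np.any(keep):
        raise ValueError("no reachable binding site: all site densities "
                         "fall below the density floor")
    n, joint = n[keep], joint[keep]
    tfp = 1.0 / (4.0 * np.pi * params.a * params.Dh * joint)
    penalty = np.where(n > 0, 1.0, params.b)
    inv = 1.0 / tfp
    r_T = float(np.sum(penalty * inv))
    # leading pathway: penalties mirrored (b_-n): forward sites penalized
    pen_L = np.where(n < 0, 1.0, params.b)
    r_L = float(np.sum(pen_L * inv))
    t_diff = 1.0 / float(np.sum(inv))
    return SitePassage(n=n, tfp=tfp, penalty=penalty, r_T=r_T, r_L=r_L,
                       t_diff=t_diff)


def pathway_probabilities(sp: SitePassage, rates: KineticRates,
                          b: float) -> PathwayProbabilities:
    """Probabilities of the five pathways from the site passage times.

    Trailing branch (detachment -> hydrolysis -> search):
        pT_n = b_n td1^2 / [tfp_n (1 + r_T td1)(td1 + th)];
    leading branch keeps its ADP (no hydrolysis, mirrored penalties):
        pL_n = b_-n td1 / [tfp_n (1 + r_L td1)].
    Termination absorbs the remainder, so the five pathways sum to one.
    """
    td1, th = rates.td1, rates.th
    pen_T = np.where(sp.n > 0, 1.0, b)
    pen_L = np.where(sp.n < 0, 1.0, b)
    pT = pen_T * td1**2 / (sp.tfp * (1.0 + sp.r_T * td1) * (td1 + th))
    pL = pen_L * td1 / (sp.tfp * (1.0 + sp.r_L * td1))
    return PathwayProbabilities(n=sp.n, pT=pT, pL=pL, g=rates.g)


def binding_times(sp: SitePassage, rates: KineticRates) -> BindingTimes:
    """Mean binding times: tT = 1/r_T + th (hydrolysis gates the trailing
    leg), tL = 1/r_L (the leading leg rebinds without hydrolysis)."""
    if sp.r_T <= 0 or sp.r_L <= 0:
        raise ValueError("zero aggregate binding rate: lattice unreachable")
    return BindingTimes(tT=1.0 / sp.r_T + rates.th, tL=1.0 / sp.r_L)
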