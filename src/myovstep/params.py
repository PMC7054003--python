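"""Model parameters for the myosin V stepping model.

All lengths are in nm, times in ms, forces in pN, energies in units of
``kBT``.  Angles are stored internally in radians; the constructors accept
degrees because the structural literature quotes degrees.

The default values are the fitted wild-type (6IQ) parameter set: leg
contour length L = 35 nm, persistence length lp = 350 nm, bound-leg
power-stroke constraint angle 65 deg with strength nu_c = 261, inter-leg
preferred angle 83 deg with strength mu_c = 5 kBT, capture radius
a = 0.4 nm, binding penalty b = 0.045, azimuthal acceptance half-width
55.6 deg and head diffusivity Dh = 5.7e-7 cm^2/s = 5.7e4 nm^2/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KBT_PN_NM",
    "MotorParams",
    "LoadForce",
    "KineticRates",
    "PowerStroke",
    "JointPotentialSpec",
    "mutant_params",
]

#: Thermal energy in pN nm at T ~ 297 K.  The model is formulated in kBT
#: units; this constant only enters through the dimensionless combination
#: beta*F*L for the load force.
KBT_PN_NM = 4.1

# Effective head-head exclusion lengths (nm) calibrated per lever-arm
# length: 4IQ (L=25), 6IQ (L=35), 8IQ (L=45).
_DV_BY_L = {25.0: 20.0, 35.0: 27.5, 45.0: 35.0}


def _dv_for_length(L: float) -> float:
    """Effective exclusion length for a given leg length (linear in L)."""
    if L in _DV_BY_L:
        return _DV_BY_L[L]
    # interpolate/extrapolate linearly: dV ~ 0.75 L + 1.25
    return 0.75 * L + 1.25


@dataclass(frozen=True)
class MotorParams:
    """Structural and binding parameters of the two-legged motor."""

    L: float = 35.0          # leg contour length, nm
    lp: float = 350.0        # persistence length, nm
    theta_c: float = math.radians(65.0)   # bound-leg constraint polar angle
    nu_c: float = 261.0      # bound-leg tangent constraint strength, kBT
    theta_p: float = math.radians(83.0)   # preferred inter-leg angle
    mu_c: float = 5.0        # inter-leg constraint strength, kBT
    a: float = 0.4           # capture radius, nm
    b: float = 0.045         # binding penalty for disfavoured sites
    dphi_ac: float = math.radians(55.6)   # azimuthal acceptance half-width
    Dh: float = 5.7e4        # head diffusion constant, nm^2/ms
    dV: float = 27.5         # head-head exclusion length, nm
    kBT: float = KBT_PN_NM   # thermal energy, pN nm

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("leg length L must be positive")
        if self.lp < self.L:
            raise ValueError(
                "stiff regime assumed: persistence length lp must be >= L"
            )
        if not 0.0 < self.b <= 1.0:
            raise ValueError("binding penalty b must lie in (0, 1]")
        if self.a <= 0:
            raise ValueError("capture radius a must be positive")
        if not 0.0 <= self.dphi_ac <= math.pi:
            raise ValueError("acceptance half-width must lie in [0, pi]")
        if self.mu_c < 0 or self.nu_c < 0:
            raise ValueError("constraint strengths must be nonnegative")

    @classmethod
    def from_degrees(cls, *, theta_c=65.0, theta_p=83.0, dphi_ac=55.6,
                     **kwargs) -> "MotorParams":
        return cls(
            theta_c=math.radians(theta_c),
            theta_p=math.radians(theta_p),
            dphi_ac=math.radians(dphi_ac),
            **kwargs,
        )

    @property
    def kappa(self) -> float:
        """Flexibility parameter L/lp (<= 1 in the stiff regime)."""
        return self.L / self.lp

    @property
    def T_eff(self) -> float:
        """Zero-force power-stroke effectiveness 1 + 20 nu_c/(20 + 7 kappa nu_c)."""
        return 1.0 + 20.0 * self.nu_c / (20.0 + 7.0 * self.kappa * self.nu_c)

    @property
    def u_c(self) -> np.ndarray:
        """Preferred bound-leg direction: in the x-z plane, theta_c from z."""
        return np.array(
            [math.sin(self.theta_c), 0.0, math.cos(self.theta_c)]
        )

    @property
    def ta(self) -> float:
        """Time to diffuse one capture radius, a^2/Dh (ms)."""
        return self.a**2 / self.Dh

    def with_(self, **kwargs) -> "MotorParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def mutant_params(mutant: str = "6IQ", **kwargs) -> MotorParams:
    """Parameter set for a lever-arm-length mutant.

    ``mutant`` is one of ``"4IQ"``, ``"6IQ"`` (wild type) or ``"8IQ"``;
    the head plus each IQ motif contributes ~5 nm of contour length, so
    L = 25, 35, 45 nm respectively.  The exclusion length dV scales with
    the leg length.
    """
    lengths = {"4IQ": 25.0, "6IQ": 35.0, "8IQ": 45.0}
    try:
        L = lengths[mutant]
    except KeyError:
        raise ValueError(f"unknown mutant {mutant!r}; expected one of {sorted(lengths)}")
    defaults = dict(L=L, dV=_dv_for_length(L))
    defaults.update(kwargs)
    return MotorParams(**defaults)


@dataclass(frozen=True)
class LoadForce:
    """External load transmitted through the tail to the leg joint.

    The direction is ``(sin th_F cos ph_F, sin th_F sin ph_F, -cos th_F)``
    so that ``theta_F = phi_F = 0`` is a pure backward (minus-end) pull.
    """

    F: float = 0.0                 # magnitude, pN
    theta_F: float = 0.0           # polar angle from -z, radians
    phi_F: float = 0.0             # azimuth from +x, radians

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("force magnitude must be nonnegative")

    @classmethod
    def from_degrees(cls, F: float = 0.0, theta_F: float = 0.0,
                     phi_F: float = 0.0) -> "LoadForce":
        return cls(F=F, theta_F=math.radians(theta_F),
                   phi_F=math.radians(phi_F))

    @property
    def direction(self) -> np.ndarray:
        st, ct = math.sin(self.theta_F), math.cos(self.theta_F)
        return np.array(
            [st * math.cos(self.phi_F), st * math.sin(self.phi_F), -ct]
        )

    @property
    def vector(self) -> np.ndarray:
        """Force vector in pN."""
        return self.F * self.direction


@dataclass(frozen=True)
class PowerStroke:
    """Effective bound-leg constraint, possibly renormalized by load."""

    T_eff: float
    u_c: np.ndarray
    u_c_prime: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.u_c_prime is None:
            object.__setattr__(self, "u_c_prime", self.u_c)

    @property
    def theta_c_prime(self) -> float:
        """Effective constraint polar angle arctan(x / z) of u_c'."""
        return math.atan2(self.u_c_prime[0], self.u_c_prime[2])


def effective_constraint(params: MotorParams, force: LoadForce) -> PowerStroke:
    """Renormalize the power stroke under load.

    The load acts on the joint, adding an aligning field beta*F*L F_hat to
    the orientational field T u_c of the bound-leg end direction:

        T' = sqrt(T^2 + (bFL)^2 + 2 T bFL F_hat . u_c),
        u_c' = (T u_c + bFL F_hat) / T'.
    """
    T = params.T_eff
    uc = params.u_c
    if force.F == 0.0:
        return PowerStroke(T_eff=T, u_c=uc, u_c_prime=uc)
    bfl = force.F * params.L / params.kBT
    fhat = force.direction
    vec = T * uc + bfl * fhat
    Tp = math.sqrt(float(vec @ vec))
    if Tp < 1e-12:
        raise ValueError(
            "degenerate effective constraint: load exactly cancels the "
            "power stroke direction"
        )
    return PowerStroke(T_eff=Tp, u_c=uc, u_c_prime=vec / Tp)


@dataclass(frozen=True)
class KineticRates:
    """Mean timescales of the chemical steps (ms).

    td1: trailing-head (ADP-release limited) detachment time, default 1/12 s.
    td2: leading-head detachment time, default 1/1.5 s; the gating ratio
    g = td2/td1 > 1 expresses preferential rear-head release.
    th:  ATP hydrolysis time, default 1/750 s.
    """

    td1: float = 1000.0 / 12.0
    td2: float = 1000.0 / 1.5
    th: float = 1000.0 / 750.0

    def __post_init__(self) -> None:
        if min(self.td1, self.td2, self.th) <= 0:
            raise ValueError("all kinetic times must be positive")
        if self.td2 <= self.td1:
            raise ValueError("gating requires td2 > td1")

    @property
    def g(self) -> float:
        return self.td2 / self.td1

    @property
    def t_wait(self) -> float:
        """Mean waiting time between detachment events, g td1/(1+g)."""
        return self.g * self.td1 / (1.0 + self.g)


@dataclass(frozen=True)
class JointPotentialSpec:
    """Inter-leg joint potential.

    ``form="cosine"``: mu_c [1 - cos(theta_J - theta_p)] (default).
    ``form="quartic"``: mu_c [d^2/2 + h3 d^3/6 + h4 d^4/24], d = theta_J - theta_p.
    """

    form: str = "cosine"
    mu_c: float = 5.0
    theta_p: float = math.radians(83.0)
    h3: float = 0.0
    h4: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("cosine", "quartic"):
            raise ValueError("form must be 'cosine' or 'quartic'")

    def energy(self, theta_J) -> np.ndarray:
        """Joint energy in kBT for inter-leg angle(s) theta_J (radians)."""
        d = np.asarray(theta_J, dtype=float) - self.theta_p
        if self.form == "cosine":
            return self.mu_c * (1.0 - np.cos(d))
        return self.mu_c * (d**2 / 2.0 + self.h3 * d**3 / 6.0
                            + self.h4 * d**4 / 24.0)


def joint_potential(theta_J, spec: JointPotentialSpec) -> np.ndarray:
    """Energy (kBT) of the inter-leg joint at angle ``theta_J``."""
    return spec.energy(theta_J)
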