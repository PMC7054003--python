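"""Configuration and output glue: YAML parameter files with validated
defaults, CSV/matrix export with metadata headers, and reproducibility
manifests.

Configs quote angles in degrees (as the structural literature does);
they are converted to radians when the dataclasses are built.  An empty
file yields the full fitted wild-type defaults.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .lattice import ActinLattice
from .params import KineticRates, LoadForce, MotorParams

__all__ = ["Config", "load_config", "save_config", "write_table",
           "read_table", "write_manifest"]

_MOTOR_KEYS = {
    "L": "L", "lp": "lp", "nu_c": "nu_c", "mu_c": "mu_c", "a": "a",
    "b": "b", "Dh": "Dh", "dV": "dV", "kBT": "kBT",
    "theta_c_deg": "theta_c", "theta_p_deg": "theta_p",
    "dphi_ac_deg": "dphi_ac",
}
_RATE_KEYS = {"td1_ms": "td1", "td2_ms": "td2", "th_ms": "th"}
_FORCE_KEYS = {"F_pN": "F", "theta_F_deg": "theta_F", "phi_F_deg": "phi_F"}
_LATTICE_KEYS = {"R": "R", "dz": "dz", "n_max": "n_max"}
_ANGLE_KEYS = {"theta_c_deg", "theta_p_deg", "dphi_ac_deg",
               "theta_F_deg", "phi_F_deg"}


@dataclass
class Config:
    """Validated parameter set with fitted wild-type defaults."""

    motor: MotorParams = field(default_factory=MotorParams)
    rates: KineticRates = field(default_factory=KineticRates)
    force: LoadForce = field(default_factory=LoadForce)
    lattice: ActinLattice = field(default_factory=ActinLattice)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        m, r, f, lat = self.motor, self.rates, self.force, self.lattice
        d = {
            "motor": {
                "L": m.L, "lp": m.lp, "nu_c": m.nu_c, "mu_c": m.mu_c,
                "a": m.a, "b": m.b, "Dh": m.Dh, "dV": m.dV, "kBT": m.kBT,
                "theta_c_deg": math.degrees(m.theta_c),
                "theta_p_deg": math.degrees(m.theta_p),
                "dphi_ac_deg": math.degrees(m.dphi_ac),
            },
            "rates": {"td1_ms": r.td1, "td2_ms": r.td2, "th_ms": r.th},
            "force": {"F_pN": f.F, "theta_F_deg": math.degrees(f.theta_F),
                      "phi_F_deg": math.degrees(f.phi_F)},
            "lattice": {"R": lat.R, "dz": lat.dz, "n_max": lat.n_max},
        }
        if self.extra:
            d.update(self.extra)
        return d

    def derived_summary(self) -> dict:
        """Derived quantities a user should see echoed: T, g, beta*F*L."""
        return {
            "T_eff": self.motor.T_eff,
            "gating_ratio_g": self.rates.g,
            "beta_F_L": self.force.F * self.motor.L / self.motor.kBT,
            "ta_ns": self.motor.ta * 1e6,
        }


def _build_section(cls, mapping: dict, section: dict, name: str):
    kwargs = {}
    for key, value in section.items():
        if key not in mapping:
            raise ValueError(f"unknown key {key!r} in config section {name!r}")
        attr = mapping[key]
        if key in _ANGLE_KEYS:
            value = math.radians(float(value))
        kwargs[attr] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {name!r}: {exc}") from exc


_KNOWN_EXTRA = {"steps", "force_scan", "offaxis", "constraint_scan",
                "runs", "bd", "fit", "contours", "seed"}


def load_config(path) -> Config:
    """Load and validate a YAML config; missing keys take defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"motor", "rates", "force", "lattice"} | _KNOWN_EXTRA
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config section {key!r}")
    motor = _build_section(MotorParams, _MOTOR_KEYS, raw.get("motor") or {},
                           "motor")
    rates = _build_section(KineticRates, _RATE_KEYS, raw.get("rates") or {},
                           "rates")
    force = _build_section(LoadForce, _FORCE_KEYS, raw.get("force") or {},
                           "force")
    lattice = _build_section(ActinLattice, _LATTICE_KEYS,
                             raw.get("lattice") or {}, "lattice")
    extra = {k: raw[k] for k in raw
             if k in _KNOWN_EXTRA}
    return Config(motor=motor, rates=rates, force=force, lattice=lattice,
                  extra=extra)


def save_config(config: Config, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_table(path, array: np.ndarray, columns: list[str],
                metadata: Optional[dict] = None,
                overwrite: bool = True) -> None:
    """CSV with '#'-prefixed JSON metadata header lines."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(path)
    lines = []
    if metadata:
        lines.append("# " + json.dumps(metadata, sort_keys=True, default=float))
    lines.append(",".join(columns))
    arr = np.atleast_2d(array)
    for row in arr:
        lines.append(",".join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_table(path):
    """Read a CSV written by write_table -> (array, columns, metadata)."""
    lines = Path(path).read_text().splitlines()
    meta = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        try:
            meta = json.loads(lines[i].lstrip("# "))
        except json.JSONDecodeError:
            pass
        i += 1
    columns = lines[i].split(",")
    data = np.array([[float(v) for v in ln.split(",")]
                     for ln in lines[i + 1:] if ln.strip()])
    return data, columns, meta


def write_manifest(path, config: Config, seed: Optional[int] = None,
                   outputs: Optional[dict] = None) -> None:
    """JSON manifest: full parameter echo, derived state, seed, and
    checksums of output files, enabling bit-exact replay."""
    import myovstep

    entry = {
        "package": "myovstep",
        "version": getattr(myovstep, "__version__", "unknown"),
        "config": config.to_dict(),
        "derived": config.derived_summary(),
        "seed": seed,
        "outputs": {},
    }
    if outputs:
        for name, fpath in outputs.items():
            digest = hashlib.sha256(Path(fpath).read_bytes()).hexdigest()
            entry["outputs"][name] = {"path": str(fpath), "sha256": digest}
    Path(path).write_text(json.dumps(entry, indent=1, sort_keys=True,
                                     default=float))
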