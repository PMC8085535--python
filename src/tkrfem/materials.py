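"""Compressible neo-Hookean constitutive math and the implant material library.

The deformable implant parts (CoCrMo femoral component, UHMWPE tibial insert)
use the compressible neo-Hookean strain-energy density

    Psi(F) = G/2 (I1 - 3) - G ln J + lambda/2 (ln J)^2,

with I1 = tr(F^T F), J = det F, and Lame coefficients derived from the
engineering constants via E = 2G(1+v), lambda = 2Gv/(1-2v). The Cauchy
stress follows from the standard derivation of that energy:

    sigma = (1/J) [ G (B - I) + lambda ln J I ],   B = F F^T.

Units are the consistent mm-N-MPa system used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "NeoHookeanMaterial",
    "RigidMaterial",
    "MaterialError",
    "InvertedElementError",
    "lame_from_engineering",
    "strain_energy",
    "cauchy_stress",
    "default_library",
]


class MaterialError(ValueError):
    """Invalid material parameters."""


class InvertedElementError(ValueError):
    """Deformation gradient with non-positive determinant."""


def lame_from_engineering(E: float, v: float) -> tuple[float, float]:
    """Shear modulus G and Lame lambda (MPa) from Young's modulus and
    Poisson's ratio. The incompressible limit v = 0.5 is unsupported."""
    if E <= 0:
        raise MaterialError(f"Young's modulus must be positive, got {E}")
    if not 0 <= v < 0.5:
        raise MaterialError(f"Poisson's ratio must lie in [0, 0.5), got {v}")
    G = E / (2.0 * (1.0 + v))
    lam = 2.0 * G * v / (1.0 - 2.0 * v)
    return G, lam


@dataclass
class NeoHookeanMaterial:
    name: str
    E: float  # MPa
    v: float
    G: float = field(init=False)
    lam: float = field(init=False)

    def __post_init__(self) -> None:
        self.G, self.lam = lame_from_engineering(self.E, self.v)

    def to_dict(self) -> dict:
        return {"name": self.name, "type": "neo-Hookean", "E": self.E, "v": self.v}


@dataclass
class RigidMaterial:
    """Rigid-body material; density is solver bookkeeping only (quasi-static
    analyses never use inertia). Units tonne/mm^3."""

    name: str
    density: float = 7.8e-9

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise MaterialError("density must be positive")

    def to_dict(self) -> dict:
        return {"name": self.name, "type": "rigid body", "density": self.density}


def _check_F(F) -> tuple[np.ndarray, float]:
    F = np.asarray(F, dtype=float).reshape(3, 3)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvertedElementError(f"det(F) = {J} <= 0 (inverted element)")
    return F, J


def strain_energy(F, m: NeoHookeanMaterial) -> float:
    """Strain-energy density Psi(F) in MPa; zero iff F is a rotation."""
    F, J = _check_F(F)
    I1 = float(np.trace(F.T @ F))
    lnJ = np.log(J)
    return 0.5 * m.G * (I1 - 3.0) - m.G * lnJ + 0.5 * m.lam * lnJ**2


def cauchy_stress(F, m: NeoHookeanMaterial) -> np.ndarray:
    """Cauchy stress (MPa, symmetric), consistent with :func:`strain_energy`."""
    F, J = _check_F(F)
    B = F @ F.T
    return (m.G * (B - np.eye(3)) + m.lam * np.log(J) * np.eye(3)) / J


def first_pk_stress(F, m: NeoHookeanMaterial) -> np.ndarray:
    """First Piola-Kirchhoff stress, P = d Psi / d F = J sigma F^{-T}."""
    F, J = _check_F(F)
    return J * cauchy_stress(F, m) @ np.linalg.inv(F).T


def default_library() -> dict[str, object]:
    """Material assignments of the six-part TKR model: CoCrMo femoral
    component, UHMWPE tibial insert, rigid bones and tray."""
    return {
        "CoCrMo": NeoHookeanMaterial("CoCrMo", E=210000.0, v=0.3),
        "UHMWPE": NeoHookeanMaterial("UHMWPE", E=1200.0, v=0.46),
        "rigid_femur": RigidMaterial("rigid_femur"),
        "rigid_tibia": RigidMaterial("rigid_tibia"),
        "rigid_fibula": RigidMaterial("rigid_fibula"),
        "rigid_tray": RigidMaterial("rigid_tray"),
    }


def library_to_yaml(lib: dict) -> str:
    return yaml.safe_dump({k: v.to_dict() for k, v in lib.items()}, sort_keys=False)


def library_from_yaml(text: str) -> dict:
    out = {}
    for key, d in yaml.safe_load(text).items():
        d = dict(d)
        kind = d.pop("type")
        if kind == "neo-Hookean":
            out[key] = NeoHookeanMaterial(**d)
        elif kind == "rigid body":
            out[key] = RigidMaterial(**d)
        else:
            raise MaterialError(f"unknown material type {kind!r}")
    return out
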