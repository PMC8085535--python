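"""Tension-only nonlinear spring model of the collateral ligaments.

Each retained collateral (MCL, LCL) is a point-to-point spring with the
piecewise force-strain law of Blankevoort-type knee models::

    f(eps) = 0                          eps < 0          (slack)
    f(eps) = k * eps^2 / (4 * eps_l)    0 <= eps <= 2*eps_l  (toe region)
    f(eps) = k * (eps - eps_l)          eps > 2*eps_l    (linear region)

where ``eps = (L - L0)/L0``. ``2*eps_l`` is the threshold strain at which the
quadratic toe region hands over to the linear region; both branches equal
``k*eps_l`` there, which is the only reading of the law that keeps the force
continuous. ``k`` is a stiffness in N (strains are dimensionless), ``eps_l``
defaults to 0.03.

The zero-load length follows from the reference strain ``eps_r`` (the strain
at the full-extension reference pose, negative = slack)::

    L0 = Lr / (eps_r + 1)

Default parameters: MCL k = 8250 N, eps_r = 0.04; LCL k = 6000 N,
eps_r = -0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "LigamentBundle",
    "LigamentError",
    "zero_load_length",
    "ligament_force",
    "make_default_bundles",
    "perturb_attachments",
    "scale_parameter",
    "DIRECTION_VECTORS",
    "DEFAULT_EPS_L",
]

DEFAULT_EPS_L = 0.03

#: Anatomical direction tags on the model axes (medial = -x, anterior = +y).
DIRECTION_VECTORS = {
    "anterior": np.array([0.0, 1.0, 0.0]),
    "posterior": np.array([0.0, -1.0, 0.0]),
    "medial": np.array([-1.0, 0.0, 0.0]),
    "lateral": np.array([1.0, 0.0, 0.0]),
    "proximal": np.array([0.0, 0.0, 1.0]),
    "distal": np.array([0.0, 0.0, -1.0]),
}


class LigamentError(ValueError):
    """Invalid ligament parameters or state."""


def zero_load_length(L_r: float, eps_r: float) -> float:
    """Length at which the ligament first becomes taut, ``Lr/(eps_r+1)``."""
    if eps_r <= -1.0:
        raise LigamentError(f"reference strain must exceed -1, got {eps_r}")
    if L_r <= 0:
        raise LigamentError(f"reference length must be positive, got {L_r}")
    return L_r / (eps_r + 1.0)


@dataclass
class LigamentBundle:
    """A collateral ligament as parallel tension-only spring strands.

    ``k`` is the total bundle stiffness; with ``n_strands > 1`` it is split
    equally so the bundle total force equals the single-spring value.
    """

    name: str
    origin: np.ndarray        # femoral attachment (mm)
    insertion: np.ndarray     # tibial/fibular attachment (mm)
    k: float                  # N
    eps_r: float              # reference strain at the full-extension pose
    eps_l: float = DEFAULT_EPS_L
    n_strands: int = 1
    L_r: float = field(init=False)
    L_0: float = field(init=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if self.k <= 0:
            raise LigamentError("stiffness k must be positive")
        if self.eps_l <= 0:
            raise LigamentError("linear-limit strain eps_l must be positive")
        if self.n_strands < 1:
            raise LigamentError("n_strands must be >= 1")
        L_r = float(np.linalg.norm(self.insertion - self.origin))
        if L_r == 0:
            raise LigamentError(f"{self.name}: coincident origin and insertion")
        self.L_r = L_r
        self.L_0 = zero_load_length(L_r, self.eps_r)

    def strain(self, L: float) -> float:
        return (L - self.L_0) / self.L_0

    def force(self, L) -> float:
        return ligament_force(L, self)

    def force_at_pose(self, origin_world: np.ndarray) -> tuple[float, np.ndarray, float]:
        """Tension, unit direction (origin -> insertion) and length for a
        transformed femoral origin."""
        d = self.insertion - origin_world
        L = float(np.linalg.norm(d))
        return ligament_force(L, self), d / L, L

    def strand_attachments(self, spread_axis=None, spread: float = 0.0):
        """Per-strand attachment pairs, distributed along a line segment."""
        if self.n_strands == 1 or spread == 0.0:
            return [(self.origin.copy(), self.insertion.copy())] * self.n_strands
        axis = np.asarray(spread_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        offs = np.linspace(-spread / 2, spread / 2, self.n_strands)
        return [(self.origin + t * axis, self.insertion + t * axis) for t in offs]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "origin": self.origin.tolist(),
            "insertion": self.insertion.tolist(),
            "k": self.k,
            "eps_r": self.eps_r,
            "eps_l": self.eps_l,
            "n_strands": self.n_strands,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LigamentBundle":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LigamentBundle":
        return cls.from_dict(yaml.safe_load(text))


def ligament_force(L, bundle: LigamentBundle):
    """Bundle tension (N) at current length ``L`` (mm); tension-only,
    continuous and non-decreasing in strain."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise LigamentError("ligament length must be positive")
    eps = (L - bundle.L_0) / bundle.L_0
    k, el = bundle.k, bundle.eps_l
    toe = 0.25 * k * eps**2 / el
    lin = k * (eps - el)
    f = np.where(eps < 0, 0.0, np.where(eps <= 2 * el, toe, lin))
    return float(f) if np.isscalar(f) or f.ndim == 0 else f


def make_default_bundles(
    femur_landmarks: dict,
    tibia_landmarks: dict,
    fibula_landmarks: dict,
    eps_l: float = DEFAULT_EPS_L,
) -> list[LigamentBundle]:
    """MCL and LCL with the standard stiffness/reference-strain parameters.

    ``L_r`` is measured from the supplied attachment points at the reference
    (full-extension) pose; ``L_0`` follows from the reference strain.
    """
    mcl = LigamentBundle(
        name="MCL",
        origin=femur_landmarks["mcl_origin"],
        insertion=tibia_landmarks["mcl_insertion"],
        k=8250.0,
        eps_r=0.04,
        eps_l=eps_l,
    )
    lcl = LigamentBundle(
        name="LCL",
        origin=femur_landmarks["lcl_origin"],
        insertion=fibula_landmarks["lcl_insertion"],
        k=6000.0,
        eps_r=-0.05,
        eps_l=eps_l,
    )
    return [mcl, lcl]


def perturb_attachments(
    b: LigamentBundle, direction: str, distance: float
) -> LigamentBundle:
    """Translate BOTH attachments by the same vector.

    Shifting origin and insertion together keeps the difference vector, hence
    ``L_r`` and ``L_0``, unchanged — the attachment-position sensitivity mode
    that varies ligament geometry without re-tensioning the spring.
    """
    if distance < 0:
        raise LigamentError("perturbation distance must be >= 0")
    try:
        v = DIRECTION_VECTORS[direction]
    except KeyError:
        raise LigamentError(
            f"unknown direction {direction!r}; expected one of {sorted(DIRECTION_VECTORS)}"
        ) from None
    shift = distance * v
    return replace(b, origin=b.origin + shift, insertion=b.insertion + shift)


def scale_parameter(b: LigamentBundle, which: str, pct: float) -> LigamentBundle:
    """Scale ``eps_r`` or ``k`` by a signed percentage.

    Scaling is multiplicative (``value * (1 + pct/100)``). When ``eps_r``
    changes, ``L_0`` is recomputed with ``L_r`` held fixed: the perturbation
    changes pre-tension, not geometry. An absolute-offset mode for ``eps_r``
    is available as ``which='eps_r_abs'`` (then ``pct`` is the offset * 100).
    """
    if pct <= -100:
        raise LigamentError("percentage must exceed -100")
    if which == "k":
        return replace(b, k=b.k * (1.0 + pct / 100.0))
    if which == "eps_r":
        new = b.eps_r * (1.0 + pct / 100.0)
    elif which == "eps_r_abs":
        new = b.eps_r + pct / 100.0
    else:
        raise LigamentError(f"unknown parameter {which!r}; expected 'eps_r' or 'k'")
    if new <= -1.0:
        raise LigamentError(f"scaled reference strain {new} is <= -1")
    return replace(b, eps_r=new)
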