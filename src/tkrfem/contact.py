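"""Reduced-order quasi-static tibiofemoral contact solver.

The full deformable FE contact problem is replaced by a Winkler elastic
foundation: the insert's articular faces act as independent compressive
springs, with per-face pressure ``p = k_f * g+`` where ``g+`` is the positive
part of the penetration of the rigid femoral surface, measured from each face
centroid along the face normal. The foundation modulus uses the confined
elastic layer formula

    k_f = E (1 - v) / [ (1 + v) (1 - 2 v) h ],

with the insert's UHMWPE constants and the local layer thickness ``h``
measured from the mesh (articular face to insert bottom).

Pose and equilibrium
--------------------
The femur (and rigidly attached femoral component) has three enabled DOFs:
prescribed flexion ``theta`` about the medial-lateral axis through the condyle
centers, solved vertical offset ``u_z``, and solved varus-valgus angle ``phi``
about the anterior-posterior axis through the joint-line center. For each
gait sample the solver finds ``(u_z, phi)`` satisfying vertical force and
y-moment equilibrium of contact + ligament wrenches against the applied axial
force Fz and drive moment My, by damped Newton iteration with a numerical
Jacobian and a bisection fallback on the vertical DOF, warm-started along
the cycle.

Sign conventions (medial = -x): positive contact pressure pushes the femur
up; taut collaterals pull it down; a positive applied My loads the lateral
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AlignmentPerturbation, TriSurface, rotation_about
from .ligaments import LigamentBundle
from .materials import NeoHookeanMaterial
from .synthetic import SyntheticGeomParams, default_landmarks, make_synthetic_tkr

__all__ = [
    "RigidSphereSet",
    "RigidPlane",
    "RigidMeshSurface",
    "FoundationModel",
    "JointPose",
    "PressureField",
    "ConvergenceError",
    "foundation_modulus",
    "settle_to_contact",
    "solve_timestep",
    "run_gait",
    "peak_metrics",
    "build_synthetic_contact_model",
]


class ConvergenceError(RuntimeError):
    """Equilibrium iteration failed within budget."""


def foundation_modulus(E: float, v: float, h) -> np.ndarray:
    """Confined-layer Winkler modulus k_f (MPa/mm) for layer thickness h."""
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("layer thickness must be positive")
    return E * (1.0 - v) / ((1.0 + v) * (1.0 - 2.0 * v) * h)


# ---------------------------------------------------------------------------
# rigid articular surfaces
# ---------------------------------------------------------------------------

class RigidSphereSet:
    """Union of spheres (the synthetic condyles), with closed-form gap query.

    The gap from point ``p`` along unit direction ``n`` is the smaller root of
    ``|p + t n - c|^2 = R^2`` (negative when the point has penetrated), taken
    over all spheres; +inf if the line misses every sphere.
    """

    def __init__(self, centers, radius: float):
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.radius = float(radius)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "RigidSphereSet":
        return RigidSphereSet(self.centers @ np.asarray(R).T + np.asarray(t), self.radius)

    def gap_along(self, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        dirs = np.atleast_2d(dirs)
        best = np.full(len(points), np.inf)
        for c in self.centers:
            d = points - c
            b = np.einsum("ij,ij->i", d, dirs)
            cc = np.einsum("ij,ij->i", d, d) - self.radius**2
            disc = b * b - cc
            hit = disc >= 0
            t1 = np.where(hit, -b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
            best = np.minimum(best, t1)
        return best


class RigidPlane:
    """Half-space bounded by a plane (flat-punch oracle surface).

    ``point`` is on the plane, ``normal`` points out of the rigid body (down,
    toward the foundation)."""

    def __init__(self, point, normal):
        self.point = np.asarray(point, dtype=float).reshape(3)
        n = np.asarray(normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "RigidPlane":
        R = np.asarray(R)
        return RigidPlane(R @ self.point + np.asarray(t), R @ self.normal)

    def gap_along(self, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        dirs = np.atleast_2d(dirs)
        denom = dirs @ self.normal
        num = (self.point - points) @ self.normal
        out = np.full(len(points), np.inf)
        ok = np.abs(denom) > 1e-12
        out[ok] = num[ok] / denom[ok]
        return out


class RigidMeshSurface:
    """Triangulated rigid surface with a ray-cast gap query (general meshes).

    The gap rule matches the analytic surfaces: for a point outside the body
    it is the distance along the query direction to the nearest entry
    crossing; for a penetrated point it is (negative) the distance back to
    the surface. Slower than the analytic surfaces (dense numpy ray casting,
    no spatial index); meant for ingested implant geometry at modest face
    counts and as a cross-check of the analytic queries.
    """

    def __init__(self, surface: TriSurface):
        self.surface = surface

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "RigidMeshSurface":
        return RigidMeshSurface(self.surface.transformed(R, t))

    def gap_along(self, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        from .geometry import points_inside, ray_mesh_intersections

        points = np.atleast_2d(points)
        dirs = np.atleast_2d(dirs)
        inside = points_inside(self.surface, points)
        crossings = ray_mesh_intersections(self.surface, points, dirs)
        out = np.full(len(points), np.inf)
        for i, ts in enumerate(crossings):
            if inside[i]:
                behind = ts[ts < 0]
                if len(behind):
                    out[i] = behind.max()
            else:
                ahead = ts[ts >= 0]
                if len(ahead):
                    out[i] = ahead.min()
        return out


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class JointPose:
    """Pose of the femur chain: prescribed flexion, solved height and tilt."""

    theta: float  # flexion, deg
    u_z: float    # vertical offset, mm (negative = settled down)
    phi: float    # varus-valgus angle, deg (positive tilts lateral side down)


@dataclass
class PressureField:
    """Per-face contact pressure on the insert and its summary metrics."""

    pressures: np.ndarray      # MPa, >= 0, one per contact face
    areas: np.ndarray          # mm^2
    centroids: np.ndarray      # mm
    normals: np.ndarray        # unit, pointing toward the femur

    @property
    def face_forces(self) -> np.ndarray:
        return self.pressures * self.areas

    @property
    def total_force(self) -> float:
        """Total vertical (z) contact force, N."""
        return float(np.sum(self.pressures * self.areas * self.normals[:, 2]))

    @property
    def max_pressure(self) -> float:
        return float(self.pressures.max()) if len(self.pressures) else 0.0

    @property
    def cop(self) -> np.ndarray:
        """Pressure-area-weighted centroid of the contact patch (mm)."""
        w = self.pressures * self.areas
        tot = w.sum()
        if tot == 0:
            return np.full(3, np.nan)
        return (w[:, None] * self.centroids).sum(axis=0) / tot

    def compartment_force(self, side: str) -> float:
        """Vertical contact force carried by the medial (x<0) or lateral
        (x>0) compartment."""
        mask = self.centroids[:, 0] < 0 if side == "medial" else self.centroids[:, 0] >= 0
        return float(
            np.sum(self.pressures[mask] * self.areas[mask] * self.normals[mask, 2])
        )


@dataclass
class FoundationModel:
    """Elastic-foundation contact model of the tibiofemoral joint."""

    contact_centroids: np.ndarray     # insert articular face centroids (mm)
    contact_normals: np.ndarray       # unit normals toward the femur
    contact_areas: np.ndarray         # mm^2
    k_f: np.ndarray                   # per-face foundation modulus (MPa/mm)
    layer_thickness: np.ndarray       # per-face h (mm)
    rigid_surface: object             # femoral articular surface (body frame)
    ligaments: list = field(default_factory=list)
    flexion_axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vv_axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alignment_pivot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    settled_u_z: float | None = None

    def __post_init__(self) -> None:
        self.contact_centroids = np.asarray(self.contact_centroids, dtype=float).reshape(-1, 3)
        self.contact_normals = np.asarray(self.contact_normals, dtype=float).reshape(-1, 3)
        self.contact_areas = np.asarray(self.contact_areas, dtype=float).ravel()
        self.k_f = np.broadcast_to(
            np.asarray(self.k_f, dtype=float), self.contact_areas.shape
        ).copy()
        self.layer_thickness = np.broadcast_to(
            np.asarray(self.layer_thickness, dtype=float), self.contact_areas.shape
        ).copy()
        if np.any(self.contact_areas <= 0):
            raise ValueError("contact face areas must be positive")
        if np.any(self.k_f <= 0):
            raise ValueError("foundation modulus must be positive")

    # -- pose machinery ---------------------------------------------------
    def pose_transform(self, pose: JointPose) -> tuple[np.ndarray, np.ndarray]:
        """Rigid map of femur-frame points to world: flexion about the ML
        axis through ``flexion_axis_point``, then varus-valgus about the AP
        axis through ``vv_axis_point``, then vertical translation."""
        R1, t1 = rotation_about((1.0, 0.0, 0.0), pose.theta, self.flexion_axis_point)
        R2, t2 = rotation_about((0.0, 1.0, 0.0), pose.phi, self.vv_axis_point)
        R = R2 @ R1
        t = R2 @ t1 + t2 + np.array([0.0, 0.0, pose.u_z])
        return R, t

    def posed_surface(self, pose: JointPose):
        R, t = self.pose_transform(pose)
        return self.rigid_surface.transformed(R, t)

    def gaps(self, pose: JointPose) -> np.ndarray:
        surf = self.posed_surface(pose)
        return surf.gap_along(self.contact_centroids, self.contact_normals)

    def pressures(self, pose: JointPose) -> PressureField:
        g = self.gaps(pose)
        pen = np.where(np.isfinite(g), np.maximum(-g, 0.0), 0.0)
        return PressureField(
            pressures=self.k_f * pen,
            areas=self.contact_areas,
            centroids=self.contact_centroids,
            normals=self.contact_normals,
        )

    def ligament_wrench(self, pose: JointPose) -> tuple[float, float, list]:
        """Vertical ligament force on the femur (N, negative = pulling down)
        and its y-moment about the varus-valgus axis point; plus a per-bundle
        (name, tension, length) log."""
        R, t = self.pose_transform(pose)
        fz = 0.0
        my = 0.0
        log = []
        for b in self.ligaments:
            o_w = R @ b.origin + t
            f, direction, L = b.force_at_pose(o_w)
            force = f * direction  # on the femur, toward the insertion
            r = o_w - self.vv_axis_point
            fz += force[2]
            my += r[2] * force[0] - r[0] * force[2]
            log.append((b.name, f, L))
        return fz, my, log

    def residual(self, pose: JointPose, Fz: float, My: float) -> np.ndarray:
        """(vertical force, y-moment) equilibrium residual on the femur."""
        pf = self.pressures(pose)
        w = pf.pressures * pf.areas
        contact_fz = float(np.sum(w * pf.normals[:, 2]))
        r = pf.centroids - self.vv_axis_point
        contact_my = float(
            np.sum(w * (r[:, 2] * pf.normals[:, 0] - r[:, 0] * pf.normals[:, 2]))
        )
        lig_fz, lig_my, _ = self.ligament_wrench(pose)
        return np.array([contact_fz + lig_fz - Fz, contact_my + lig_my + My])

    # -- perturbation -----------------------------------------------------
    def with_alignment(
        self, p: AlignmentPerturbation, clearance: float = 0.5
    ) -> "FoundationModel":
        """Malalign the femoral component relative to the femur bone.

        The component geometry is transformed in the femur body frame about
        ``alignment_pivot``; ligament attachments (on the bones) stay put.
        If the tilt consumes the initial apex gap, the component is lifted
        vertically to restore ``clearance`` mm before settling — the vertical
        position is a solved, force-driven DOF, so this pre-translation does
        not change the equilibrium solution.
        """
        if p.is_rotation and p.pivot is None:
            p = replace(p, pivot=self.alignment_pivot)
        R, t = p.transform()
        model = replace(self, rigid_surface=self.rigid_surface.transformed(R, t),
                        settled_u_z=None)
        g = model.gaps(JointPose(0.0, 0.0, 0.0))
        g = g[np.isfinite(g)]
        if len(g) and g.min() < clearance:
            lift = clearance - float(g.min())
            model = replace(
                model,
                rigid_surface=model.rigid_surface.transformed(
                    np.eye(3), np.array([0.0, 0.0, lift])
                ),
            )
        return model

    def with_ligaments(self, bundles: list) -> "FoundationModel":
        return replace(self, ligaments=list(bundles), settled_u_z=None)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def settle_to_contact(
    model: FoundationModel,
    tol: float = 1e-6,
    theta: float = 0.0,
    max_drop: float = 200.0,
) -> float:
    """Largest downward vertical offset with maximum penetration <= tol (mm).

    Bisection on the signed-gap function; the initial pose must be gap-open
    everywhere (the settling step starts above first contact).
    """

    def max_pen(u):
        g = model.gaps(JointPose(theta, u, 0.0))
        g = g[np.isfinite(g)]
        return float(np.maximum(-g, 0.0).max()) if len(g) else 0.0

    if max_pen(0.0) > tol:
        raise ValueError(
            "initial pose already interpenetrates; review geometry/alignment"
        )
    lo, hi = 0.0, None  # lo: feasible (pen <= tol), hi: infeasible
    step = 1.0
    u = 0.0
    while hi is None:
        u -= step
        if -u > max_drop:
            raise ConvergenceError("no contact found within max_drop")
        if max_pen(u) > tol:
            hi = u
        else:
            lo = u
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if max_pen(mid) > tol:
            hi = mid
        else:
            lo = mid
        if lo - hi < tol * 0.5:
            break
    model.settled_u_z = lo
    return lo


def _scaled(r: np.ndarray, Fz: float, My: float) -> np.ndarray:
    return np.array([r[0] / max(abs(Fz), 1.0), r[1] / max(abs(My), 1.0)])


def solve_timestep(
    model: FoundationModel,
    theta: float,
    Fz: float,
    My: float,
    prev_pose: JointPose | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[JointPose, PressureField]:
    """Solve (u_z, phi) for one gait sample.

    Converged when |F_contact,z + F_lig,z - Fz| <= tol*max(Fz,1) and the
    y-moment residual <= tol*max(|My|,1). Damped Newton with a forward-
    difference Jacobian; if Newton stalls, the vertical DOF is bracketed by
    bisection at fixed phi and Newton restarts from there.
    """
    if Fz < 0:
        raise ValueError("axial force must be >= 0")
    if model.settled_u_z is None:
        settle_to_contact(model, theta=theta)
    if Fz == 0.0:
        pose = JointPose(theta, model.settled_u_z, prev_pose.phi if prev_pose else 0.0)
        pf = model.pressures(pose)
        pf.pressures[:] = 0.0
        return pose, pf

    if prev_pose is not None:
        x = np.array([prev_pose.u_z, np.deg2rad(prev_pose.phi)])
    else:
        x = np.array([model.settled_u_z - 1e-3, 0.0])
    try:
        x = _newton_solve(model, theta, Fz, My, x, tol, max_iter)
    except ConvergenceError:
        x = _nested_solve(model, theta, Fz, My, x, tol)
    pose = JointPose(theta, x[0], np.rad2deg(x[1]))
    return pose, model.pressures(pose)


def _newton_solve(model, theta, Fz, My, x, tol, max_iter):
    """Damped 2D Newton on (u_z, phi_rad); fast path."""

    def res(xv):
        return model.residual(JointPose(theta, xv[0], np.rad2deg(xv[1])), Fz, My)

    h = np.array([1e-5, 1e-6])  # FD steps: mm, rad
    x = x.copy()
    r = res(x)
    best = (np.linalg.norm(_scaled(r, Fz, My)), x.copy())
    stalls = 0
    for _ in range(max_iter):
        rs = _scaled(r, Fz, My)
        if np.all(np.abs(rs) <= tol):
            return x
        J = np.empty((2, 2))
        for j in range(2):
            xp = x.copy()
            xp[j] += h[j]
            J[:, j] = (res(xp) - r) / h[j]
        if abs(np.linalg.det(J)) < 1e-12 or not np.all(np.isfinite(J)):
            # out of contact: push down along z until stiffness appears
            x[0] -= 0.05
            r = res(x)
            continue
        dx = np.linalg.solve(J, -r)
        # damping: backtrack until the scaled residual decreases
        lam = 1.0
        norm0 = np.linalg.norm(rs)
        for _ in range(10):
            xn = x + lam * dx
            rn = res(xn)
            if np.linalg.norm(_scaled(rn, Fz, My)) < norm0:
                break
            lam *= 0.5
        else:
            # stalled: re-anchor the vertical DOF by bisection, then retry
            stalls += 1
            if stalls > 3:
                raise ConvergenceError("Newton stalled")
            x = np.array([_bisect_uz(model, theta, x[1], Fz, My), x[1]])
            r = res(x)
            continue
        x, r = xn, rn
        nrm = np.linalg.norm(_scaled(r, Fz, My))
        if nrm < best[0]:
            best = (nrm, x.copy())
    raise ConvergenceError(
        f"no equilibrium in {max_iter} iterations; best scaled residual {best[0]:.3e} "
        f"at u_z={best[1][0]:.4f} mm, phi={np.rad2deg(best[1][1]):.4f} deg"
    )


def _nested_solve(model, theta, Fz, My, x0, tol, phi_span=0.35):
    """Robust fallback: inner scalar solve of vertical equilibrium, outer
    root-find of the moment residual over phi (rad). Handles contact-set
    changes that defeat the 2D Newton (e.g. tilted components near My = 0).
    """
    from scipy.optimize import brentq

    uz_cache = {"u": x0[0]}

    def moment_at(phi):
        u = _solve_uz(model, theta, phi, Fz, tol, u_start=uz_cache["u"])
        uz_cache["u"] = u
        return model.residual(JointPose(theta, u, np.rad2deg(phi)), Fz, My)[1]

    phi0 = x0[1]
    m0 = moment_at(phi0)
    if abs(m0) <= tol * max(abs(My), 1.0):
        return np.array([uz_cache["u"], phi0])
    # expand a bracket around the current phi (the moment residual is
    # decreasing in phi: positive residual means rotate toward +phi)
    direction = 1.0 if m0 > 0 else -1.0
    step = 0.01
    prev, cur, m_prev = phi0, phi0, m0
    for _ in range(40):
        cur = prev + direction * step
        m_cur = moment_at(cur)
        if m_cur == 0.0:
            return np.array([uz_cache["u"], cur])
        if np.sign(m_cur) != np.sign(m_prev):
            break
        prev, m_prev = cur, m_cur
        step *= 1.5
        if abs(cur - phi0) > phi_span:
            raise ConvergenceError("could not bracket the varus-valgus DOF")
    else:
        raise ConvergenceError("could not bracket the varus-valgus DOF")
    lo, hi = sorted([prev, cur])
    phi = brentq(moment_at, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    u = _solve_uz(model, theta, phi, Fz, tol, u_start=uz_cache["u"])
    r = model.residual(JointPose(theta, u, np.rad2deg(phi)), Fz, My)
    if np.any(np.abs(_scaled(r, Fz, My)) > tol):
        raise ConvergenceError(
            f"nested solve residual {r} exceeds tolerance at phi={np.rad2deg(phi):.4f} deg"
        )
    return np.array([u, phi])


def _solve_uz(model, theta, phi_rad, Fz, tol, u_start=None):
    """Scalar vertical equilibrium at fixed phi: Newton with a bisection
    safety net (the vertical residual is monotone in u_z)."""
    phi = np.rad2deg(phi_rad)

    def fres(u):
        return model.residual(JointPose(theta, u, phi), Fz, 0.0)[0]

    target = tol * max(Fz, 1.0) * 0.5
    u = model.settled_u_z if u_start is None else u_start
    lo = hi = None  # lo: residual > 0 (too deep), hi: residual < 0
    for _ in range(100):
        r = fres(u)
        if abs(r) <= target:
            return u
        if r > 0:
            lo = u
        else:
            hi = u
        h = 1e-6
        dr = (fres(u + h) - r) / h
        if dr < 1e-9:
            un = u - 0.05 if r < 0 else u + 0.05
        else:
            un = u - r / dr
        if lo is not None and hi is not None and not (min(lo, hi) < un < max(lo, hi)):
            un = 0.5 * (lo + hi)
        u = un
    raise ConvergenceError(f"vertical equilibrium not met at phi={phi:.4f} deg")


def _bisect_uz(model, theta, phi_rad, Fz, My, budget=200):
    phi = np.rad2deg(phi_rad)

    def fres(u):
        return model.residual(JointPose(theta, u, phi), Fz, My)[0]

    hi = model.settled_u_z  # contact-free side: residual = -Fz < 0
    lo = hi
    step = 0.05
    for _ in range(budget):
        lo -= step
        if fres(lo) > 0:
            break
        step *= 1.5
    else:
        raise ConvergenceError("bisection could not bracket the vertical DOF")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fres(mid) > 0:
            lo = mid
        else:
            hi = mid
        if abs(fres(mid)) <= 1e-7 * max(Fz, 1.0):
            return mid
    return 0.5 * (lo + hi)


@dataclass
class GaitStepRecord:
    time: float
    pose: JointPose
    pressure: PressureField
    residual: np.ndarray
    ligament_log: list


def run_gait(model: FoundationModel, bc, tol: float = 1e-6) -> list[GaitStepRecord]:
    """Solve every sample of a gait record, warm-starting along the cycle."""
    if model.settled_u_z is None:
        settle_to_contact(model, theta=float(bc.flexion[0]))
    records: list[GaitStepRecord] = []
    prev = None
    for i in range(len(bc)):
        try:
            pose, pf = solve_timestep(
                model, float(bc.flexion[i]), float(bc.Fz[i]), float(bc.My[i]),
                prev_pose=prev, tol=tol,
            )
        except ConvergenceError as exc:
            raise ConvergenceError(f"sample {i} (t={bc.t[i]:.4f}s): {exc}") from exc
        r = model.residual(pose, float(bc.Fz[i]), float(bc.My[i])) if bc.Fz[i] > 0 else np.zeros(2)
        _, _, lig = model.ligament_wrench(pose)
        records.append(GaitStepRecord(float(bc.t[i]), pose, pf, r, lig))
        prev = pose
    return records


def peak_metrics(traj: list, bc) -> dict:
    """Peak contact metrics at the two axial-force maxima of stance.

    Finds the interior local maxima of the total vertical contact force,
    picks the ones nearest 20% and 80% of stance (earlier sample wins ties)
    and reports the per-face maximum pressures there. With fewer than two
    interior maxima the 20%/80% time indices are used directly (``fallback``
    flag set).
    """
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least 2 samples")
    force = np.array([rec.pressure.total_force for rec in traj])
    s = bc.stance_fraction
    interior = [
        i for i in range(1, len(force) - 1)
        if force[i] > force[i - 1] and force[i] >= force[i + 1]
    ]
    fallback = len(interior) < 2
    idx = []
    for target in (0.20, 0.80):
        if fallback:
            idx.append(int(np.argmin(np.abs(s - target))))
        else:
            cands = sorted(interior, key=lambda i: (abs(s[i] - target), s[i]))
            idx.append(cands[0])
    i1, i2 = idx
    return {
        "P1": traj[i1].pressure.max_pressure,
        "P2": traj[i2].pressure.max_pressure,
        "F1": float(force[i1]),
        "F2": float(force[i2]),
        "i1": i1,
        "i2": i2,
        "fallback": fallback,
    }


# ---------------------------------------------------------------------------
# synthetic model assembly
# ---------------------------------------------------------------------------

def build_synthetic_contact_model(
    params: SyntheticGeomParams | None = None,
    insert_material: NeoHookeanMaterial | None = None,
    ligaments: list[LigamentBundle] | None = None,
) -> FoundationModel:
    """Foundation model of the synthetic assembly.

    Contact faces are the insert top faces inside the dish recesses (centroid
    below the plateau); the rigid femoral surface is the analytic two-sphere
    condyle set. The foundation modulus uses the UHMWPE constants and the
    local insert thickness under each face.
    """
    p = params or SyntheticGeomParams()
    mat = insert_material or NeoHookeanMaterial("UHMWPE", E=1200.0, v=0.46)
    parts = make_synthetic_tkr(p)
    insert = parts["tibial_insert"]
    normals = insert.face_normals()
    centroids = insert.face_centroids()
    areas = insert.face_areas()
    in_dish = (centroids[:, 2] < -1e-9) & (normals[:, 2] > 0.5)
    centroids, normals, areas = centroids[in_dish], normals[in_dish], areas[in_dish]
    h = centroids[:, 2] + p.insert_thickness
    k_f = foundation_modulus(mat.E, mat.v, h)
    zf = p.condyle_centers[0, 2]
    fem_bounds = parts["femoral_component"].bounds()
    if ligaments is None:
        lm = default_landmarks(p)
        from .ligaments import make_default_bundles

        ligaments = make_default_bundles(lm["femur"], lm["tibia"], lm["fibula"])
    return FoundationModel(
        contact_centroids=centroids,
        contact_normals=normals,
        contact_areas=areas,
        k_f=k_f,
        layer_thickness=h,
        rigid_surface=RigidSphereSet(p.condyle_centers, p.condyle_radius),
        ligaments=ligaments,
        flexion_axis_point=np.array([0.0, 0.0, zf]),
        vv_axis_point=np.zeros(3),
        alignment_pivot=fem_bounds.mean(axis=0),
    )
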