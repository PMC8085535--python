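"""Surface and volume mesh types, I/O, validity checks and rigid alignment.

All geometry lives in a single model frame, in millimetres:

* ``x`` — medial-lateral axis (flexion-extension rotation axis); medial is
  ``-x`` for the right knee modeled here.
* ``y`` — anterior-posterior axis (varus-valgus rotation axis); anterior is
  ``+y``.
* ``z`` — vertical / longitudinal axis (joint distraction-compression);
  proximal is ``+z``.

Motion-lab data recorded in an ``x``-forward / ``y``-right / ``z``-up frame is
converted into this frame at ingestion with a fixed rotation
(:data:`LAB_TO_MODEL`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "TriSurface",
    "TetMesh",
    "ValidationReport",
    "AlignmentPerturbation",
    "GeometryError",
    "load_surface",
    "save_surface",
    "validate_surface",
    "tetrahedralize",
    "apply_alignment",
    "rotation_about",
    "reflect_x",
    "LAB_TO_MODEL",
]

#: Vertex-merge tolerance (mm).
MERGE_TOL = 1e-9

#: Fixed rotation taking the gait-lab frame (x forward, y right, z up) into
#: the model frame (x medial-lateral/right, y anterior, z up).
LAB_TO_MODEL = np.array(
    [
        [0.0, 1.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
    ]
)
# Note: the lab y axis (subject's right) maps onto model x, the lab x axis
# (forward) onto model y (anterior).


class GeometryError(ValueError):
    """Raised for invalid geometry input or parameters."""


@dataclass
class TriSurface:
    """A triangulated surface mesh (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError(f"face indices out of range for part {self.name!r}")

    # -- basic queries ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy(), self.name)

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def edges(self) -> np.ndarray:
        """All (unsorted) directed edges, one row per face edge."""
        f = self.faces
        return np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(c, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n = np.linalg.norm(c, axis=1)
        n[n == 0] = 1.0
        return c / n[:, None]

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem (signed)."""
        v = self.vertices
        f = self.faces
        return float(np.einsum("ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))) / 6.0

    @property
    def is_watertight(self) -> bool:
        return validate_surface(self).watertight

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "TriSurface":
        """Rigidly transformed copy, ``v -> R v + t``."""
        return TriSurface(self.vertices @ np.asarray(R).T + np.asarray(t), self.faces.copy(), self.name)


@dataclass
class TetMesh:
    """A 4-node tetrahedral volume mesh."""

    nodes: np.ndarray
    tets: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise GeometryError(f"tet indices out of range for part {self.name!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        n = self.nodes
        t = self.tets
        a = n[t[:, 1]] - n[t[:, 0]]
        b = n[t[:, 2]] - n[t[:, 0]]
        c = n[t[:, 3]] - n[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def volume(self) -> float:
        return float(self.tet_volumes().sum())


@dataclass
class ValidationReport:
    """Summary of surface-mesh defects."""

    n_vertices: int
    n_faces: int
    boundary_edges: int
    nonmanifold_edges: int
    duplicate_vertices: int
    degenerate_faces: list = field(default_factory=list)

    @property
    def n_degenerate_faces(self) -> int:
        return len(self.degenerate_faces)

    @property
    def watertight(self) -> bool:
        return self.boundary_edges == 0

    @property
    def clean(self) -> bool:
        return (
            self.watertight
            and self.nonmanifold_edges == 0
            and self.duplicate_vertices == 0
            and not self.degenerate_faces
        )


@dataclass
class AlignmentPerturbation:
    """A rigid malalignment of an implant component.

    ``varus``/``valgus`` rotate about the anterior-posterior (y) axis,
    ``internal_rotation``/``external_rotation`` about the vertical (z) axis.
    For rotations ``magnitude`` is in degrees, for ``translation`` in mm
    (along ``axis``). Sign conventions (medial = -x, right knee): varus drops
    the medial side, internal rotation turns the anterior face medially.
    """

    mode: str
    magnitude: float
    pivot: np.ndarray | None = None
    axis: np.ndarray | None = None

    _MODE_AXES = {
        "varus": (0.0, -1.0, 0.0),
        "valgus": (0.0, 1.0, 0.0),
        "internal_rotation": (0.0, 0.0, 1.0),
        "external_rotation": (0.0, 0.0, -1.0),
        "flexion": (1.0, 0.0, 0.0),
    }

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise GeometryError("perturbation magnitude must be >= 0")
        if self.pivot is not None:
            self.pivot = np.asarray(self.pivot, dtype=float).reshape(3)
        if self.mode in self._MODE_AXES:
            if self.axis is None:
                self.axis = np.array(self._MODE_AXES[self.mode])
        elif self.mode == "translation":
            if self.axis is None:
                raise GeometryError("translation perturbation requires an axis")
        else:
            raise GeometryError(f"unknown perturbation mode {self.mode!r}")
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise GeometryError("zero-length perturbation axis")
        self.axis = self.axis / norm

    @property
    def is_rotation(self) -> bool:
        return self.mode != "translation"

    def transform(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(R, t)`` with points mapping as ``p -> R p + t``."""
        if self.is_rotation:
            if self.pivot is None:
                raise GeometryError(
                    "rotation perturbation needs a pivot (none set and no context default)"
                )
            return rotation_about(self.axis, self.magnitude, self.pivot)
        return np.eye(3), self.axis * self.magnitude

    def inverse(self) -> "AlignmentPerturbation":
        return replace(self, axis=-self.axis)


def rotation_about(axis, angle_deg: float, pivot) -> tuple[np.ndarray, np.ndarray]:
    """Rotation by ``angle_deg`` about ``axis`` through ``pivot`` as ``(R, t)``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("zero-length rotation axis")
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm).as_matrix()
    pivot = np.asarray(pivot, dtype=float)
    return R, pivot - R @ pivot


# ---------------------------------------------------------------------------
# validation / I/O
# ---------------------------------------------------------------------------

def validate_surface(s: TriSurface, degenerate_area_tol: float = 1e-12) -> ValidationReport:
    """Count boundary edges (holes), non-manifold edges, duplicate vertices
    and degenerate (area ~ 0) faces. The surface is watertight iff there are
    no boundary edges."""
    if s.n_faces == 0:
        return ValidationReport(s.n_vertices, 0, 0, 0, _duplicate_count(s.vertices), [])
    und = np.sort(s.edges(), axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    nonmanifold = int((counts > 2).sum())
    degenerate = np.flatnonzero(s.face_areas() <= degenerate_area_tol).tolist()
    return ValidationReport(
        n_vertices=s.n_vertices,
        n_faces=s.n_faces,
        boundary_edges=boundary,
        nonmanifold_edges=nonmanifold,
        duplicate_vertices=_duplicate_count(s.vertices),
        degenerate_faces=degenerate,
    )


def _duplicate_count(vertices: np.ndarray) -> int:
    if len(vertices) < 2:
        return 0
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(MERGE_TOL)
    if not pairs:
        return 0
    # number of vertices that would disappear on merging coincident groups
    parent = list(range(len(vertices)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = {find(i) for i, _ in enumerate(parent)}
    return len(vertices) - len(roots)


def _merge_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL):
    """Merge vertices closer than ``tol`` and reindex faces."""
    if len(vertices) == 0:
        return vertices, faces
    tree = cKDTree(vertices)
    groups = tree.query_ball_point(vertices, tol)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    new_pts = []
    for i, grp in enumerate(groups):
        rep = min(grp)
        if rep == i:
            remap[i] = len(new_pts)
            new_pts.append(vertices[i])
        else:
            remap[i] = remap[rep]
    return np.asarray(new_pts), remap[faces]


def load_surface(
    path,
    fmt: str | None = None,
    name: str = "",
    drop_degenerate: bool = False,
) -> TriSurface:
    """Load a triangulated surface (binary or ASCII STL; OFF/PLY also accepted).

    Vertices are deduplicated within :data:`MERGE_TOL`. If the surface is
    watertight and inside-out (negative enclosed volume) the winding is
    flipped so normals point outward. Degenerate (zero-area) faces are listed
    in the validation report and removed only when ``drop_degenerate`` is set.
    """
    try:
        mesh = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize I/O failure modes
        raise GeometryError(f"cannot read surface {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        mesh = mesh.to_mesh()
    if len(getattr(mesh, "faces", [])) == 0:
        raise GeometryError(f"cannot read surface {path}: no faces parsed")
    verts, faces = _merge_vertices(
        np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)
    )
    s = TriSurface(verts, faces, name or str(path))
    report = validate_surface(s)
    if drop_degenerate and report.degenerate_faces:
        keep = np.ones(s.n_faces, dtype=bool)
        keep[report.degenerate_faces] = False
        s = TriSurface(s.vertices, s.faces[keep], s.name)
        report = validate_surface(s)
    s.validation = report
    if report.watertight and s.volume() < 0:
        s = TriSurface(s.vertices, s.faces[:, ::-1], s.name)
        s.validation = report
    return s


def save_surface(s: TriSurface, path, fmt: str | None = None) -> None:
    """Write a surface as STL (or any format trimesh can export)."""
    s.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# point containment / ray casting (vectorized numpy; no spatial index)
# ---------------------------------------------------------------------------

def points_inside(s: TriSurface, points: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Point-in-mesh test by the generalized winding number.

    Robust for watertight, outward-oriented surfaces; O(faces * points),
    evaluated in chunks. Winding ~ 1 inside, ~ 0 outside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = s.vertices[s.faces]  # (F, 3, 3)
    out = np.empty(len(points), dtype=bool)
    for start in range(0, len(points), chunk):
        p = points[start:start + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        det = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", a, b) * lc
            + np.einsum("pfi,pfi->pf", b, c) * la
            + np.einsum("pfi,pfi->pf", c, a) * lb
        )
        winding = np.arctan2(det, denom).sum(axis=1) / (2.0 * np.pi)
        out[start:start + chunk] = winding > 0.5
    return out


def ray_mesh_intersections(
    s: TriSurface, origins: np.ndarray, directions: np.ndarray, eps: float = 1e-12
) -> list[np.ndarray]:
    """Signed ray parameters of all intersections of each line with the mesh.

    Moller-Trumbore over all faces (no broadphase); returns, per ray, the
    sorted array of signed ``t`` where ``origin + t*direction`` hits a face.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = s.vertices[s.faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    hits: list[np.ndarray] = []
    for o, d in zip(origins, directions):
        pvec = np.cross(d, e2)
        det = np.einsum("fi,fi->f", e1, pvec)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - v0
        u = np.einsum("fi,fi->f", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("i,fi->f", d, qvec) * inv
        t = np.einsum("fi,fi->f", e2, qvec) * inv
        valid = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
        hits.append(np.sort(t[valid]))
    return hits


# ---------------------------------------------------------------------------
# tetrahedralization
# ---------------------------------------------------------------------------

def tetrahedralize(
    s: TriSurface, max_cell_volume: float = np.inf, max_refine_passes: int = 4
) -> TetMesh:
    """Delaunay-based tetrahedralization of a watertight surface.

    The point set is the surface vertices plus an interior Steiner grid sized
    from ``max_cell_volume``; the Delaunay tets are filtered by centroid
    containment, and oversized tets are refined by centroid insertion. All
    returned tets have positive volume under the (n0; n1, n2, n3) ordering
    convention. Total tet volume tracks the divergence-theorem surface volume
    (exactly for convex inputs).
    """
    report = validate_surface(s)
    if not report.watertight:
        raise GeometryError(
            f"tetrahedralize requires a watertight surface; "
            f"{report.boundary_edges} boundary edges found on {s.name!r}"
        )
    pts = [s.vertices]
    if np.isfinite(max_cell_volume):
        h = (3.0 * max_cell_volume) ** (1.0 / 3.0)
        lo, hi = s.bounds()
        axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
        if all(len(a) for a in axes):
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            inside = points_inside(s, grid)
            if inside.any():
                pts.append(grid[inside])
    points = np.vstack(pts)
    for _ in range(max_refine_passes + 1):
        tets = _delaunay_inside(points, s)
        mesh = TetMesh(points, tets, s.name)
        vols = mesh.tet_volumes()
        if not np.isfinite(max_cell_volume):
            break
        big = vols > max_cell_volume
        if not big.any():
            break
        centroids = points[tets[big]].mean(axis=1)
        points = np.vstack([points, centroids])
    return mesh


def _delaunay_inside(points: np.ndarray, s: TriSurface) -> np.ndarray:
    tri = Delaunay(points)
    tets = tri.simplices
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    vols = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    tets = tets[np.abs(vols) > 1e-12]
    vols = vols[np.abs(vols) > 1e-12]
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    centroids = points[tets].mean(axis=1)
    inside = points_inside(s, centroids)
    return tets[inside]


# ---------------------------------------------------------------------------
# rigid alignment
# ---------------------------------------------------------------------------

def apply_alignment(s: TriSurface, p: AlignmentPerturbation) -> TriSurface:
    """Apply a rigid malalignment to a surface (topology preserved)."""
    R, t = p.transform()
    out = s.transformed(R, t)
    out.name = s.name
    return out


def reflect_x(s: TriSurface) -> TriSurface:
    """Mirror a surface through the sagittal midplane x = 0 (winding fixed)."""
    v = s.vertices.copy()
    v[:, 0] *= -1.0
    return TriSurface(v, s.faces[:, ::-1].copy(), s.name)


def reflection_residual(s: TriSurface, axis: int = 0) -> float:
    """Max distance from each reflected vertex to the nearest original vertex.

    Zero (to tolerance) for a surface that is mirror-symmetric about the
    ``axis``-normal midplane as a point set.
    """
    v = s.vertices.copy()
    v[:, axis] *= -1.0
    tree = cKDTree(s.vertices)
    d, _ = tree.query(v)
    return float(d.max()) if len(d) else 0.0
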