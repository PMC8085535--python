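"""Synthetic TKR assembly: parametric implant and bone-stub geometry.

The generator emulates the articulating parts of a cemented posterior-
stabilized-style knee implant at desk scale:

* femoral component — two spherical condyles (radius ``condyle_radius``,
  centers at ``x = +/- condyle_spacing/2``) joined by a box bridge;
* tibial insert — a rectangular UHMWPE block whose top surface carries two
  spherical dish recesses (radius ``dish_radius``) concentric with the
  condyles;
* tibial tray — a flat plate under the insert;
* femur / tibia / fibula — cylindrical bone stubs.

The spherical condyle / spherical dish pairing is deliberate: initial contact
is a point at each dish center and the elastic-foundation contact problem has
a closed-form oracle. The whole assembly is mirror-symmetric about the
sagittal midplane ``x = 0`` (the fibula stub sits on the midplane for this
reason — a symmetry aid, not an anatomical claim).

Frame: x medial-lateral (medial = -x), y anterior (+), z up. The insert top
plateau defines ``z = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import GeometryError, TetMesh, TriSurface, reflect_x, tetrahedralize

__all__ = [
    "SyntheticGeomParams",
    "make_synthetic_tkr",
    "default_landmarks",
    "tetrahedralize_part",
]


@dataclass
class SyntheticGeomParams:
    """Parameters of the synthetic assembly (all lengths in mm)."""

    condyle_radius: float = 20.0          # R_c, femoral condyle sphere radius
    dish_radius: float = 24.0             # R_d, insert dish sphere radius (> R_c)
    condyle_spacing: float = 46.0         # d_ml, medial-lateral center distance
    initial_gap: float = 2.0              # apex gap femur-insert at reference pose
    insert_size: tuple = (76.0, 50.0)     # insert block footprint (x, y)
    insert_thickness: float = 12.0        # insert block height
    dish_depth: float = 3.0               # recess depth at dish center
    tray_size: tuple = (80.0, 54.0, 4.0)  # tray plate (x, y, z)
    insert_grid: tuple = (61, 41)         # top-surface grid (nx, ny); nx odd for symmetry
    sphere_subdivisions: int = 3          # icosphere refinement of the condyles
    stub_radius: float = 12.0             # femur/tibia stub cylinder radius
    stub_length: float = 40.0
    fibula_radius: float = 5.0
    fibula_length: float = 30.0

    def __post_init__(self) -> None:
        if self.condyle_radius >= self.dish_radius:
            raise GeometryError(
                "condyle radius must be smaller than dish radius "
                "(conforming-edge contact breaks the point-contact initialization)"
            )
        if self.condyle_spacing < 0:
            raise GeometryError("condyle spacing must be >= 0")
        if min(self.insert_size) <= 0 or self.insert_thickness <= 0 or self.dish_depth <= 0:
            raise GeometryError("insert dimensions must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def dish_rim_radius(self) -> float:
        """Lateral radius of the circular recess cut into the plateau."""
        t = self.dish_depth
        return float(np.sqrt(self.dish_radius**2 - (self.dish_radius - t) ** 2))

    @property
    def dish_centers(self) -> np.ndarray:
        """Dish sphere centers (above the plateau, z = R_d - depth)."""
        zc = self.dish_radius - self.dish_depth
        d = self.condyle_spacing / 2.0
        return np.array([[-d, 0.0, zc], [d, 0.0, zc]])

    @property
    def condyle_centers(self) -> np.ndarray:
        """Femoral condyle sphere centers at the reference pose."""
        zf = -self.dish_depth + self.initial_gap + self.condyle_radius
        d = self.condyle_spacing / 2.0
        return np.array([[-d, 0.0, zf], [d, 0.0, zf]])


def _concat(surfaces: list[TriSurface], name: str) -> TriSurface:
    verts, faces, off = [], [], 0
    for s in surfaces:
        verts.append(s.vertices)
        faces.append(s.faces + off)
        off += s.n_vertices
    return TriSurface(np.vstack(verts), np.vstack(faces), name)


def _box(extents, center, name="") -> TriSurface:
    b = trimesh.creation.box(extents=extents)
    return TriSurface(np.asarray(b.vertices) + np.asarray(center), np.asarray(b.faces), name)


def _cylinder(radius, height, center, name="") -> TriSurface:
    c = trimesh.creation.cylinder(radius=radius, height=height, sections=48)
    return TriSurface(np.asarray(c.vertices) + np.asarray(center), np.asarray(c.faces), name)


def _femoral_component(p: SyntheticGeomParams) -> TriSurface:
    base = trimesh.creation.icosphere(subdivisions=p.sphere_subdivisions, radius=p.condyle_radius)
    right = TriSurface(
        np.asarray(base.vertices) + p.condyle_centers[1], np.asarray(base.faces)
    )
    left = reflect_x(right)  # exact mirror of the lateral condyle
    zf = p.condyle_centers[0, 2]
    bridge = _box(
        extents=(max(p.condyle_spacing, 1e-6), p.condyle_radius, 0.6 * p.condyle_radius),
        center=(0.0, 0.0, zf + 0.5 * p.condyle_radius),
    )
    return _concat([left, right, bridge], "femoral_component")


def _insert_top_height(p: SyntheticGeomParams, x, y) -> np.ndarray:
    """Plateau height field: 0 on the flat plateau, dipping into the dishes."""
    z = np.zeros(np.broadcast(x, y).shape)
    for cx, cy, cz in p.dish_centers:
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        inside = rho2 < p.dish_rim_radius**2
        z_dish = cz - np.sqrt(np.maximum(p.dish_radius**2 - rho2, 0.0))
        z = np.where(inside, np.minimum(z, z_dish), z)
    return z


def _tibial_insert(p: SyntheticGeomParams) -> TriSurface:
    nx, ny = p.insert_grid
    lx, ly = p.insert_size
    xs = np.linspace(-lx / 2, lx / 2, nx)
    ys = np.linspace(-ly / 2, ly / 2, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Zt = _insert_top_height(p, X, Y)
    top = np.stack([X, Y, Zt], axis=-1).reshape(-1, 3)
    bot = np.stack([X, Y, np.full_like(X, -p.insert_thickness)], axis=-1).reshape(-1, 3)
    verts = np.vstack([top, bot])
    nb = nx * ny

    def tid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = tid(i, j), tid(i + 1, j), tid(i + 1, j + 1), tid(i, j + 1)
            # top (normal +z): ccw seen from above
            faces += [[a, b, c], [a, c, d]]
            # bottom (normal -z): reversed
            faces += [[a + nb, c + nb, b + nb], [a + nb, d + nb, c + nb]]
    # side walls around the perimeter
    ring = (
        [tid(i, 0) for i in range(nx)]
        + [tid(nx - 1, j) for j in range(1, ny)]
        + [tid(i, ny - 1) for i in range(nx - 2, -1, -1)]
        + [tid(0, j) for j in range(ny - 2, 0, -1)]
    )
    for k in range(len(ring)):
        a = ring[k]
        b = ring[(k + 1) % len(ring)]
        faces += [[a, a + nb, b + nb], [a, b + nb, b]]
    return TriSurface(verts, np.asarray(faces), "tibial_insert")


def make_synthetic_tkr(params: SyntheticGeomParams | None = None) -> dict[str, TriSurface]:
    """Build the six-part synthetic assembly; every surface is watertight."""
    p = params or SyntheticGeomParams()
    insert = _tibial_insert(p)
    fem = _femoral_component(p)
    tray_z = -p.insert_thickness - p.tray_size[2] / 2
    tray = _box(p.tray_size, (0.0, 0.0, tray_z), "tibial_tray")
    fem_top = fem.bounds()[1, 2]
    femur = _cylinder(
        p.stub_radius, p.stub_length, (0.0, 0.0, fem_top + p.stub_length / 2 - 2.0), "femur"
    )
    tib_top = -p.insert_thickness - p.tray_size[2]
    tibia = _cylinder(
        p.stub_radius, p.stub_length, (0.0, 0.0, tib_top - p.stub_length / 2), "tibia"
    )
    # fibula stub on the midplane (keeps the assembly mirror-symmetric)
    fibula = _cylinder(
        p.fibula_radius,
        p.fibula_length,
        (0.0, -p.insert_size[1] / 2 - 2 * p.fibula_radius, tib_top - p.fibula_length / 2),
        "fibula",
    )
    return {
        "femoral_component": fem,
        "tibial_insert": insert,
        "tibial_tray": tray,
        "femur": femur,
        "tibia": tibia,
        "fibula": fibula,
    }


def default_landmarks(params: SyntheticGeomParams | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Collateral-ligament attachment landmarks for the synthetic assembly.

    Femoral origins sit near the epicondyles, close to the flexion axis
    (through the condyle centers) so the collaterals stay near-isometric over
    flexion, as they do anatomically. Insertions are on the medial tibia (MCL)
    and on the fibular head (LCL). Medial = -x.
    """
    p = params or SyntheticGeomParams()
    zf = p.condyle_centers[0, 2]
    d = p.condyle_spacing / 2.0 + p.condyle_radius
    return {
        "femur": {
            "mcl_origin": np.array([-d - 3.0, 0.0, zf + 1.0]),
            "lcl_origin": np.array([d + 3.0, 0.0, zf + 1.0]),
        },
        "tibia": {
            "mcl_insertion": np.array([-d + 3.0, 0.0, zf - 65.0]),
        },
        "fibula": {
            "lcl_insertion": np.array([d - 3.0, -5.0, zf - 70.0]),
        },
    }


def tetrahedralize_part(surface: TriSurface, params: SyntheticGeomParams | None = None,
                        max_cell_volume: float = np.inf) -> TetMesh:
    """Volume-mesh a synthetic part.

    The femoral component is a union of three overlapping closed solids
    (two condyle spheres and the bridge), which breaks the no-self-
    intersection precondition of the generic mesher; it is therefore meshed
    piecewise and the piece meshes are concatenated. All other parts go
    through :func:`tkrfem.geometry.tetrahedralize` directly.
    """
    if surface.name != "femoral_component":
        return tetrahedralize(surface, max_cell_volume)
    p = params or SyntheticGeomParams()
    base = trimesh.creation.icosphere(subdivisions=p.sphere_subdivisions, radius=p.condyle_radius)
    right = TriSurface(np.asarray(base.vertices) + p.condyle_centers[1], np.asarray(base.faces),
                       "condyle")
    left = reflect_x(right)
    zf = p.condyle_centers[0, 2]
    bridge = _box(
        (max(p.condyle_spacing, 1e-6), p.condyle_radius, 0.6 * p.condyle_radius),
        (0.0, 0.0, zf + 0.5 * p.condyle_radius),
        "bridge",
    )
    nodes, tets, off = [], [], 0
    for piece in (left, right, bridge):
        m = tetrahedralize(piece, max_cell_volume)
        nodes.append(m.nodes)
        tets.append(m.tets + off)
        off += m.n_nodes
    return TetMesh(np.vstack(nodes), np.vstack(tets), "femoral_component")
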