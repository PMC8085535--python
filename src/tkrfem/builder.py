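"""Assembly of the six-part TKR model and FEBio-format (.feb) file emission.

The assembled model mirrors the standard rigid-bone TKR idealization:

* parts — femur, tibia, fibula (rigid bone stubs), tibial tray (rigid),
  femoral component and tibial insert (deformable, tetrahedral meshes with
  CoCrMo / UHMWPE neo-Hookean materials);
* contacts — rigid ties femur/femoral-component and tray/insert, plus a
  frictionless sliding-elastic interface femoral-component/insert;
* connectors — three rigid cylindrical joints (flexion-extension about x,
  joint distraction along z, varus-valgus about y);
* kinematics — the femur chain keeps exactly three DOFs (z translation,
  x rotation, y rotation); tibia, fibula and tray are fully constrained;
* protocol — two steps: a contact-settling ramp, then the gait cycle.
  Flexion is a prescribed rotation, z is force-driven (Fz), y moment-driven
  (My).

The writer targets the FEBio 3.0 XML dialect by default (a 2.5 emitter is
available behind the ``spec_version`` flag); ligaments serialize as discrete
nonlinear springs with the force-strain law tabulated as a force-displacement
curve. Output is deterministic: fixed float formatting, no timestamps, so the
same model always writes byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .gait import LoadCurve
from .geometry import TetMesh, TriSurface
from .ligaments import LigamentBundle
from .materials import NeoHookeanMaterial, RigidMaterial, default_library

__all__ = [
    "BodyPart",
    "ContactInterface",
    "CylindricalConnector",
    "FEModel",
    "AssemblyError",
    "assemble_model",
    "write_feb",
    "summarize_feb",
    "PART_ROLES",
]

#: Fixed part roles: bones and tray rigid, implant articulating parts deformable.
PART_ROLES = {
    "femur": "rigid",
    "tibia": "rigid",
    "fibula": "rigid",
    "tibial_tray": "rigid",
    "femoral_component": "deformable",
    "tibial_insert": "deformable",
}

#: Default material assignment per part.
PART_MATERIALS = {
    "femur": "rigid_femur",
    "tibia": "rigid_tibia",
    "fibula": "rigid_fibula",
    "tibial_tray": "rigid_tray",
    "femoral_component": "CoCrMo",
    "tibial_insert": "UHMWPE",
}


class AssemblyError(ValueError):
    """Missing or inconsistent model ingredients."""


@dataclass
class BodyPart:
    name: str
    mesh: object          # TetMesh (deformable) or TriSurface (rigid)
    role: str             # 'rigid' | 'deformable'
    material: object      # NeoHookeanMaterial | RigidMaterial

    def __post_init__(self) -> None:
        if self.role not in ("rigid", "deformable"):
            raise AssemblyError(f"unknown role {self.role!r} for part {self.name!r}")
        if self.role == "deformable" and not isinstance(self.mesh, TetMesh):
            raise AssemblyError(
                f"deformable part {self.name!r} requires a TetMesh, got "
                f"{type(self.mesh).__name__}"
            )
        if self.role == "rigid" and not isinstance(self.mesh, (TriSurface, TetMesh)):
            raise AssemblyError(f"rigid part {self.name!r} has no mesh")


@dataclass
class ContactInterface:
    kind: str                    # 'rigid_tie' | 'sliding_elastic'
    name: str
    primary: str                 # part name owning the primary face set
    secondary: str
    penalty: float = 1.0
    auto_penalty: bool = True
    augmented: bool = False
    friction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("rigid_tie", "sliding_elastic"):
            raise AssemblyError(f"unknown contact kind {self.kind!r}")


@dataclass
class CylindricalConnector:
    name: str                    # 'flexion_extension' | 'joint_distraction' | 'varus_valgus'
    body_a: str
    body_b: str
    origin: np.ndarray
    axis: np.ndarray
    driven_dof: str              # 'rotation' | 'translation'
    drive: str                   # 'prescribed_motion' | 'applied_load'
    curve: str                   # load-curve key

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise AssemblyError("connector axis must be nonzero")
        self.axis = self.axis / n


@dataclass
class FEModel:
    parts: dict[str, BodyPart]
    materials: dict[str, object]
    ligaments: list[LigamentBundle]
    contacts: list[ContactInterface]
    connectors: list[CylindricalConnector]
    curves: dict[str, LoadCurve]
    settle_duration: float = 0.1
    settle_increments: int = 10
    free_dofs: tuple = ("z_translation", "x_rotation", "y_rotation")

    @property
    def steps(self) -> list[dict]:
        gait_end = self.curves["Fz"].t_end
        n_gait = max(len(self.curves["Fz"].points) - 2, 1)
        return [
            {"name": "settle", "t0": 0.0, "t1": self.settle_duration,
             "increments": self.settle_increments},
            {"name": "gait", "t0": self.settle_duration, "t1": gait_end,
             "increments": n_gait},
        ]

    def counts(self) -> dict[str, int]:
        nodes = sum(
            p.mesh.n_nodes if isinstance(p.mesh, TetMesh) else p.mesh.n_vertices
            for p in self.parts.values()
        )
        elements = sum(
            p.mesh.n_tets if isinstance(p.mesh, TetMesh) else p.mesh.n_faces
            for p in self.parts.values()
        )
        return {
            "nodes": nodes,
            "elements": elements,
            "materials": len(self.materials),
            "contacts": len(self.contacts),
            "connectors": len(self.connectors),
            "ligaments": len(self.ligaments),
            "steps": len(self.steps),
            "curves": len(self.curves),
        }


def assemble_model(
    parts: dict[str, object],
    materials: dict[str, object] | None = None,
    ligaments: list[LigamentBundle] | None = None,
    bc_curves: dict[str, LoadCurve] | None = None,
    config: dict | None = None,
) -> FEModel:
    """Assemble the complete TKR model.

    ``parts`` maps the six canonical part names to meshes (TetMesh for the
    deformable implant parts, TriSurface for rigid parts); ``bc_curves``
    must provide 'flexion', 'Fz' and 'My'. Raises :class:`AssemblyError`
    naming any missing ingredient.
    """
    config = dict(config or {})
    materials = materials or default_library()
    missing = sorted(set(PART_ROLES) - set(parts))
    if missing:
        raise AssemblyError(f"missing parts: {missing}")
    if ligaments is None or len(ligaments) == 0:
        raise AssemblyError("ligament bundles (MCL, LCL) are required")
    bc_curves = bc_curves or {}
    missing_curves = sorted({"flexion", "Fz", "My"} - set(bc_curves))
    if missing_curves:
        raise AssemblyError(f"missing load curves: {missing_curves}")

    body_parts = {}
    for name, mesh in parts.items():
        role = PART_ROLES[name]
        mat_key = config.get("part_materials", PART_MATERIALS)[name]
        try:
            mat = materials[mat_key]
        except KeyError:
            raise AssemblyError(f"material {mat_key!r} for part {name!r} not in library") from None
        body_parts[name] = BodyPart(name, mesh, role, mat)

    contact_cfg = config.get("contact", {})
    contacts = [
        ContactInterface("rigid_tie", "femur_component_tie", "femoral_component", "femur"),
        ContactInterface("rigid_tie", "tray_insert_tie", "tibial_insert", "tibial_tray"),
        ContactInterface(
            "sliding_elastic", "tibiofemoral_contact", "femoral_component", "tibial_insert",
            penalty=contact_cfg.get("penalty", 1.0),
            auto_penalty=contact_cfg.get("auto_penalty", True),
            augmented=contact_cfg.get("augmented", False),
            friction=contact_cfg.get("friction", 0.0),
        ),
    ]

    origin = np.asarray(config.get("joint_center", (0.0, 0.0, 0.0)), dtype=float)
    flex_origin = np.asarray(config.get("flexion_axis_point", origin), dtype=float)
    connectors = [
        CylindricalConnector("flexion_extension", "femur", "tibia", flex_origin,
                             (1.0, 0.0, 0.0), "rotation", "prescribed_motion", "flexion"),
        CylindricalConnector("joint_distraction", "femur", "tibia", origin,
                             (0.0, 0.0, 1.0), "translation", "applied_load", "Fz"),
        CylindricalConnector("varus_valgus", "femur", "tibia", origin,
                             (0.0, 1.0, 0.0), "rotation", "applied_load", "My"),
    ]

    lig_names = {b.name for b in ligaments}
    if not {"MCL", "LCL"} <= lig_names:
        raise AssemblyError(f"expected MCL and LCL bundles, got {sorted(lig_names)}")

    return FEModel(
        parts=body_parts,
        materials=materials,
        ligaments=list(ligaments),
        contacts=contacts,
        connectors=connectors,
        curves=dict(bc_curves),
        settle_duration=config.get("settle_duration", 0.1),
        settle_increments=config.get("settle_increments", 10),
    )


# ---------------------------------------------------------------------------
# FEB emission
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def _vec(v) -> str:
    return ",".join(_fmt(x) for x in v)


def _spring_curve(b: LigamentBundle, n_samples: int = 41, max_strain: float = 0.30):
    """Tabulated force-displacement curve of the ligament law.

    Displacement is ``L - L_0``; the grid spans slack (-0.05*L_0) through
    ``max_strain``, with a breakpoint at the quadratic-to-linear transition.
    """
    eps = np.unique(np.concatenate([
        np.linspace(-0.05, 2 * b.eps_l, n_samples // 2),
        np.linspace(2 * b.eps_l, max_strain, n_samples - n_samples // 2),
    ]))
    d = eps * b.L_0
    f = np.array([b.force(b.L_0 + di) for di in d])
    return np.column_stack([d, f])


def write_feb(m: FEModel, path, spec_version: str = "3.0") -> None:
    """Emit the model as a FEBio-format XML file (byte-deterministic)."""
    if spec_version not in ("3.0", "2.5"):
        raise ValueError(f"unsupported FEBio spec version {spec_version!r}")
    root = etree.Element("febio_spec", version=spec_version)
    etree.SubElement(root, "Module", type="solid")

    # materials
    mat_el = etree.SubElement(root, "Material")
    mat_ids = {}
    for i, (key, mat) in enumerate(sorted(m.materials.items()), start=1):
        mat_ids[key] = i
        if isinstance(mat, NeoHookeanMaterial):
            el = etree.SubElement(mat_el, "material", id=str(i), name=key,
                                  type="neo-Hookean")
            etree.SubElement(el, "E").text = _fmt(mat.E)
            etree.SubElement(el, "v").text = _fmt(mat.v)
        elif isinstance(mat, RigidMaterial):
            el = etree.SubElement(mat_el, "material", id=str(i), name=key,
                                  type="rigid body")
            etree.SubElement(el, "density").text = _fmt(mat.density)
        else:
            raise AssemblyError(f"cannot serialize material {key!r}")

    # mesh
    mesh_el = etree.SubElement(root, "Mesh")
    offset = 0
    part_mat_key = {}
    for name, part in m.parts.items():
        for mk, mv in m.materials.items():
            if mv is part.material:
                part_mat_key[name] = mk
                break
        nodes_el = etree.SubElement(mesh_el, "Nodes", name=name)
        pts = part.mesh.nodes if isinstance(part.mesh, TetMesh) else part.mesh.vertices
        for i, pnt in enumerate(pts, start=1):
            etree.SubElement(nodes_el, "node", id=str(offset + i)).text = _vec(pnt)
        if isinstance(part.mesh, TetMesh):
            el_el = etree.SubElement(mesh_el, "Elements", type="tet4", name=name)
            conn = part.mesh.tets
        else:
            el_el = etree.SubElement(mesh_el, "Elements", type="tri3", name=name)
            conn = part.mesh.faces
        for i, row in enumerate(conn, start=1):
            etree.SubElement(el_el, "elem", id=str(i)).text = ",".join(
                str(offset + int(j) + 1) for j in row
            )
        offset += len(pts)

    # extra nodes for the discrete ligament springs
    lig_node_ids = []
    if m.ligaments:
        lig_nodes_el = etree.SubElement(mesh_el, "Nodes", name="ligament_attachments")
        nid = offset
        for b in m.ligaments:
            ids = []
            for pnt in (b.origin, b.insertion):
                nid += 1
                etree.SubElement(lig_nodes_el, "node", id=str(nid)).text = _vec(pnt)
                ids.append(nid)
            lig_node_ids.append(ids)
        for b, ids in zip(m.ligaments, lig_node_ids):
            ds = etree.SubElement(mesh_el, "DiscreteSet", name=b.name)
            etree.SubElement(ds, "delem").text = f"{ids[0]},{ids[1]}"

    # mesh domains
    dom_el = etree.SubElement(root, "MeshDomains")
    for name, part in m.parts.items():
        tag = "SolidDomain" if isinstance(part.mesh, TetMesh) else "ShellDomain"
        etree.SubElement(dom_el, tag, name=name, mat=part_mat_key[name])

    # discrete ligament springs
    if m.ligaments:
        disc_el = etree.SubElement(root, "Discrete")
        for i, b in enumerate(m.ligaments, start=1):
            dm = etree.SubElement(disc_el, "discrete_material", id=str(i), name=b.name,
                                  type="nonlinear spring")
            pts_el = etree.SubElement(dm, "force")
            pts_el.set("type", "point")
            curve = etree.SubElement(pts_el, "points")
            for d, f in _spring_curve(b):
                etree.SubElement(curve, "pt").text = f"{_fmt(d)},{_fmt(f)}"
            etree.SubElement(disc_el, "discrete", dmat=str(i), discrete_set=b.name)

    # rigid constraints: tibia/fibula/tray fully fixed; femur keeps z
    # translation + x/y rotation (enforced through the connectors/BCs)
    rigid_el = etree.SubElement(root, "Rigid")
    for name in ("tibia", "fibula", "tibial_tray"):
        rc = etree.SubElement(rigid_el, "rigid_constraint", name=f"fix_{name}",
                              type="fix")
        etree.SubElement(rc, "rb").text = part_mat_key[name]
        etree.SubElement(rc, "dofs").text = "Rx,Ry,Rz,Ru,Rv,Rw"
    rc = etree.SubElement(rigid_el, "rigid_constraint", name="fix_femur", type="fix")
    etree.SubElement(rc, "rb").text = part_mat_key["femur"]
    etree.SubElement(rc, "dofs").text = "Rx,Ry,Rw"  # lock x,y translation + z rotation

    curve_ids = {key: i for i, key in enumerate(sorted(m.curves), start=1)}
    for con in m.connectors:
        el = etree.SubElement(rigid_el, "rigid_connector", name=con.name,
                              type="rigid cylindrical joint")
        etree.SubElement(el, "body_a").text = part_mat_key[con.body_a]
        etree.SubElement(el, "body_b").text = part_mat_key[con.body_b]
        etree.SubElement(el, "joint_origin").text = _vec(con.origin)
        etree.SubElement(el, "joint_axis").text = _vec(con.axis)
        drive = etree.SubElement(el, "drive", dof=con.driven_dof, mode=con.drive)
        drive.set("lc", str(curve_ids[con.curve]))

    # contacts
    contact_el = etree.SubElement(root, "Contact")
    for c in m.contacts:
        kind = "tied" if c.kind == "rigid_tie" else "sliding-elastic"
        el = etree.SubElement(contact_el, "contact", type=kind, name=c.name,
                              surface_pair=f"{c.primary}__{c.secondary}")
        etree.SubElement(el, "penalty").text = _fmt(c.penalty)
        if c.kind == "sliding_elastic":
            etree.SubElement(el, "auto_penalty").text = str(int(c.auto_penalty))
            etree.SubElement(el, "laugon").text = str(int(c.augmented))
            etree.SubElement(el, "fric_coeff").text = _fmt(c.friction)

    # load curves
    ld_el = etree.SubElement(root, "LoadData")
    for key in sorted(m.curves):
        lc = m.curves[key]
        el = etree.SubElement(ld_el, "load_controller", id=str(curve_ids[key]),
                              name=key, type="loadcurve")
        etree.SubElement(el, "interpolate").text = "LINEAR"
        etree.SubElement(el, "extend").text = "CONSTANT"
        pts_el = etree.SubElement(el, "points")
        for t, v in lc.points:
            etree.SubElement(pts_el, "point").text = f"{_fmt(t)},{_fmt(v)}"

    # two-step protocol
    steps_el = etree.SubElement(root, "Step")
    for s in m.steps:
        st = etree.SubElement(steps_el, "step", name=s["name"])
        ctrl = etree.SubElement(st, "Control")
        etree.SubElement(ctrl, "time_steps").text = str(s["increments"])
        dt = (s["t1"] - s["t0"]) / max(s["increments"], 1)
        etree.SubElement(ctrl, "step_size").text = _fmt(dt)
        auto = etree.SubElement(ctrl, "time_stepper")
        etree.SubElement(auto, "dtmin").text = _fmt(dt / 100.0)
        etree.SubElement(auto, "dtmax").text = _fmt(dt)

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def summarize_feb(path) -> dict[str, int]:
    """Parse a .feb file back into structural counts (round-trip check)."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValueError(f"cannot parse FEB file {path}: {exc}") from exc
    root = tree.getroot()
    n = {
        "nodes": 0,
        "elements": 0,
        "materials": len(root.findall("./Material/material")),
        "contacts": len(root.findall("./Contact/contact")),
        "connectors": len(root.findall("./Rigid/rigid_connector")),
        "ligaments": len(root.findall("./Discrete/discrete_material")),
        "steps": len(root.findall("./Step/step")),
        "curves": len(root.findall("./LoadData/load_controller")),
    }
    for nodes in root.findall("./Mesh/Nodes"):
        if nodes.get("name") != "ligament_attachments":
            n["nodes"] += len(nodes.findall("node"))
    for elems in root.findall("./Mesh/Elements"):
        n["elements"] += len(elems.findall("elem"))
    return n
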