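import numpy as np
import pytest
from lxml import etree

from tkrfem.builder import (
    AssemblyError,
    PART_ROLES,
    assemble_model,
    summarize_feb,
    write_feb,
)
from tkrfem.gait import build_load_curves, synth_gait
from tkrfem.ligaments import make_default_bundles
from tkrfem.synthetic import default_landmarks, make_synthetic_tkr, tetrahedralize_part


@pytest.fixture(scope="module")
def model_inputs(coarse_params):
    parts_surf = make_synthetic_tkr(coarse_params)
    parts = {}
    for name, surf in parts_surf.items():
        if PART_ROLES[name] == "deformable":
            parts[name] = tetrahedralize_part(surf, coarse_params)
        else:
            parts[name] = surf
    lm = default_landmarks(coarse_params)
    ligaments = make_default_bundles(lm["femur"], lm["tibia"], lm["fibula"])
    curves = build_load_curves(synth_gait("normal", seed=1, n_points=25), 0.1)
    return parts, ligaments, curves


@pytest.fixture(scope="module")
def model(model_inputs):
    parts, ligaments, curves = model_inputs
    return assemble_model(parts, ligaments=ligaments, bc_curves=curves)


class TestAssembly:
    def test_structural_contract(self, model):
        assert len(model.contacts) == 3
        assert len(model.connectors) == 3
        assert len(model.ligaments) == 2
        assert len(model.steps) == 2
        kinds = sorted(c.kind for c in model.contacts)
        assert kinds == ["rigid_tie", "rigid_tie", "sliding_elastic"]
        sliding = [c for c in model.contacts if c.kind == "sliding_elastic"][0]
        assert {sliding.primary, sliding.secondary} == {"femoral_component", "tibial_insert"}

    def test_connector_axes(self, model):
        by_name = {c.name: c for c in model.connectors}
        assert np.allclose(by_name["flexion_extension"].axis, [1, 0, 0])
        assert np.allclose(by_name["joint_distraction"].axis, [0, 0, 1])
        assert np.allclose(by_name["varus_valgus"].axis, [0, 1, 0])
        assert by_name["flexion_extension"].drive == "prescribed_motion"
        assert by_name["joint_distraction"].drive == "applied_load"
        assert by_name["varus_valgus"].drive == "applied_load"

    def test_part_roles(self, model):
        for name, part in model.parts.items():
            assert part.role == PART_ROLES[name]

    def test_ligament_attachment_sides(self, model):
        mcl = [b for b in model.ligaments if b.name == "MCL"][0]
        lcl = [b for b in model.ligaments if b.name == "LCL"][0]
        assert mcl.origin[0] < 0 < lcl.origin[0]  # medial vs lateral femur side

    def test_missing_part_named(self, model_inputs):
        parts, ligaments, curves = model_inputs
        incomplete = {k: v for k, v in parts.items() if k != "fibula"}
        with pytest.raises(AssemblyError, match="fibula"):
            assemble_model(incomplete, ligaments=ligaments, bc_curves=curves)

    def test_missing_curve_named(self, model_inputs):
        parts, ligaments, curves = model_inputs
        partial = {k: v for k, v in curves.items() if k != "My"}
        with pytest.raises(AssemblyError, match="My"):
            assemble_model(parts, ligaments=ligaments, bc_curves=partial)

    def test_deformable_part_demands_tetmesh(self, model_inputs, coarse_params):
        parts, ligaments, curves = model_inputs
        swapped = dict(parts)
        swapped["tibial_insert"] = make_synthetic_tkr(coarse_params)["tibial_insert"]
        with pytest.raises(AssemblyError, match="TetMesh"):
            assemble_model(swapped, ligaments=ligaments, bc_curves=curves)


class TestFebEmission:
    def test_well_formed_with_two_steps(self, model, tmp_path):
        path = tmp_path / "model.feb"
        write_feb(model, path)
        root = etree.parse(str(path)).getroot()
        assert root.get("version") == "3.0"
        assert len(root.findall("./Step/step")) == 2

    def test_material_constants_serialized_exactly(self, model, tmp_path):
        path = tmp_path / "model.feb"
        write_feb(model, path)
        root = etree.parse(str(path)).getroot()
        mats = {m.get("name"): m for m in root.findall("./Material/material")}
        uh = mats["UHMWPE"]
        assert uh.get("type") == "neo-Hookean"
        assert float(uh.findtext("E")) == 1200.0
        assert float(uh.findtext("v")) == 0.46
        co = mats["CoCrMo"]
        assert float(co.findtext("E")) == 210000.0
        assert float(co.findtext("v")) == 0.3
        for name in ("rigid_femur", "rigid_tibia", "rigid_fibula", "rigid_tray"):
            assert mats[name].get("type") == "rigid body"

    def test_roundtrip_counts(self, model, tmp_path):
        path = tmp_path / "model.feb"
        write_feb(model, path)
        digest = summarize_feb(path)
        expected = model.counts()
        for key in ("nodes", "elements", "materials", "contacts", "connectors",
                    "ligaments", "steps", "curves"):
            assert digest[key] == expected[key], key

    def test_write_idempotent_bytes(self, model, tmp_path):
        p1, p2 = tmp_path / "a.feb", tmp_path / "b.feb"
        write_feb(model, p1)
        write_feb(model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unsupported_spec_version(self, model, tmp_path):
        with pytest.raises(ValueError):
            write_feb(model, tmp_path / "x.feb", spec_version="9.9")

    def test_spec_25_dialect(self, model, tmp_path):
        path = tmp_path / "model25.feb"
        write_feb(model, path, spec_version="2.5")
        assert etree.parse(str(path)).getroot().get("version") == "2.5"

    def test_truncated_file_rejected(self, model, tmp_path):
        path = tmp_path / "model.feb"
        write_feb(model, path)
        path.write_bytes(path.read_bytes()[:200])
        with pytest.raises(ValueError):
            summarize_feb(path)

    def test_empty_model_file_zero_counts(self, tmp_path):
        path = tmp_path / "empty.feb"
        path.write_text('<?xml version="1.0"?><febio_spec version="3.0"/>')
        digest = summarize_feb(path)
        assert all(v == 0 for v in digest.values())


class TestRoundTripRandomized:
    def test_randomized_configurations(self, tmp_path):
        """assemble -> write -> summarize is the identity on counts for
        randomized synthetic configurations."""
        from tkrfem.synthetic import SyntheticGeomParams

        rng = np.random.default_rng(0)
        for trial in range(3):
            params = SyntheticGeomParams(
                condyle_radius=float(rng.uniform(16, 22)),
                dish_radius=float(rng.uniform(24, 28)),
                condyle_spacing=float(rng.uniform(40, 50)),
                insert_grid=(13, 9),
                sphere_subdivisions=1,
            )
            parts_surf = make_synthetic_tkr(params)
            parts = {
                name: tetrahedralize_part(surf, params)
                if PART_ROLES[name] == "deformable" else surf
                for name, surf in parts_surf.items()
            }
            lm = default_landmarks(params)
            ligaments = make_default_bundles(lm["femur"], lm["tibia"], lm["fibula"])
            n_pts = int(rng.integers(21, 40))
            curves = build_load_curves(synth_gait("smooth", seed=trial, n_points=n_pts), 0.1)
            model = assemble_model(parts, ligaments=ligaments, bc_curves=curves)
            path = tmp_path / f"m{trial}.feb"
            write_feb(model, path)
            assert summarize_feb(path) == {
                k: v for k, v in model.counts().items()
            }
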