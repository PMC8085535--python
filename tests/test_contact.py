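import numpy as np
import pytest

from tkrfem.contact import (
    ConvergenceError,
    FoundationModel,
    JointPose,
    RigidMeshSurface,
    RigidPlane,
    RigidSphereSet,
    build_synthetic_contact_model,
    foundation_modulus,
    peak_metrics,
    run_gait,
    settle_to_contact,
    solve_timestep,
)
from tkrfem.gait import GaitBC, synth_gait
from tkrfem.geometry import AlignmentPerturbation
from tkrfem.ligaments import LigamentBundle


def flat_foundation(n=50, half=10.0, k_f=100.0, rigid=None, ligaments=()):
    """Uniform square grid of vertical foundation faces under a rigid surface."""
    xs = np.linspace(-half, half, n + 1)
    mids = (xs[:-1] + xs[1:]) / 2
    cx, cy = np.meshgrid(mids, mids, indexing="ij")
    cents = np.column_stack([cx.ravel(), cy.ravel(), np.zeros(n * n)])
    area = (xs[1] - xs[0]) ** 2
    return FoundationModel(
        contact_centroids=cents,
        contact_normals=np.tile([0.0, 0.0, 1.0], (n * n, 1)),
        contact_areas=np.full(n * n, area),
        k_f=k_f,
        layer_thickness=5.0,
        rigid_surface=rigid or RigidPlane((0, 0, 2.0), (0, 0, -1.0)),
        ligaments=list(ligaments),
    )


class TestFoundationModulus:
    def test_confined_layer_formula(self):
        # UHMWPE E=1200, v=0.46, h=10: E(1-v)/((1+v)(1-2v)h)
        expected = 1200 * 0.54 / (1.46 * 0.08 * 10.0)
        assert foundation_modulus(1200.0, 0.46, 10.0) == pytest.approx(expected)

    def test_positive_thickness_required(self):
        with pytest.raises(ValueError):
            foundation_modulus(1200.0, 0.46, 0.0)


class TestSettle:
    def test_uniform_gap_plane(self):
        model = flat_foundation()
        u = settle_to_contact(model, tol=1e-5)
        assert u == pytest.approx(-2.0, abs=1e-4)

    def test_sphere_first_contact_at_dish_center(self):
        model = build_synthetic_contact_model()
        u = settle_to_contact(model, tol=1e-5)
        # apex gap is the generator's initial_gap (2 mm); the faceted dish's
        # face centroids sit slightly above the smooth surface, so first
        # contact lands within mesh-discretization distance of 2 mm
        assert u == pytest.approx(-2.0, abs=0.05)

    def test_prepenetrated_start_rejected(self):
        model = flat_foundation(rigid=RigidPlane((0, 0, -0.5), (0, 0, -1.0)))
        with pytest.raises(ValueError, match="interpenetrat"):
            settle_to_contact(model)


class TestOracles:
    def test_flat_punch_uniform_pressure(self):
        """Rigid plane on a flat foundation: p = Fz/A, delta = Fz/(k_f A)."""
        model = flat_foundation(n=50, k_f=100.0)
        settle_to_contact(model)
        Fz = 4000.0
        A = 400.0
        pose, pf = solve_timestep(model, 0.0, Fz, 0.0)
        assert pf.pressures.max() == pytest.approx(Fz / A, rel=1e-6)
        assert pf.pressures.min() == pytest.approx(Fz / A, rel=1e-6)
        delta = -(pose.u_z + 2.0)
        assert delta == pytest.approx(Fz / (100.0 * A), rel=1e-6)
        assert pose.phi == pytest.approx(0.0, abs=1e-9)

    def test_sphere_on_foundation_closed_form(self):
        """F = pi k_f R delta^2, p_max = k_f delta, within 1% at 2500 faces."""
        R, k_f = 20.0, 100.0
        model = flat_foundation(n=50, k_f=k_f,
                                rigid=RigidSphereSet([[0.0, 0.0, R + 1.0]], R))
        settle_to_contact(model)
        delta_target = 0.3
        Fz = np.pi * k_f * R * delta_target**2
        pose, pf = solve_timestep(model, 0.0, Fz, 0.0)
        delta = -(pose.u_z + 1.0)
        assert delta == pytest.approx(delta_target, rel=0.01)
        assert pf.max_pressure == pytest.approx(k_f * delta, rel=0.01)
        assert pf.total_force == pytest.approx(np.pi * k_f * R * delta**2, rel=0.01)

    def test_mesh_surface_matches_plane(self):
        """Ray-cast rigid surface agrees with the analytic plane query."""
        import trimesh

        from tkrfem.geometry import TriSurface

        box = trimesh.creation.box(extents=(30.0, 30.0, 4.0))
        punch = TriSurface(np.asarray(box.vertices) + [0, 0, 4.0], np.asarray(box.faces))
        model_mesh = flat_foundation(n=10, rigid=RigidMeshSurface(punch))
        model_plane = flat_foundation(n=10, rigid=RigidPlane((0, 0, 2.0), (0, 0, -1.0)))
        g_mesh = model_mesh.gaps(JointPose(0, -1.0, 0))
        g_plane = model_plane.gaps(JointPose(0, -1.0, 0))
        np.testing.assert_allclose(g_mesh, g_plane, atol=1e-9)


class TestEquilibriumProperties:
    def test_load_control_doubling_kf(self):
        """Doubling the foundation modulus leaves total force unchanged and
        raises peak pressure for curved contact."""
        R = 20.0
        Fz = 500.0
        results = {}
        for k_f in (100.0, 200.0):
            model = flat_foundation(n=40, k_f=k_f,
                                    rigid=RigidSphereSet([[0.0, 0.0, R + 1.0]], R))
            settle_to_contact(model)
            _, pf = solve_timestep(model, 0.0, Fz, 0.0)
            results[k_f] = pf
        assert results[100.0].total_force == pytest.approx(Fz, rel=1e-6)
        assert results[200.0].total_force == pytest.approx(Fz, rel=1e-6)
        assert results[200.0].max_pressure > results[100.0].max_pressure

    def test_symmetric_model_zero_tilt(self, contact_model):
        """Mirror-symmetric geometry with symmetric ligaments and My=0 gives
        phi=0 and balanced compartment loads."""
        sym_ligs = [
            LigamentBundle("MCL", (-45, 0, 20), (-42, 0, -45), k=7000, eps_r=0.02),
            LigamentBundle("LCL", (45, 0, 20), (42, 0, -45), k=7000, eps_r=0.02),
        ]
        model = contact_model.with_ligaments(sym_ligs)
        settle_to_contact(model)
        pose, pf = solve_timestep(model, 0.0, 1500.0, 0.0)
        assert pose.phi == pytest.approx(0.0, abs=1e-6)
        med = pf.compartment_force("medial")
        lat = pf.compartment_force("lateral")
        assert abs(med - lat) <= 1e-3 * (med + lat)

    def test_medial_share_monotone_in_varus_moment(self, contact_model):
        """A varus drive moment (negative My here) monotonically shifts load
        toward the medial compartment."""
        settle_to_contact(contact_model)
        shares = []
        prev = None
        for My in np.linspace(15000.0, -15000.0, 7):
            pose, pf = solve_timestep(contact_model, 0.0, 2000.0, float(My), prev_pose=prev)
            shares.append(pf.compartment_force("medial") / pf.total_force)
            prev = pose
        assert all(b >= a - 1e-9 for a, b in zip(shares, shares[1:]))

    def test_cop_inside_contact_patch(self, contact_model):
        settle_to_contact(contact_model)
        _, pf = solve_timestep(contact_model, 0.0, 2000.0, 0.0)
        loaded = pf.centroids[pf.pressures > 0]
        cop = pf.cop
        assert loaded[:, 0].min() <= cop[0] <= loaded[:, 0].max()
        assert loaded[:, 1].min() <= cop[1] <= loaded[:, 1].max()


class TestGaitRun:
    def test_101_sample_run_equilibrium(self, contact_model, normal_bc):
        traj = run_gait(contact_model, normal_bc)
        assert len(traj) == 101
        for i, rec in enumerate(traj):
            assert abs(rec.residual[0]) <= 1e-6 * max(normal_bc.Fz[i], 1.0)
            assert abs(rec.residual[1]) <= 1e-6 * max(abs(normal_bc.My[i]), 1.0)
            assert np.all(rec.pressure.pressures >= 0)

    def test_zero_force_trial_unloaded(self, contact_model):
        n = 25
        bc = GaitBC(np.linspace(0, 1, n), np.zeros(n), np.zeros(n), np.zeros(n), "null")
        traj = run_gait(contact_model, bc)
        assert all(rec.pressure.total_force == 0.0 for rec in traj)
        assert all(rec.pressure.max_pressure == 0.0 for rec in traj)

    def test_convergence_error_reports_sample(self, contact_model):
        bad = GaitBC(
            np.linspace(0, 1, 3), np.zeros(3),
            np.array([100.0, 1e12, 100.0]), np.zeros(3), "bad",
        )
        with pytest.raises(ConvergenceError, match="sample"):
            run_gait(contact_model, bad)


class TestPeakMetrics:
    def test_two_peak_gait_peaks_found(self, contact_model, normal_bc):
        traj = run_gait(contact_model, normal_bc)
        m = peak_metrics(traj, normal_bc)
        s = normal_bc.stance_fraction
        assert not m["fallback"]
        assert abs(s[m["i1"]] - 0.20) <= 0.02
        assert abs(s[m["i2"]] - 0.80) <= 0.02
        assert m["P2"] > 0 and m["P1"] > 0

    def test_constant_force_fallback(self, contact_model):
        n = 26
        bc = GaitBC(np.linspace(0, 1, n), np.zeros(n), np.full(n, 800.0),
                    np.zeros(n), "const")
        traj = run_gait(contact_model, bc)
        m = peak_metrics(traj, bc)
        assert m["fallback"]
        assert m["P1"] == pytest.approx(m["P2"], rel=1e-9)

    def test_single_sample_rejected(self, contact_model):
        with pytest.raises(ValueError):
            peak_metrics([object()], None)


class TestAlignmentSensitivityDirection:
    def test_varus_tilt_raises_peak_pressure(self, contact_model, normal_bc):
        """5 deg varus malalignment of the femoral component increases the
        single-compartment peak contact pressure on the synthetic model."""
        ref = peak_metrics(run_gait(contact_model, normal_bc), normal_bc)
        tilted = contact_model.with_alignment(AlignmentPerturbation("varus", 5.0))
        settle_to_contact(tilted)
        per = peak_metrics(run_gait(tilted, normal_bc), normal_bc)
        assert per["P2"] > ref["P2"]
        assert per["P1"] > ref["P1"]
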