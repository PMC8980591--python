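import numpy as np
import pytest

from conftest import make_patch, make_single_square
from pericav.materials import SolidMaterialParams
from pericav.metrics import green_lagrange_principal
from pericav.solid import (SolidSolver, skull_frame_body_force,
                           stable_timestep)
from pericav.loading import generate_load_case


class TestStableTimestep:
    def test_single_square_hand_value(self, brain):
        mesh = make_single_square(h=1e-3)
        c = np.sqrt((brain.K + 4 * brain.G0 / 3) / brain.density)
        assert stable_timestep(mesh, brain) == pytest.approx(
            0.5 * 1e-3 / c)
        assert stable_timestep(mesh, brain) == pytest.approx(2.280e-6,
                                                             rel=1e-3)

    def test_halving_h_halves_dt(self, brain):
        dt1 = stable_timestep(make_single_square(1e-3), brain)
        dt2 = stable_timestep(make_single_square(0.5e-3), brain)
        assert dt2 == pytest.approx(dt1 / 2)

    def test_quadrupling_K_halves_dt(self):
        m1 = SolidMaterialParams()
        m2 = SolidMaterialParams(K=4 * m1.K)
        mesh = make_single_square()
        # G0 contributes negligibly next to K
        assert stable_timestep(mesh, m2) == pytest.approx(
            stable_timestep(mesh, m1) / 2, rel=1e-3)

    def test_degenerate_element_rejected(self, brain):
        mesh = make_single_square()
        mesh.node_coordinates[1] = mesh.node_coordinates[0]
        mesh.node_coordinates[2] = mesh.node_coordinates[3]
        with pytest.raises(ValueError):
            stable_timestep(mesh, brain)


class TestInternalForces:
    def test_zero_stress_zero_forces(self, brain):
        s = SolidSolver(make_patch(), brain, fix_outer_boundary=False)
        assert np.all(s.internal_forces() == 0)

    def test_uniform_stress_patch_interior_free(self, brain):
        n = 4
        s = SolidSolver(make_patch(n=n), brain, fix_outer_boundary=False)
        s.sigma[..., 0] = 100.0
        s.sigma[..., 1] = -40.0
        s.sigma[..., 2] = 25.0
        f = s.internal_forces()
        interior = [i * n + j for i in range(1, n - 1)
                    for j in range(1, n - 1)]
        assert np.abs(f[interior]).max() < 1e-10 * np.abs(f).max()

    def test_edge_reaction_equals_pressure_times_length(self, brain):
        """Uniform pressure p: the summed boundary reaction on one edge of
        the patch equals p times the edge length (static equilibrium)."""
        n, h, p = 4, 1e-3, 100.0
        s = SolidSolver(make_patch(n=n, h=h), brain,
                        fix_outer_boundary=False)
        s.sigma[..., 0] = -p
        s.sigma[..., 1] = -p
        f = s.internal_forces()
        top = [i * n + (n - 1) for i in range(n)]
        assert abs(f[top, 1].sum()) == pytest.approx(p * (n - 1) * h)

    def test_numba_and_numpy_paths_agree(self, default_pair, brain):
        _, nth = default_pair
        s1 = SolidSolver(nth, brain, use_numba=True)
        s2 = SolidSolver(nth, brain, use_numba=False)
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1e-5, (nth.n_nodes, 2))
        v = rng.normal(0, 1e-3, (nth.n_nodes, 2))
        for s in (s1, s2):
            s.u[:] = u
            s.v[:] = v
            s._kinematics()
            s._update_stress(1e-6)
        assert np.allclose(s1._F, s2._F, rtol=1e-13, atol=0)
        assert np.allclose(s1.sigma, s2.sigma, rtol=1e-8, atol=1e-10)
        assert np.allclose(s1.internal_forces(), s2.internal_forces(),
                           rtol=1e-8, atol=1e-12)


class TestStepping:
    def test_quiescent_state_unchanged(self, brain):
        s = SolidSolver(make_single_square(), brain,
                        fix_outer_boundary=False)
        for _ in range(10):
            s.step(1e-6)
        assert np.all(s.u == 0) and np.all(s.v == 0)

    def test_uniform_body_force_rigid_translation(self, brain):
        """A free mesh under uniform body force translates rigidly; the
        element strains stay at round-off."""
        s = SolidSolver(make_patch(), brain, fix_outer_boundary=False)
        g = np.tile([10.0, -4.0], (s.n_nodes, 1))
        dt = 1e-6
        for _ in range(200):
            s.step(dt, body_accel=g)
        strain = green_lagrange_principal(s.element_fields().F)
        assert np.abs(strain).max() < 1e-12
        assert s.u[0, 0] == pytest.approx(0.5 * 10 * (200 * dt) ** 2,
                                          rel=0.02)

    def test_rigid_rotation_produces_no_strain(self, brain):
        """Objectivity: prescribing a rigid rotation of all nodes leaves
        Green-Lagrange strains at round-off."""
        s = SolidSolver(make_patch(), brain, fix_outer_boundary=False)
        X = s.mesh.node_coordinates
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s.u[:] = X @ R.T - X
        s._kinematics()
        strain = np.abs(green_lagrange_principal(s.element_fields().F))
        assert strain.max() < 1e-10

    def test_clamped_strip_shear_vibration_period(self):
        """Fundamental period of a clamped-free strip in shear is 4H/c_s
        with c_s = sqrt(G/rho); measured period within 10%."""
        m = SolidMaterialParams(G0=2.2e3, Ginf=2.2e3 - 1e-9, tau=1.0)
        H, w, nh = 0.02, 0.005, 8
        from pericav.geometry import QuadMesh

        xs, ys = np.meshgrid(np.linspace(0, w, 3),
                             np.linspace(0, H, nh + 1), indexing="ij")
        nodes = np.column_stack([xs.ravel(), ys.ravel()])
        conn = []
        ncol = nh + 1
        for i in range(2):
            for j in range(nh):
                a = i * ncol + j
                conn.append([a, a + ncol, a + ncol + 1, a + 1])
        E = len(conn)
        mesh = QuadMesh(nodes, np.array(conn), np.full(E, "", object),
                        np.full(E, "brain", object), {})
        s = SolidSolver(mesh, m, fix_outer_boundary=False,
                        bulk_viscosity=0.06, shear_viscosity=0.0)
        s.fixed[np.isclose(nodes[:, 1], 0.0)] = True
        s.v[:, 0] = 0.001
        s.v[s.fixed] = 0.0
        dt = stable_timestep(mesh, m, 0.5)
        tip = np.isclose(nodes[:, 1], H)
        t_hist, x_hist = [], []
        for _ in range(int(0.09 / dt)):
            s.step(dt)
            t_hist.append(s.t)
            x_hist.append(s.u[tip, 0].mean())
        x = np.array(x_hist)
        t = np.array(t_hist)
        # motion starts from zero displacement with positive velocity, so
        # the first upward zero crossing marks one full period
        sign = np.sign(x)
        ups = np.where((sign[:-1] <= 0) & (sign[1:] > 0))[0]
        assert len(ups) >= 1
        period = t[ups[0]]
        c_s = np.sqrt(m.G0 / m.density)
        assert period == pytest.approx(4 * H / c_s, rel=0.10)

    def test_energy_bounded_after_load_removal(self, brain):
        """With no external load, kinetic + strain energy does not grow by
        more than 1% per millisecond (only viscous dissipation acts)."""
        s = SolidSolver(make_patch(n=6, h=2e-3), brain,
                        fix_outer_boundary=False)
        rng = np.random.default_rng(1)
        s.v[:] = rng.normal(0, 0.01, s.v.shape)
        dt = stable_timestep(s.mesh, brain, 0.5)
        s.step(dt)
        e_prev = sum(s.energies())
        t_prev = s.t
        while s.t < 2e-3:
            s.step(dt)
            if s.t - t_prev >= 5e-4:
                e = sum(s.energies())
                growth = (e / e_prev - 1) / ((s.t - t_prev) * 1e3)
                assert growth < 0.01
                e_prev, t_prev = e, s.t

    def test_inversion_reported_with_element_and_step(self, brain):
        s = SolidSolver(make_single_square(), brain,
                        fix_outer_boundary=False)
        s.u[1] = [-2e-3, 0.0]   # collapse the element
        with pytest.raises(RuntimeError, match="element 0"):
            s._kinematics()


class TestSkullFrameForce:
    def test_zero_load_zero_field(self):
        lc = generate_load_case(0.0, 0.0, duration=0.01)
        pos = np.array([[0.05, 0.0], [0.0, 0.02]])
        a = skull_frame_body_force(pos, lc, 0.005)
        assert np.all(a == 0)

    def test_pure_translation_uniform_field(self):
        lc = generate_load_case(100.0, 0.0, duration=0.01, direction=0.0)
        pos = np.array([[0.05, 0.0], [-0.03, 0.02]])
        a = skull_frame_body_force(pos, lc, 0.005)
        assert np.allclose(a[0], a[1])
        assert a[0, 0] == pytest.approx(-100.0)

    def test_euler_term_magnitude(self):
        """alpha = 1000 rad/s^2 at r = (0.05, 0): tangential term 50 m/s^2."""
        lc = generate_load_case(0.0, 1000.0, duration=0.01)
        i_peak = np.argmax(lc.alpha_z)
        t = lc.times[i_peak]
        pos = np.array([[0.05, 0.0]])
        a = skull_frame_body_force(pos, lc, t, omega_z=0.0)
        assert abs(a[0, 1]) == pytest.approx(1000.0 * 0.05)
        assert a[0, 1] < 0  # -alpha x r
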