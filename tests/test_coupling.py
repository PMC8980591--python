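import numpy as np
import pytest

from pericav.coupling import (WallCoupling, compute_coupling_forces,
                              default_penalty_stiffness,
                              pressure_traction_forces, wall_penalization)
from pericav.fluid import FluidGrid


def flat_interface_grid(n=20, dx=0.05, level=0.5):
    """Fluid occupies y > level; the rest is void."""
    g = FluidGrid.uniform(n, n, dx)
    ys = (np.arange(n) + 0.5) * dx
    g.Vc[:] = (ys[None, :] > level).astype(float)
    g.Vv = 1.0 - g.Vc
    g.M = g.eos.rho0 * g.Vc
    return g


def wall_at(y, x0=0.4, x1=0.6):
    """One wall segment with the fluid (above) on its right."""
    nodes = np.array([[x1, y], [x0, y]])
    edges = np.array([[0, 1]])
    return nodes, edges


class TestPenaltyForceLaw:
    def test_zero_penetration_zero_force(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.5)
        f, fx, fy, info = compute_coupling_forces(nodes, edges, g, 1e6)
        assert np.all(f == 0)
        assert info["penetration"][0] == 0.0

    def test_linear_law_hand_value(self):
        """Separation d = 1e-4 m at k = 1e6 on a 1 m segment gives a
        100 N anti-parallel force pair."""
        g = flat_interface_grid()
        nodes = np.array([[1.0, 0.5 - 1e-4], [0.0, 0.5 - 1e-4]])
        edges = np.array([[0, 1]])
        f, fx, fy, _ = compute_coupling_forces(nodes, edges, g, 1e6)
        total = f.sum(axis=0)
        assert total[1] == pytest.approx(100.0, rel=1e-3)
        assert fx.sum() == pytest.approx(0.0, abs=1e-12)
        assert fy.sum() == pytest.approx(-total[1], rel=1e-12)

    def test_both_signs_transmitted(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.5 - 1e-4)      # gap: tension, pulls up
        f_gap, *_ = compute_coupling_forces(nodes, edges, g, 1e6)
        nodes2, _ = wall_at(0.5 + 1e-4)         # overlap: compression
        f_pen, *_ = compute_coupling_forces(nodes2, edges, g, 1e6)
        assert f_gap.sum(axis=0)[1] > 0
        assert f_pen.sum(axis=0)[1] < 0

    def test_tangential_slip_is_free(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.5)
        f0, *_ = compute_coupling_forces(nodes, edges, g, 1e6)
        nodes_slid = nodes + [0.07, 0.0]
        f1, *_ = compute_coupling_forces(nodes_slid, edges, g, 1e6)
        assert np.abs(f0).max() < 1e-10
        assert np.abs(f1).max() < 1e-10

    def test_equal_and_opposite_momentum_injection(self):
        g = flat_interface_grid()
        rng = np.random.default_rng(2)
        nodes = np.column_stack([np.linspace(0.2, 0.8, 7),
                                 0.5 + rng.uniform(-0.02, 0.02, 7)])
        edges = np.column_stack([np.arange(1, 7), np.arange(6)])
        f, fx, fy, _ = compute_coupling_forces(nodes, edges, g, 1e6)
        scale = np.abs(f).sum() + 1.0
        assert abs(f[:, 0].sum() + fx.sum()) < 1e-12 * scale
        assert abs(f[:, 1].sum() + fy.sum()) < 1e-12 * scale

    def test_deadband_suppresses_subcell_offsets(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.5 - 0.01)      # 0.2 cell gap
        f, *_ = compute_coupling_forces(nodes, edges, g, 1e6,
                                        deadband_cells=0.5)
        assert np.all(f == 0)

    def test_traction_cap_bounds_force(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.5 - 0.08)      # large gap
        f, *_ = compute_coupling_forces(nodes, edges, g, 1e9,
                                        traction_cap=1e3)
        length = 0.2
        assert np.abs(f).sum() <= 1e3 * length * 1.0001

    def test_nonpositive_stiffness_rejected(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.5)
        with pytest.raises(ValueError):
            compute_coupling_forces(nodes, edges, g, 0.0)

    def test_baseline_calibration_zeroes_initial_forces(self):
        """Calibrating against the initial contour removes sub-cell bias:
        forces at the calibration configuration vanish identically."""
        g = flat_interface_grid(level=0.5123)   # off-grid interface
        nodes, edges = wall_at(0.5123)
        c = WallCoupling(edges, k_penalty=1e6)
        c.calibrate(nodes, g)
        f, *_ = c.forces(nodes, g)
        assert np.abs(f).max() < 1e-10


class TestDefaultStiffness:
    def test_scales_with_bulk_modulus_over_cell(self):
        g = flat_interface_grid()
        k = default_penalty_stiffness(g, relaxation=0.1)
        assert k == pytest.approx(0.1 * g.eos.rho0 * g.eos.C**2 / g.dx)


class TestWallPenalization:
    def test_occupancy_sides_and_wall_velocity(self):
        g = flat_interface_grid()
        # closed square wall around the middle; fluid inside on the right
        nodes = np.array([[0.3, 0.3], [0.7, 0.3], [0.7, 0.7], [0.3, 0.7]])
        edges = np.array([[1, 0], [2, 1], [3, 2], [0, 3]])  # cavity inside
        vel = np.tile([0.5, -0.25], (4, 1))
        chi_u, uw, chi_v, vw = wall_penalization(g, nodes, edges, vel)
        # deep inside the square: chi -> 0 (cavity); far outside: chi -> 1
        assert chi_u[10, 10] == 0.0
        assert chi_u[2, 2] == 1.0
        assert uw[10, 10] == pytest.approx(0.5)
        assert vw[2, 2] == pytest.approx(-0.25)

    def test_smooth_in_wall_position(self):
        """chi varies continuously as the wall moves sub-cell distances."""
        g = flat_interface_grid()
        edges = np.array([[1, 0], [2, 1], [3, 2], [0, 3]])
        vals = []
        for off in np.linspace(0, g.dx, 6):
            nodes = np.array([[0.3, 0.3], [0.7, 0.3], [0.7, 0.7],
                              [0.3, 0.7]]) + [off, 0.0]
            chi_u, *_ = wall_penalization(g, nodes, edges)
            vals.append(chi_u[6, 10])
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 0.35     # no 0-to-1 jumps


class TestPressureTraction:
    def test_static_pressurized_cavity_traction_matches_pressure(self):
        """Static equilibrium: the traction on a wall section bounding a
        uniformly pressurized fluid equals p times its length within 5%."""
        g = flat_interface_grid()
        mu = 1e-4
        g.M *= 1 + mu                       # pressurize the fluid
        from pericav.materials import eos_pressure

        p = eos_pressure(mu)
        nodes, edges = wall_at(0.5)
        f = pressure_traction_forces(g, nodes, edges)
        # pressure above pushes the wall down (away from the cavity)
        assert f.sum(axis=0)[1] == pytest.approx(-p * 0.2, rel=0.05)
        assert abs(f.sum(axis=0)[0]) < 1e-9 * abs(f.sum(axis=0)[1])

    def test_dry_wall_feels_nothing(self):
        g = flat_interface_grid()
        nodes, edges = wall_at(0.1)         # deep in the void region
        f = pressure_traction_forces(g, nodes, edges)
        assert np.all(f == 0)
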