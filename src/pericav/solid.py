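"""Explicit central-difference dynamics of the brain slice.

Plane-strain, fully integrated (2x2 Gauss) four-node quadrilaterals; lumped
mass; rigid outer (skull) boundary in a skull-fixed frame, so the impact
enters as a fictitious body-force field (translational + Euler + centrifugal
terms).  The stress update is the viscoelastic neo-Hookean model of
:mod:`pericav.materials`, evaluated here through a componentwise fast path;
:func:`pericav.materials.solid_cauchy_stress` is the reference
implementation the fast path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pericav.geometry import QuadMesh, MAT_FLUID
from pericav.loading import LoadCase
from pericav.materials import SolidMaterialParams

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:              # pragma: no cover - numba is a hard dep
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "SolidSolver",
    "stable_timestep",
    "characteristic_lengths",
    "skull_frame_body_force",
]

# 2x2 Gauss points in the bilinear parent element, corners ordered CCW
_XI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_CORNER = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/d(xi, eta) for the 4 bilinear shape functions, (4 nodes, 2)."""
    g = np.empty((4, 2))
    for a in range(4):
        sx, sy = _CORNER[a]
        g[a, 0] = 0.25 * sx * (1.0 + sy * xi[1])
        g[a, 1] = 0.25 * sy * (1.0 + sx * xi[0])
    return g


def characteristic_lengths(mesh: QuadMesh, active=None,
                           coordinates=None) -> np.ndarray:
    """Per-element characteristic length: area / longest edge.

    For thin elements this resolves to the through-thickness dimension,
    which controls the explicit stability limit.  Pass ``coordinates`` to
    evaluate on a deformed configuration.
    """
    conn = mesh.element_connectivity
    if active is not None:
        conn = conn[active]
    X = mesh.node_coordinates if coordinates is None else coordinates
    xy = X[conn]
    areas = 0.5 * np.abs(
        np.sum(xy[:, :, 0] * np.roll(xy[:, :, 1], -1, axis=1)
               - np.roll(xy[:, :, 0], -1, axis=1) * xy[:, :, 1], axis=1))
    edges = np.linalg.norm(np.roll(xy, -1, axis=1) - xy, axis=2)
    longest = edges.max(axis=1)
    if np.any(longest <= 0) or np.any(areas <= 0):
        raise ValueError("degenerate element: zero characteristic length")
    return areas / longest


def stable_timestep(mesh: QuadMesh, material: SolidMaterialParams,
                    cfl_factor: float = 0.5, active=None) -> float:
    """CFL-stable explicit step: cfl * min(h / c_dil) over elements.

    ``c_dil = sqrt((K + 4 G0/3) / rho)`` is the dilatational wave speed of
    the (instantaneous) solid.
    """
    h = characteristic_lengths(mesh, active)
    c = np.sqrt((material.K + 4.0 * material.G0 / 3.0) / material.density)
    return float(cfl_factor * h.min() / c)


def skull_frame_body_force(positions: np.ndarray, load: LoadCase, t: float,
                           center=(0.0, 0.0), omega_z: float | None = None
                           ) -> np.ndarray:
    """Fictitious acceleration field in the skull-fixed frame, (N, 2) m/s^2.

    a_fict = -a_trans(t) - alpha(t) x r - omega(t) x (omega(t) x r), with r
    the node position relative to the rotation center and omega the time
    integral of the angular acceleration.
    """
    r = np.asarray(positions, dtype=float) - np.asarray(center, dtype=float)
    at = load.translational(t)
    alpha = load.angular(t)
    omega = load.angular_velocity(t) if omega_z is None else omega_z
    out = np.empty_like(r)
    out[:, 0] = -at[0] + alpha * r[:, 1] + omega**2 * r[:, 0]
    out[:, 1] = -at[1] - alpha * r[:, 0] + omega**2 * r[:, 1]
    return out


@njit(cache=False)
def _kern_kinematics(u, v, conn, G, F, L, detF):
    """Per-GP deformation and velocity gradients; returns the index of the
    first inverted element, or -1."""
    E = conn.shape[0]
    for e in range(E):
        n0, n1, n2, n3 = conn[e, 0], conn[e, 1], conn[e, 2], conn[e, 3]
        for g in range(4):
            f00 = 1.0; f01 = 0.0; f10 = 0.0; f11 = 1.0
            d00 = 0.0; d01 = 0.0; d10 = 0.0; d11 = 0.0
            for a in range(4):
                na = conn[e, a]
                gx = G[e, g, a, 0]
                gy = G[e, g, a, 1]
                f00 += u[na, 0] * gx
                f01 += u[na, 0] * gy
                f10 += u[na, 1] * gx
                f11 += u[na, 1] * gy
                d00 += v[na, 0] * gx
                d01 += v[na, 0] * gy
                d10 += v[na, 1] * gx
                d11 += v[na, 1] * gy
            det = f00 * f11 - f01 * f10
            if det <= 0.0:
                return e
            F[e, g, 0, 0] = f00
            F[e, g, 0, 1] = f01
            F[e, g, 1, 0] = f10
            F[e, g, 1, 1] = f11
            detF[e, g] = det
            i00 = f11 / det
            i01 = -f01 / det
            i10 = -f10 / det
            i11 = f00 / det
            L[e, g, 0, 0] = d00 * i00 + d01 * i10
            L[e, g, 0, 1] = d00 * i01 + d01 * i11
            L[e, g, 1, 0] = d10 * i00 + d11 * i10
            L[e, g, 1, 1] = d10 * i01 + d11 * i11
    return -1


@njit(cache=False)
def _kern_stress(F, detF, L, hel, h, s_prev, sigma, G0, Ginf, K, x, xm,
                 qlin, eta):
    """Viscoelastic neo-Hookean stress update (plane strain), in place.

    ``qlin = b1 * rho * c_dil`` scales the linear bulk-viscosity mean
    stress ``q = qlin * h_e * tr D`` damping dilatational mesh ringing;
    ``eta`` is a small Newtonian shear viscosity damping element-scale
    (high-frequency) shear modes that the Prony branch, with its loss
    peak at 1/tau, leaves undamped.
    """
    E = F.shape[0]
    ginf = Ginf / G0
    for e in range(E):
        for g in range(4):
            f00 = F[e, g, 0, 0]
            f01 = F[e, g, 0, 1]
            f10 = F[e, g, 1, 0]
            f11 = F[e, g, 1, 1]
            J = detF[e, g]
            B11 = f00 * f00 + f01 * f01
            B22 = f10 * f10 + f11 * f11
            B12 = f00 * f10 + f01 * f11
            Jm23 = J ** (-2.0 / 3.0)
            trB = Jm23 * (B11 + B22 + 1.0)
            gJ = G0 / J
            s11 = gJ * (Jm23 * B11 - trB / 3.0)
            s22 = gJ * (Jm23 * B22 - trB / 3.0)
            s12 = gJ * Jm23 * B12
            h11 = x * h[e, g, 0] + xm * (s11 - s_prev[e, g, 0])
            h22 = x * h[e, g, 1] + xm * (s22 - s_prev[e, g, 1])
            h12 = x * h[e, g, 2] + xm * (s12 - s_prev[e, g, 2])
            h[e, g, 0] = h11
            h[e, g, 1] = h22
            h[e, g, 2] = h12
            s_prev[e, g, 0] = s11
            s_prev[e, g, 1] = s22
            s_prev[e, g, 2] = s12
            sd11 = ginf * s11 + (1.0 - ginf) * h11
            sd22 = ginf * s22 + (1.0 - ginf) * h22
            sd12 = ginf * s12 + (1.0 - ginf) * h12
            if eta > 0.0:
                trD3 = (L[e, g, 0, 0] + L[e, g, 1, 1]) / 3.0
                sd11 += 2.0 * eta * (L[e, g, 0, 0] - trD3)
                sd22 += 2.0 * eta * (L[e, g, 1, 1] - trD3)
                sd12 += eta * (L[e, g, 0, 1] + L[e, g, 1, 0])
            p = K * np.log(J) / J
            # viscous mean stress resists volume-rate (tension positive)
            p += qlin * hel[e] * (L[e, g, 0, 0] + L[e, g, 1, 1])
            sigma[e, g, 0] = sd11 + p
            sigma[e, g, 1] = sd22 + p
            sigma[e, g, 2] = sd12
            sigma[e, g, 3] = -(sd11 + sd22) + p


@njit(cache=False)
def _kern_internal_forces(F, sigma, conn, G, wdetJ, f):
    """Assemble nodal internal forces from per-GP stress, in place."""
    E = conn.shape[0]
    for e in range(E):
        for g in range(4):
            s11 = sigma[e, g, 0]
            s22 = sigma[e, g, 1]
            s12 = sigma[e, g, 2]
            f00 = F[e, g, 0, 0]
            f01 = F[e, g, 0, 1]
            f10 = F[e, g, 1, 0]
            f11 = F[e, g, 1, 1]
            # P = sigma * J F^{-T};  J F^{-T} = [[f11, -f10], [-f01, f00]]
            P00 = s11 * f11 - s12 * f01
            P01 = -s11 * f10 + s12 * f00
            P10 = s12 * f11 - s22 * f01
            P11 = -s12 * f10 + s22 * f00
            w = wdetJ[e, g]
            for a in range(4):
                na = conn[e, a]
                gx = G[e, g, a, 0]
                gy = G[e, g, a, 1]
                f[na, 0] += w * (P00 * gx + P01 * gy)
                f[na, 1] += w * (P10 * gx + P11 * gy)


@dataclass
class _Fields:
    """Element kinematics recorded for the injury metrics (per element)."""

    F: np.ndarray            # (E, 2, 2) deformation gradient, GP average
    L: np.ndarray            # (E, 2, 2) velocity gradient, GP average
    stress: np.ndarray       # (E, 3, 3) Cauchy stress, GP average


class SolidSolver:
    """Vectorized explicit solver on one mesh.

    ``exclude_fluid=True`` removes ``cavity_fluid`` elements from the solid
    assembly (the paired model couples them through the ALE fluid instead);
    their nodes remain and receive coupling forces.
    """

    def __init__(self, mesh: QuadMesh,
                 material: SolidMaterialParams = SolidMaterialParams(),
                 exclude_fluid: bool = True,
                 fix_outer_boundary: bool = True,
                 rotation_center=None,
                 use_numba: bool = True,
                 bulk_viscosity: float = 0.15,
                 shear_viscosity: float = 5e-3):
        self.mesh = mesh
        self.material = material
        self.use_numba = use_numba and _HAVE_NUMBA
        self.bulk_viscosity = bulk_viscosity
        self.shear_viscosity = shear_viscosity
        active = np.ones(mesh.n_elements, bool)
        if exclude_fluid:
            active &= mesh.element_material != MAT_FLUID
        self.active = active
        self.conn = mesh.element_connectivity[active]
        X = mesh.node_coordinates
        self.n_nodes = mesh.n_nodes
        self.rotation_center = (np.asarray(rotation_center, float)
                                if rotation_center is not None
                                else X.mean(axis=0))

        E = self.conn.shape[0]
        xe = X[self.conn]                       # (E, 4, 2)
        self.gradN0 = np.empty((E, 4, 4, 2))    # (E, gp, node, comp)
        self.wdetJ = np.empty((E, 4))
        for g in range(4):
            dN = _shape_gradients(_XI[g])                    # (4, 2)
            J = np.einsum("eai,aj->eij", xe, dN)             # dX/dxi (2,2)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            if np.any(detJ <= 0):
                raise ValueError("non-positive Jacobian in solid mesh")
            inv = np.empty_like(J)
            inv[:, 0, 0] = J[:, 1, 1] / detJ
            inv[:, 0, 1] = -J[:, 0, 1] / detJ
            inv[:, 1, 0] = -J[:, 1, 0] / detJ
            inv[:, 1, 1] = J[:, 0, 0] / detJ
            self.gradN0[:, g] = np.einsum("aj,eji->eai", dN, inv)
            self.wdetJ[:, g] = detJ

        # lumped mass: a quarter of each element's mass to each node
        self.areas = np.abs(self.wdetJ).sum(axis=1)
        self.mass = np.zeros(self.n_nodes)
        np.add.at(self.mass, self.conn.ravel(),
                  np.repeat(material.density * self.areas / 4.0, 4))
        self.free = self.mass > 0
        self.fixed = np.zeros(self.n_nodes, bool)
        if fix_outer_boundary:
            edges = mesh.boundary_sets.get("outer_skull")
            if edges is not None and len(edges):
                self.fixed[np.unique(edges)] = True

        self.char_length = self.areas / np.linalg.norm(
            np.roll(X[self.conn], -1, axis=1) - X[self.conn], axis=2
        ).max(axis=1)
        c_dil = np.sqrt((material.K + 4 * material.G0 / 3) / material.density)
        self._qlin = self.bulk_viscosity * material.density * c_dil

        self.u = np.zeros((self.n_nodes, 2))
        self.v = np.zeros((self.n_nodes, 2))
        self.t = 0.0
        self.step_count = 0
        # viscoelastic history per GP, traceless: (h11, h22, h12) + s_prev
        self.h = np.zeros((E, 4, 3))
        self.s_prev = np.zeros((E, 4, 3))
        # per-GP Cauchy stress components (s11, s22, s12, s33)
        self.sigma = np.zeros((E, 4, 4))
        self._F = np.tile(np.eye(2), (E, 4, 1, 1))
        self._L = np.zeros((E, 4, 2, 2))
        self._detF = np.ones((E, 4))

    # ------------------------------------------------------------------
    def _kinematics(self) -> None:
        """Update per-GP F and L from current nodal displacement/velocity."""
        if self.use_numba:
            E = self.conn.shape[0]
            F = np.empty((E, 4, 2, 2))
            L = np.empty((E, 4, 2, 2))
            detF = np.empty((E, 4))
            bad = _kern_kinematics(self.u, self.v, self.conn, self.gradN0,
                                   F, L, detF)
            if bad >= 0:
                raise RuntimeError(
                    f"element inversion (det F <= 0) in element {bad} "
                    f"at step {self.step_count}, t = {self.t:.6e} s")
            self._F, self._L, self._detF = F, L, detF
            return
        ue = self.u[self.conn]                  # (E, 4, 2)
        ve = self.v[self.conn]
        G = self.gradN0                         # (E, g, a, j)
        # F_ij = delta_ij + sum_a u[a,i] G[g,a,j]; accumulate over the four
        # nodes with scalar-column broadcasts (fastest layout at this size)
        E = G.shape[0]
        F = np.zeros((E, 4, 2, 2))
        dvdX = np.zeros((E, 4, 2, 2))
        for a in range(4):
            Ga = G[:, :, a, :]                  # (E, g, j)
            for i in range(2):
                F[:, :, i, :] += ue[:, a, i, None, None] * Ga
                dvdX[:, :, i, :] += ve[:, a, i, None, None] * Ga
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(detF <= 0):
            e = int(np.argwhere(detF <= 0)[0][0])
            raise RuntimeError(
                f"element inversion (det F <= 0) in element {e} "
                f"at step {self.step_count}, t = {self.t:.6e} s")
        Finv = np.empty_like(F)
        Finv[..., 0, 0] = F[..., 1, 1] / detF
        Finv[..., 0, 1] = -F[..., 0, 1] / detF
        Finv[..., 1, 0] = -F[..., 1, 0] / detF
        Finv[..., 1, 1] = F[..., 0, 0] / detF
        self._F = F
        self._detF = detF
        L = np.empty_like(F)
        for i in range(2):
            for j in range(2):
                L[..., i, j] = (dvdX[..., i, 0] * Finv[..., 0, j]
                                + dvdX[..., i, 1] * Finv[..., 1, j])
        self._L = L

    def _update_stress(self, dt: float) -> None:
        """Componentwise viscoelastic neo-Hookean update (plane strain)."""
        m = self.material
        if self.use_numba:
            if dt > 0.0:
                x = np.exp(-dt / m.tau)
                xm = np.exp(-dt / (2.0 * m.tau))
            else:
                x = xm = 1.0
            _kern_stress(self._F, self._detF, self._L, self.char_length,
                         self.h, self.s_prev,
                         self.sigma, m.G0, m.Ginf, m.K, x, xm, self._qlin,
                         self.shear_viscosity)
            return
        F = self._F
        J = self._detF
        B11 = F[..., 0, 0] ** 2 + F[..., 0, 1] ** 2
        B22 = F[..., 1, 0] ** 2 + F[..., 1, 1] ** 2
        B12 = F[..., 0, 0] * F[..., 1, 0] + F[..., 0, 1] * F[..., 1, 1]
        Jm23 = J ** (-2.0 / 3.0)
        trB = Jm23 * (B11 + B22 + 1.0)
        gJ = m.G0 / J
        s11 = gJ * (Jm23 * B11 - trB / 3.0)
        s22 = gJ * (Jm23 * B22 - trB / 3.0)
        s12 = gJ * Jm23 * B12
        s = np.stack([s11, s22, s12], axis=-1)
        ginf = m.Ginf / m.G0
        if dt > 0.0:
            x = np.exp(-dt / m.tau)
            xm = np.exp(-dt / (2.0 * m.tau))
            self.h = x * self.h + xm * (s - self.s_prev)
        else:
            self.h = self.h + (s - self.s_prev)
        self.s_prev = s
        sd = ginf * s + (1.0 - ginf) * self.h
        if self.shear_viscosity > 0.0:
            Lc = self._L
            trD3 = (Lc[..., 0, 0] + Lc[..., 1, 1]) / 3.0
            eta = self.shear_viscosity
            sd = sd.copy()
            sd[..., 0] += 2.0 * eta * (Lc[..., 0, 0] - trD3)
            sd[..., 1] += 2.0 * eta * (Lc[..., 1, 1] - trD3)
            sd[..., 2] += eta * (Lc[..., 0, 1] + Lc[..., 1, 0])
        p = m.K * np.log(J) / J
        p = p + self._qlin * self.char_length[:, None] * (
            self._L[..., 0, 0] + self._L[..., 1, 1])
        self.sigma[..., 0] = sd[..., 0] + p
        self.sigma[..., 1] = sd[..., 1] + p
        self.sigma[..., 2] = sd[..., 2]
        self.sigma[..., 3] = -(sd[..., 0] + sd[..., 1]) + p   # sigma_33

    def internal_forces(self) -> np.ndarray:
        """Assembled nodal internal forces, (N, 2), from the current state.

        Per Gauss point the first Piola stress P = J sigma F^{-T} is
        contracted with the reference shape-function gradients; a uniform
        stress state on a structured patch yields zero interior force.
        """
        if self.use_numba:
            f = np.zeros((self.n_nodes, 2))
            _kern_internal_forces(self._F, self.sigma, self.conn,
                                  self.gradN0, self.wdetJ, f)
            return f
        F = self._F
        s11 = self.sigma[..., 0]
        s22 = self.sigma[..., 1]
        s12 = self.sigma[..., 2]
        # P = sigma * J F^{-T}; J F^{-T} = [[F22, -F21], [-F12, F11]]
        P = np.empty_like(F)
        P[..., 0, 0] = s11 * F[..., 1, 1] - s12 * F[..., 0, 1]
        P[..., 0, 1] = -s11 * F[..., 1, 0] + s12 * F[..., 0, 0]
        P[..., 1, 0] = s12 * F[..., 1, 1] - s22 * F[..., 0, 1]
        P[..., 1, 1] = -s12 * F[..., 1, 0] + s22 * F[..., 0, 0]
        # f[a,i] = sum_g w P[g,i,j] G[g,a,j]
        G = self.gradN0
        wP = self.wdetJ[..., None, None] * P        # (E, g, 2, 2)
        fe = np.empty((G.shape[0], 4, 2))
        for a in range(4):
            Ga = G[:, :, a, :]                      # (E, g, j)
            fe[:, a, 0] = (wP[:, :, 0, :] * Ga).sum(axis=(1, 2))
            fe[:, a, 1] = (wP[:, :, 1, :] * Ga).sum(axis=(1, 2))
        f = np.zeros((self.n_nodes, 2))
        np.add.at(f, self.conn.ravel(), fe.reshape(-1, 2))
        return f

    def step(self, dt: float, body_accel=None, external_forces=None) -> None:
        """One central-difference step.

        ``body_accel``: (N, 2) acceleration field (fictitious frame forces);
        ``external_forces``: (N, 2) nodal forces (e.g. FSI coupling).
        """
        f = -self.internal_forces()
        if external_forces is not None:
            f += external_forces
        a = np.zeros_like(f)
        a[self.free] = f[self.free] / self.mass[self.free, None]
        if body_accel is not None:
            a[self.free] += body_accel[self.free]
        self.v += dt * a
        self.v[self.fixed] = 0.0
        self.v[~self.free] = 0.0
        self.u += dt * self.v
        self.t += dt
        self.step_count += 1
        self._kinematics()
        self._update_stress(dt)
        if self.step_count % 50 == 0 and not np.all(np.isfinite(self.u)):
            n = int(np.argwhere(~np.isfinite(self.u))[0][0])
            raise RuntimeError(
                f"non-finite displacement at node {n}, step {self.step_count}")

    # ------------------------------------------------------------------
    def element_fields(self) -> _Fields:
        """GP-averaged per-element F, L, and Cauchy stress (active elements)."""
        F = self._F.mean(axis=1)
        L = self._L.mean(axis=1)
        s = self.sigma.mean(axis=1)
        stress = np.zeros(F.shape[:1] + (3, 3))
        stress[:, 0, 0] = s[:, 0]
        stress[:, 1, 1] = s[:, 1]
        stress[:, 0, 1] = stress[:, 1, 0] = s[:, 2]
        stress[:, 2, 2] = s[:, 3]
        return _Fields(F=F, L=L, stress=stress)

    def energies(self) -> tuple[float, float]:
        """(kinetic, strain) energy, J per unit thickness.

        Strain energy uses the instantaneous (G0) hyperelastic potential;
        with the viscous branch relaxing, kinetic + strain is bounded.
        """
        ke = 0.5 * float(np.sum(self.mass[:, None] * self.v**2))
        m = self.material
        F = self._F
        J = self._detF
        B11 = F[..., 0, 0] ** 2 + F[..., 0, 1] ** 2
        B22 = F[..., 1, 0] ** 2 + F[..., 1, 1] ** 2
        trB = J ** (-2.0 / 3.0) * (B11 + B22 + 1.0)
        psi = 0.5 * m.G0 * (trB - 3.0) + 0.5 * m.K * np.log(J) ** 2
        se = float(np.sum(self.wdetJ * psi))
        return ke, se
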