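"""Constitutive models for the cerebrospinal fluid and brain tissue.

The fluid follows a Mie-Grüneisen (shock-Hugoniot) equation of state for its
dilatational response, a Newtonian deviatoric law for shear, and a cut-off
(cavitation) pressure that bounds sustained tension.  The brain solid is a
nearly incompressible neo-Hookean material with a one-term Prony-series shear
relaxation, evaluated in plane strain.

Units are SI throughout: Pa, kg/m^3, m/s, s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EOSParams",
    "ViscousParams",
    "SolidMaterialParams",
    "ViscoHistory",
    "eos_pressure",
    "reference_sound_speed",
    "viscous_deviatoric_stress",
    "solid_cauchy_stress",
]


@dataclass(frozen=True)
class EOSParams:
    """Grüneisen equation-of-state constants for cerebrospinal fluid.

    ``C`` is the intercept and ``S1..S3`` the slope coefficients of the
    shock-velocity / particle-velocity fit; ``gamma0`` the Grüneisen gamma,
    ``a`` its first-order volume correction, and ``Pc`` the (negative)
    cut-off pressure emulating cavitation.
    """

    rho0: float = 1000.0        # kg/m^3
    C: float = 1482.9           # m/s
    S1: float = 2.10
    S2: float = -0.17
    S3: float = 0.01
    a: float = 0.0
    gamma0: float = 1.2
    Pc: float = -22.0e6         # Pa

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.Pc >= 0:
            raise ValueError("cut-off pressure Pc must be negative")


@dataclass(frozen=True)
class ViscousParams:
    """Newtonian deviatoric law sigma_v = gamma_visc * deviatoric strain rate.

    ``factor_two`` switches to the conventional sigma' = 2*gamma*D' form;
    the default follows the single-gamma form.  At gamma ~ 1 mPa·s the
    difference is dynamically negligible.
    """

    gamma_visc: float = 0.001   # Pa·s
    factor_two: bool = False

    def __post_init__(self) -> None:
        if self.gamma_visc < 0:
            raise ValueError("dynamic viscosity must be non-negative")


@dataclass(frozen=True)
class SolidMaterialParams:
    """Hyper-viscoelastic brain parenchyma (plane strain).

    G0/Ginf are the instantaneous and long-term shear moduli of a one-term
    Prony series with relaxation time tau; K is the bulk modulus (softened
    relative to true near-incompressibility to keep the explicit time step
    tractable).
    """

    density: float = 1040.0     # kg/m^3
    G0: float = 2.2e3           # Pa
    Ginf: float = 1.0e3         # Pa
    tau: float = 0.010          # s
    K: float = 50.0e6           # Pa

    def __post_init__(self) -> None:
        if not (self.G0 >= self.Ginf > 0):
            raise ValueError("need G0 >= Ginf > 0")
        if self.K <= self.G0:
            raise ValueError("bulk modulus must dominate shear modulus")


def eos_pressure(mu, params: EOSParams = EOSParams()):
    """Pressure from relative compression ``mu = rho/rho0 - 1``.

    Compression (mu >= 0) uses the Grüneisen ratio form

        P = rho0 C^2 mu [1 + (1 - gamma0/2) mu - (a/2) mu^2]
            / [1 - (S1-1) mu - S2 mu^2/(mu+1) - S3 mu^3/(mu+1)^2]^2

    while tension (mu < 0) uses the linearized P = rho0 C^2 mu.  The result
    is clamped from below at the cut-off pressure ``Pc`` (cavitation: the
    fluid cannot sustain large tension).  Accepts scalars or arrays.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= -1.0):
        raise ValueError("mu <= -1 corresponds to non-physical density")
    rc2 = params.rho0 * params.C**2
    num = rc2 * mu * (1.0 + (1.0 - params.gamma0 / 2.0) * mu
                      - (params.a / 2.0) * mu**2)
    den = (1.0 - (params.S1 - 1.0) * mu
           - params.S2 * mu**2 / (mu + 1.0)
           - params.S3 * mu**3 / (mu + 1.0) ** 2) ** 2
    p = np.where(mu >= 0.0, num / den, rc2 * mu)
    p = np.maximum(p, params.Pc)
    if p.ndim == 0:
        return float(p)
    return p


def reference_sound_speed(params: EOSParams = EOSParams()) -> float:
    """Linearized sound speed sqrt(dP/drho) at mu = 0; equals ``C``.

    Both branches of :func:`eos_pressure` have slope rho0*C^2 in mu at the
    reference state, and drho = rho0 dmu, so the speed is C by construction.
    """
    return params.C


def viscous_deviatoric_stress(Ddev: np.ndarray,
                              params: ViscousParams = ViscousParams(),
                              tol: float = 1e-9) -> np.ndarray:
    """Newtonian deviatoric stress sigma_v = gamma * D' (component-wise).

    ``Ddev`` must be a traceless (deviatoric) rate-of-deformation tensor in
    1/s; the output is a traceless stress tensor in Pa.
    """
    D = np.asarray(Ddev, dtype=float)
    scale = max(np.abs(D).max(), 1.0)
    if abs(np.trace(D)) > tol * scale:
        raise ValueError("input rate-of-deformation tensor is not deviatoric")
    factor = 2.0 if params.factor_two else 1.0
    return factor * params.gamma_visc * D


@dataclass
class ViscoHistory:
    """Internal state for the Prony-series deviatoric relaxation.

    ``h`` is the relaxing deviatoric stress variable and ``s_prev`` the
    instantaneous (G0) deviatoric stress at the previous step; shapes follow
    the stress tensor (3x3, or batched (..., 3, 3)).
    """

    h: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    s_prev: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    @classmethod
    def zeros(cls, shape=()) -> "ViscoHistory":
        return cls(h=np.zeros(shape + (3, 3)), s_prev=np.zeros(shape + (3, 3)))


def _plane_strain_F3(F: np.ndarray) -> np.ndarray:
    """Embed a 2x2 in-plane deformation gradient as 3x3 with F33 = 1."""
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] == (3, 3):
        return F
    F3 = np.zeros(F.shape[:-2] + (3, 3))
    F3[..., :2, :2] = F
    F3[..., 2, 2] = 1.0
    return F3


def solid_cauchy_stress(F: np.ndarray, history: ViscoHistory, dt: float,
                        params: SolidMaterialParams = SolidMaterialParams()):
    """Cauchy stress of the viscoelastic brain solid plus updated history.

    Deviatoric part: neo-Hookean instantaneous response
    s = (G0/J) dev(J^(-2/3) B) relaxed through a one-term Prony series
    G(t) = Ginf + (G0 - Ginf) exp(-t/tau) via the midpoint internal-variable
    recurrence.  Volumetric part: K ln(J) / J.  Accepts a single 2x2/3x3
    gradient or a batch (..., 2, 2).
    """
    F3 = _plane_strain_F3(F)
    J = np.asarray(np.linalg.det(F3))
    if np.any(J <= 0.0):
        raise ValueError("element inversion: det F <= 0")
    B = F3 @ np.swapaxes(F3, -1, -2)
    Jm23 = J ** (-2.0 / 3.0)
    Bbar = Jm23[..., None, None] * B
    eye = np.broadcast_to(np.eye(3), B.shape)
    trBbar = np.trace(Bbar, axis1=-2, axis2=-1)
    dev_Bbar = Bbar - (trBbar / 3.0)[..., None, None] * eye
    s = (params.G0 / J)[..., None, None] * dev_Bbar

    ginf = params.Ginf / params.G0
    if dt > 0.0:
        x = np.exp(-dt / params.tau)
        xm = np.exp(-dt / (2.0 * params.tau))
        h_new = x * history.h + xm * (s - history.s_prev)
    else:
        h_new = history.h + (s - history.s_prev)
    sigma_dev = ginf * s + (1.0 - ginf) * h_new

    p_vol = params.K * np.log(J) / J
    sigma = sigma_dev + p_vol[..., None, None] * eye
    return sigma, ViscoHistory(h=h_new, s_prev=s)
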