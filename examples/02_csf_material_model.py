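"""Evaluate the cerebrospinal-fluid material model at a few states.

The CSF follows a Grüneisen (shock-Hugoniot) equation of state whose
linearized sound speed equals the tabulated intercept C = 1482.9 m/s, a
Newtonian shear law with a 1 mPa·s viscosity, and a -22 MPa cut-off
pressure standing in for cavitation: the fluid transmits compression
stiffly but cannot sustain large tension.
"""

import numpy as np

from pericav import (EOSParams, ViscousParams, eos_pressure,
                     reference_sound_speed, viscous_deviatoric_stress)

eos = EOSParams()
print(f"reference sound speed: {reference_sound_speed(eos):.1f} m/s")

for mu in (1e-4, 1e-3, 1e-2, -1e-3, -0.015):
    p = eos_pressure(mu, eos)
    tag = "  <- clamped at the cavitation cut-off" if p == eos.Pc else ""
    print(f"  mu = {mu:+.4f}  ->  P = {p / 1e6:+9.4f} MPa{tag}")

D = np.zeros((3, 3))
D[0, 1] = D[1, 0] = 50.0     # 50 1/s shear rate, impact scale
tau = viscous_deviatoric_stress(D, ViscousParams())
print(f"\nshear stress at a 50 1/s deviatoric rate: {tau[0, 1] * 1e3:.2f} mPa"
      " - the CSF is mechanically shear-free at impact rates")
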