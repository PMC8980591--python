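"""Impulsive head-impact loading: smooth acceleration pulses.

Only peak magnitudes of the six video-confirmed football impacts are
available (Table of cases below); full kinematic traces are not, so the
waveform is an idealized haversine (sin^2) or half-sine pulse of
configurable duration, applied as an in-plane translational acceleration
plus an out-of-plane angular acceleration in the skull-fixed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LoadCase", "generate_load_case", "default_load_cases",
           "IMPACT_CASES", "GRAVITY"]

GRAVITY = 9.81  # m/s^2 per g

# Peak resultant translational acceleration (g), peak resultant rotational
# acceleration (krad/s^2) and injury severity of the six simulated impacts.
IMPACT_CASES = (
    {"label": "Case 1", "peak_translation_g": 106.1,
     "peak_rotation_krad_s2": 12.95, "severity": "concussion"},
    {"label": "Case 2", "peak_translation_g": 84.2,
     "peak_rotation_krad_s2": 6.19, "severity": "concussion"},
    {"label": "Case 3", "peak_translation_g": 134.0,
     "peak_rotation_krad_s2": 7.50, "severity": "concussion"},
    {"label": "Case 4", "peak_translation_g": 71.9,
     "peak_rotation_krad_s2": 7.75, "severity": "sub-concussion"},
    {"label": "Case 5", "peak_translation_g": 20.4,
     "peak_rotation_krad_s2": 4.14, "severity": "sub-concussion"},
    {"label": "Case 6", "peak_translation_g": 78.8,
     "peak_rotation_krad_s2": 6.24, "severity": "sub-concussion"},
)


@dataclass
class LoadCase:
    """Skull-frame kinematic load: uniform time samples of accelerations."""

    times: np.ndarray       # s
    a_x: np.ndarray         # m/s^2
    a_y: np.ndarray         # m/s^2
    alpha_z: np.ndarray     # rad/s^2
    label: str = ""
    severity: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def translational(self, t: float) -> np.ndarray:
        """Interpolated (a_x, a_y) at time t (zero outside the window)."""
        ax = np.interp(t, self.times, self.a_x, left=0.0, right=0.0)
        ay = np.interp(t, self.times, self.a_y, left=0.0, right=0.0)
        return np.array([ax, ay])

    def angular(self, t: float) -> float:
        return float(np.interp(t, self.times, self.alpha_z,
                               left=0.0, right=0.0))

    def angular_velocity(self, t: float) -> float:
        """omega_z(t): cumulative trapezoid integral of alpha_z."""
        omega = np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.alpha_z[1:] + self.alpha_z[:-1])
                              * np.diff(self.times))])
        return float(np.interp(t, self.times, omega,
                               left=0.0, right=omega[-1]))


def _pulse(shape: str, times: np.ndarray, duration: float) -> np.ndarray:
    if shape == "haversine":
        return np.sin(np.pi * times / duration) ** 2
    if shape == "half-sine":
        return np.sin(np.pi * times / duration)
    raise ValueError(f"unknown pulse shape {shape!r}")


def generate_load_case(peak_translation: float, peak_rotation: float,
                       duration: float = 0.010, shape: str = "haversine",
                       direction: float = 0.0, n_samples: int = 1001,
                       label: str = "", severity: str = "",
                       metadata: dict | None = None) -> LoadCase:
    """Build a pulse with the requested peak magnitudes.

    ``peak_translation`` (m/s^2) is applied along the in-plane unit vector
    at angle ``direction``; ``peak_rotation`` (rad/s^2) about the
    out-of-plane axis.  The series starts and ends at zero and the sample
    grid contains the mid-pulse instant, so the sampled peak equals the
    requested peak exactly.
    """
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    if n_samples % 2 == 0:
        n_samples += 1  # keep the t = T/2 sample on the grid
    times = np.linspace(0.0, duration, n_samples)
    s = _pulse(shape, times, duration)
    s[0] = s[-1] = 0.0        # exact endpoint zeros (round-off of sin(pi))
    a = peak_translation * s
    return LoadCase(
        times=times,
        a_x=a * np.cos(direction),
        a_y=a * np.sin(direction),
        alpha_z=peak_rotation * s,
        label=label,
        severity=severity,
        metadata=dict(metadata or {}),
    )


def default_load_cases(duration: float = 0.010, shape: str = "haversine",
                       n_samples: int = 1001) -> list[LoadCase]:
    """The six impact cases at their printed peak magnitudes."""
    out = []
    for case in IMPACT_CASES:
        out.append(generate_load_case(
            peak_translation=case["peak_translation_g"] * GRAVITY,
            peak_rotation=case["peak_rotation_krad_s2"] * 1e3,
            duration=duration, shape=shape, n_samples=n_samples,
            label=case["label"], severity=case["severity"],
            metadata=dict(case),
        ))
    return out
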