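"""Minimum-jerk movement primitive.

The elementary submovement used throughout the package is the minimum-jerk
velocity pulse

    v(t) = 30 (L / D) tau^2 (1 - tau)^2,   tau = t / D in [0, 1],

which traverses a distance ``L`` (m) in a duration ``D`` (s).  Its closed
forms make it a convenient analytic oracle for the feature extractors:

* peak speed      v_max = 15 L / (8 D)       (at tau = 1/2)
* peak |accel|    a_max = (10 / sqrt(3)) L / D^2
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "velocity",
    "acceleration",
    "peak_velocity",
    "peak_acceleration",
    "pulse_energy",
]


def velocity(t: np.ndarray, distance: float, duration: float) -> np.ndarray:
    """Minimum-jerk speed profile at times ``t`` (seconds from pulse onset).

    Zero outside [0, duration].
    """
    tau = np.asarray(t, dtype=float) / duration
    v = 30.0 * (distance / duration) * tau**2 * (1.0 - tau) ** 2
    return np.where((tau >= 0.0) & (tau <= 1.0), v, 0.0)


def acceleration(t: np.ndarray, distance: float, duration: float) -> np.ndarray:
    """Time derivative of :func:`velocity`; zero outside the pulse support."""
    tau = np.asarray(t, dtype=float) / duration
    a = 60.0 * (distance / duration**2) * tau * (1.0 - tau) * (1.0 - 2.0 * tau)
    return np.where((tau >= 0.0) & (tau <= 1.0), a, 0.0)


def peak_velocity(distance: float, duration: float) -> float:
    return 15.0 * distance / (8.0 * duration)


def peak_acceleration(distance: float, duration: float) -> float:
    return (10.0 / np.sqrt(3.0)) * distance / duration**2


def pulse_energy(distance: float, duration: float) -> float:
    """Integral of a(t)^2 over the pulse: (120/7) L^2 / D^3.

    With a = 60 (L/D^2) f(tau), f = tau(1-tau)(1-2tau),
    int f^2 dtau = 1/210, hence int a^2 dt = 3600/210 * L^2/D^3.
    """
    return (3600.0 / 210.0) * distance**2 / duration**3
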