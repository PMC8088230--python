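"""Projection of ball kinematics into the monocular optic variables seen
from the eye.

Variables follow the standard interception-geometry conventions:

* ``theta`` — angular (retinal) size of the ball, ``2*arctan(r/d)``;
* ``gamma`` — elevation angle between the line of sight and the eye-level
  plane, ``arctan(y/rho)`` with ``rho`` the horizontal distance;
* ``gamma_dot`` — its rate of change, computed analytically as
  ``(y'*rho - y*rho')/d**2``;
* ``beta`` — azimuth from the initial line of sight, ``atan2(|x|, z)``,
  so values above pi/2 mean the ball has passed behind the observer's
  frontal plane.

All angles are in radians internally; degrees appear only at file I/O
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, GeometryError, InsideBallError
from .geometry import KinematicState, TrajectorySpec, track_arrays


@dataclass(frozen=True)
class OpticState:
    """Monocular optic variables of the ball at one instant.

    Angles in radians, rates in rad/s, distance in metres.
    """

    t: float
    theta: float
    gamma: float
    gamma_dot: float
    beta: float
    d: float


def project_optics(state: KinematicState, ball_radius: float) -> OpticState:
    """Project one kinematic state into optic variables.

    Raises
    ------
    InsideBallError
        If the eye-ball distance does not exceed the ball radius.
    DegenerateGeometryError
        If the horizontal distance is zero (elevation undefined).
    """
    x, y, z = state.x, state.y, state.z
    d = math.sqrt(x * x + y * y + z * z)
    if d <= ball_radius:
        raise InsideBallError(f"eye-ball distance {d:.4f} m <= radius {ball_radius} m")
    rho = math.hypot(x, z)
    if rho < 1e-12:
        raise DegenerateGeometryError("elevation angle undefined at rho = 0")
    rho_dot = (x * state.vx + z * state.vz) / rho
    return OpticState(
        t=state.t,
        theta=2.0 * math.atan(ball_radius / d),
        gamma=math.atan(y / rho),
        gamma_dot=(state.vy * rho - y * rho_dot) / (d * d),
        beta=math.atan2(abs(x), z),
        d=d,
    )


def optic_arrays(spec: TrajectorySpec, t: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised optic variables over an array of times.

    Returns a dict of equal-length arrays keyed ``t, theta, gamma,
    gamma_dot, beta, d`` (plus the underlying ``rho``).  States with the
    eye inside the ball are not filtered here; callers clip as needed.
    """
    k = track_arrays(spec, np.asarray(t, dtype=float))
    x, y, z = k["x"], k["y"], k["z"]
    d = np.sqrt(x * x + y * y + z * z)
    rho = np.hypot(x, z)
    if np.any(rho < 1e-12):
        raise DegenerateGeometryError("elevation angle undefined at rho = 0")
    rho_dot = (x * k["vx"] + z * k["vz"]) / rho
    return {
        "t": k["t"],
        "theta": 2.0 * np.arctan(spec.ball_radius / d),
        "gamma": np.arctan(y / rho),
        "gamma_dot": (k["vy"] * rho - y * rho_dot) / (d * d),
        "beta": np.arctan2(np.abs(x), z),
        "d": d,
        "rho": rho,
    }


def optic_state_at(spec: TrajectorySpec, t: float) -> OpticState:
    """Optic variables of ``spec`` at time ``t`` (range-checked)."""
    from .geometry import ball_state

    return project_optics(ball_state(spec, t), spec.ball_radius)


def optic_series(spec: TrajectorySpec, dt: float) -> list[OpticState]:
    """Optic variables sampled at t = 0, dt, ..., T.

    The final grid point is forced to land on T.  Samples where the eye
    would be inside the ball (d <= r) are dropped from the end of the
    series; time stamps are strictly increasing.
    """
    T = spec.flight_time
    if not (0 < dt <= T):
        raise GeometryError(f"dt must lie in (0, T]; got {dt}")
    n = int(round(T / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    t = t[t <= T + 1e-12]
    if t[-1] < T - 1e-12:
        t = np.append(t, T)
    arr = optic_arrays(spec, t)
    keep = arr["d"] > spec.ball_radius
    return [
        OpticState(
            t=float(arr["t"][i]),
            theta=float(arr["theta"][i]),
            gamma=float(arr["gamma"][i]),
            gamma_dot=float(arr["gamma_dot"][i]),
            beta=float(arr["beta"][i]),
            d=float(arr["d"][i]),
        )
        for i in np.nonzero(keep)[0]
    ]


def series_frame(spec: TrajectorySpec, dt: float):
    """Optic series as a pandas DataFrame with the canonical CSV columns."""
    import pandas as pd

    states = optic_series(spec, dt)
    return pd.DataFrame(
        {
            "t_s": [s.t for s in states],
            "theta_rad": [s.theta for s in states],
            "gamma_rad": [s.gamma for s in states],
            "gamma_dot_rad_s": [s.gamma_dot for s in states],
            "beta_rad": [s.beta for s in states],
            "d_m": [s.d for s in states],
        }
    )
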