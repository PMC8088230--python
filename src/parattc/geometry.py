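"""Closed-form kinematics of a gravity-only parabolic flight in an
observer-centred frame.

The frame is right-handed with the eye at the origin: +y up, +z pointing
toward the ball's initial position, x lateral.  Eye level is the plane
y = 0; the ball is launched from (0, 0, z_init) and lands at
(+/-x_end, 0, z_end) after ``flight_time`` seconds.  Horizontal velocity
components are constant (no drag or spin); the vertical launch speed is
fixed at g*T/2 so the ball returns to eye level exactly at t = T.

Lateral handedness is carried as a ``side`` label; all derived geometry
depends on ``|x|`` only, so mirrored trajectories are equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateGeometryError, GeometryError, ValidationError

STANDARD_GRAVITY = 9.807  # m/s^2, sea-level standard
SOCCER_BALL_RADIUS = 0.11  # m

_SIDES = ("left", "right")


@dataclass(frozen=True)
class TrajectorySpec:
    """One parabolic flight launched and landing at eye level.

    Parameters
    ----------
    z_init
        Depth of the launch point, metres (must be positive: the ball
        starts in front of the observer).
    x_end
        Magnitude of the lateral landing offset, metres.
    z_end
        Depth of the landing point, metres; negative values put the
        landing point behind the observer.
    flight_time
        Total flight duration T, seconds.
    g
        Gravitational acceleration, m/s^2.
    ball_radius
        Physical ball radius, metres.
    side
        ``"left"`` or ``"right"``: sign of the lateral offset.
    gs_rel
        Optional design label: fraction of flight time at which the
        gravity+size TTC model was designed to have zero error.
    traj_id
        Optional identifier used in trial tables and CSV output.
    """

    z_init: float
    x_end: float
    z_end: float
    flight_time: float
    g: float = STANDARD_GRAVITY
    ball_radius: float = SOCCER_BALL_RADIUS
    side: str = "right"
    gs_rel: float | None = None
    traj_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.flight_time > 0):
            raise ValidationError(f"flight_time must be > 0, got {self.flight_time}")
        if not (self.g > 0):
            raise ValidationError(f"g must be > 0, got {self.g}")
        if not (self.ball_radius > 0):
            raise ValidationError(f"ball_radius must be > 0, got {self.ball_radius}")
        if not (self.z_init > 0):
            raise ValidationError(f"z_init must be > 0, got {self.z_init}")
        if self.x_end < 0:
            raise ValidationError("x_end is a magnitude and must be >= 0")
        if self.side not in _SIDES:
            raise ValidationError(f"side must be one of {_SIDES}, got {self.side!r}")
        if self.gs_rel is not None and not (0 < self.gs_rel < 1):
            raise ValidationError(f"gs_rel must lie in (0, 1), got {self.gs_rel}")

    @property
    def sign(self) -> int:
        """Lateral sign: +1 for right, -1 for left."""
        return 1 if self.side == "right" else -1

    def mirrored(self) -> "TrajectorySpec":
        """The same flight reflected to the other side."""
        other = "left" if self.side == "right" else "right"
        return replace(self, side=other)

    def with_flight_time(self, flight_time: float) -> "TrajectorySpec":
        """Same ground track, different flight duration."""
        return replace(self, flight_time=flight_time)


@dataclass(frozen=True)
class KinematicState:
    """Ball position and velocity at one instant, observer frame (m, m/s)."""

    t: float
    x: float
    y: float
    z: float
    vx: float
    vy: float
    vz: float


def launch_velocity(spec: TrajectorySpec) -> tuple[float, float, float]:
    """Launch velocity (vx, vy0, vz) in m/s.

    Horizontal components are fixed by the endpoints and flight time;
    the vertical component g*T/2 makes y(T) = 0 exactly.
    """
    T = spec.flight_time
    vx = spec.sign * spec.x_end / T
    vz = (spec.z_end - spec.z_init) / T
    vy0 = spec.g * T / 2.0
    return vx, vy0, vz


def ball_state(spec: TrajectorySpec, t: float) -> KinematicState:
    """Ball kinematics at time ``t`` seconds after launch (0 <= t <= T)."""
    if not (0.0 <= t <= spec.flight_time):
        raise GeometryError(
            f"t = {t} outside flight interval [0, {spec.flight_time}]"
        )
    vx, vy0, vz = launch_velocity(spec)
    return KinematicState(
        t=t,
        x=vx * t,
        y=vy0 * t - 0.5 * spec.g * t * t,
        z=spec.z_init + vz * t,
        vx=vx,
        vy=vy0 - spec.g * t,
        vz=vz,
    )


def track_arrays(spec: TrajectorySpec, t: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised ball kinematics over an array of times (no range check)."""
    t = np.asarray(t, dtype=float)
    vx, vy0, vz = launch_velocity(spec)
    return {
        "t": t,
        "x": vx * t,
        "y": vy0 * t - 0.5 * spec.g * t * t,
        "z": spec.z_init + vz * t,
        "vx": np.full_like(t, vx),
        "vy": vy0 - spec.g * t,
        "vz": np.full_like(t, vz),
    }


def ground_track_rho(spec: TrajectorySpec, tau):
    """Horizontal eye-ball distance and its tau-derivative at flight
    fraction ``tau`` in [0, 1].

    Returns ``(rho, drho_dtau)`` in metres; ``tau`` may be a scalar or an
    array.  rho is side-independent since it depends on x only through x^2.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0) or np.any(tau_arr > 1):
        raise GeometryError("tau must lie in [0, 1]")
    x = spec.x_end * tau_arr
    z = spec.z_init + (spec.z_end - spec.z_init) * tau_arr
    rho = np.hypot(x, z)
    if np.any(rho < 1e-9):
        raise DegenerateGeometryError("ground track passes through the eye")
    drho = (x * spec.x_end + z * (spec.z_end - spec.z_init)) / rho
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(rho), float(drho)
    return rho, drho


def apex_height(spec: TrajectorySpec) -> float:
    """Maximum height above eye level, g*T^2/8, reached at t = T/2."""
    return spec.g * spec.flight_time**2 / 8.0
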