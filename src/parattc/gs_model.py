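"""The gravity+size (GS) time-to-contact predictor and its error profile.

The GS model estimates the remaining time before a ball in parabolic
flight returns to eye level by combining two context priors — the
gravitational acceleration ``g`` and the physical ball size ``s = 2r`` —
with three monocular optic variables: angular size ``theta``, elevation
angle ``gamma`` and its rate of change ``gamma_dot``:

    TTC_GS = (2 / g) * (s / theta) * (gamma_dot / cos(gamma))

``s/theta`` converts retinal size to an eye-ball distance estimate;
dividing by ``cos(gamma)`` turns it into horizontal distance; ``2/g``
normalises the elevation rate into seconds.  The estimator is exact
throughout the flight for head-on trajectories (landing point at the
eye).  For laterally offset trajectories it is exact at launch,
overestimates early in the flight, crosses zero error at one privileged
time point, and underestimates thereafter.

This module evaluates the predictor through the full optic projection,
locates the privileged zero-error time by bracketed root finding, and
quantifies Weber-fraction discriminability of individual cues between
the two flight durations used in the experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import NoPrivilegedTimeError, UndefinedPredictionError, UndefinedRatioError
from .geometry import TrajectorySpec
from .optics import OpticState, optic_arrays, optic_state_at


@dataclass(frozen=True)
class GSPrediction:
    """Model-predicted vs true remaining flight time at one instant.

    ``error = ttc_gs - ttc_true``; positive error means the model
    overestimates the remaining time.
    """

    t: float
    ttc_gs: float
    ttc_true: float

    @property
    def error(self) -> float:
        return self.ttc_gs - self.ttc_true


@dataclass(frozen=True)
class CueComparison:
    """Relative difference of one optic cue between the two flight durations.

    ``rel_diff_pct`` is the proportion of change from the short-duration
    cue value to the long-duration one, in percent; ``discriminable``
    marks differences at or above the Weber-fraction threshold.
    """

    cue: str
    value_short: float
    value_long: float
    rel_diff_pct: float
    discriminable: bool


CUE_NAMES = ("theta", "gamma", "gamma_dot", "gs_output")


def gs_ttc(optic: OpticState, ball_diameter: float, g: float) -> float:
    """GS-model remaining TTC (seconds) from one optic state."""
    if optic.theta <= 0:
        raise UndefinedPredictionError("theta must be positive")
    cg = math.cos(optic.gamma)
    if abs(cg) < 1e-12 or abs(optic.gamma) >= math.pi / 2:
        raise UndefinedPredictionError("prediction undefined at |gamma| = pi/2")
    return (2.0 / g) * (ball_diameter / optic.theta) * (optic.gamma_dot / cg)


def gs_ttc_at(spec: TrajectorySpec, t: float) -> float:
    """GS prediction for ``spec`` at time ``t``, via the full optic projection."""
    return gs_ttc(optic_state_at(spec, t), 2.0 * spec.ball_radius, spec.g)


def _gs_arrays(spec: TrajectorySpec, t: np.ndarray) -> np.ndarray:
    """Vectorised GS prediction over an array of times."""
    arr = optic_arrays(spec, t)
    s = 2.0 * spec.ball_radius
    return (2.0 / spec.g) * (s / arr["theta"]) * (arr["gamma_dot"] / np.cos(arr["gamma"]))


def gs_error_profile(spec: TrajectorySpec, dt: float) -> list[GSPrediction]:
    """Prediction-error profile sampled every ``dt`` seconds.

    The grid runs from t = 0 to t = T - 1 ms: the final millisecond is
    excluded to avoid the small-distance regime, irrelevant to laterally
    offset flights.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = spec.flight_time
    t = np.arange(0.0, T - 1e-3 + dt / 2, dt)
    t = t[t <= T - 1e-3 + 1e-12]
    ttc = _gs_arrays(spec, t)
    return [
        GSPrediction(t=float(ti), ttc_gs=float(p), ttc_true=float(T - ti))
        for ti, p in zip(t, ttc)
    ]


def error_frame(spec: TrajectorySpec, dt: float):
    """Error profile as a DataFrame (t_s, ttc_gs_s, ttc_true_s, error_s)."""
    import pandas as pd

    preds = gs_error_profile(spec, dt)
    return pd.DataFrame(
        {
            "t_s": [p.t for p in preds],
            "ttc_gs_s": [p.ttc_gs for p in preds],
            "ttc_true_s": [p.ttc_true for p in preds],
            "error_s": [p.error for p in preds],
        }
    )


def privileged_time(spec: TrajectorySpec, grid_dt: float = 1e-3) -> float:
    """First post-launch time at which the GS prediction error crosses zero.

    The error profile touches zero at launch, rises, and for laterally
    offset flights crosses back through zero once.  The profile is
    scanned on a ``grid_dt`` grid over (0.05*T, 0.95*T) and the first
    positive-to-negative sign change is refined by Brent's method to
    better than 1e-6 s.

    Raises
    ------
    NoPrivilegedTimeError
        If no sign change exists in the scanned window (e.g. head-on
        flights, for which the model is exact throughout).
    """
    T = spec.flight_time
    t = np.arange(0.05 * T, 0.95 * T, grid_dt)
    err = _gs_arrays(spec, t) - (T - t)
    sign = np.sign(err)
    crossings = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if len(crossings) == 0:
        raise NoPrivilegedTimeError(
            "prediction error has no positive-to-negative crossing in (0.05T, 0.95T)"
        )
    i = crossings[0]

    def f(ti: float) -> float:
        return float(_gs_arrays(spec, np.array([ti]))[0]) - (T - ti)

    return float(brentq(f, t[i], t[i + 1], xtol=1e-9))


def privileged_fraction(spec: TrajectorySpec) -> float:
    """Privileged time as a fraction of total flight time."""
    return privileged_time(spec) / spec.flight_time


def cue_discriminability(
    spec_short: TrajectorySpec,
    spec_long: TrajectorySpec,
    t_last_visible: tuple[float, float],
    weber: float = 0.05,
) -> list[CueComparison]:
    """Weber-fraction discriminability of optic cues between two flight
    durations.

    For each cue (theta, gamma, gamma_dot, and the composite GS-model
    output) evaluated at the last visible frame of each flight, the
    proportion of change from the short-duration value is
    ``|c_long - c_short| / |c_short| * 100`` percent; the cue is
    discriminable when the change reaches the Weber threshold
    (default 5%).
    """
    t_short, t_long = t_last_visible
    o_short = optic_state_at(spec_short, t_short)
    o_long = optic_state_at(spec_long, t_long)
    values = {
        "theta": (o_short.theta, o_long.theta),
        "gamma": (o_short.gamma, o_long.gamma),
        "gamma_dot": (o_short.gamma_dot, o_long.gamma_dot),
        "gs_output": (
            gs_ttc(o_short, 2 * spec_short.ball_radius, spec_short.g),
            gs_ttc(o_long, 2 * spec_long.ball_radius, spec_long.g),
        ),
    }
    out = []
    for cue, (c_s, c_l) in values.items():
        if abs(c_s) < 1e-12:
            raise UndefinedRatioError(f"cue {cue!r} is zero for the reference flight")
        pct = abs(c_l - c_s) / abs(c_s) * 100.0
        out.append(
            CueComparison(
                cue=cue,
                value_short=c_s,
                value_long=c_l,
                rel_diff_pct=pct,
                discriminable=pct >= weber * 100.0,
            )
        )
    return out
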