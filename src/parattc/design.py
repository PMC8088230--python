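"""Inverse trajectory design: construct parabolic flights whose GS-model
prediction error is zero at a prescribed fraction of flight time.

With flight fraction tau = t/T and ground-track distance rho(tau), the
GS prediction (to the small-angle size approximation) reduces to

    TTC_GS(tau) = T * (phi'(tau) - phi(tau) * rho'(tau)/rho(tau)),
    phi(tau) = tau - tau**2,

so zero error at tau* is equivalent to the duration-free condition

    rho'(tau*) / rho(tau*) = -1 / (1 - tau*).

The condition depends only on the ground-track endpoints, which is why
the same endpoint triple yields the same privileged fraction for any
flight duration.  The solver fixes two of {z_init, x_end, z_end}, frees
the third, and brackets the root of this condition; the returned
trajectory is always re-verified through the full optic projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import DesignInfeasibleError, ValidationError
from .geometry import SOCCER_BALL_RADIUS, STANDARD_GRAVITY, TrajectorySpec
from .gs_model import privileged_time

_FREE_PARAMS = ("z_init", "x_end", "z_end")

# Endpoint triples of the published experimental set, ordered by design
# fraction 0.3 ... 0.7 (metres).
PAPER_Z_INIT = (23.49, 24.23, 25.16, 26.24, 27.47)
PAPER_X_END = (15.09, 12.53, 10.06, 7.71, 5.53)
PAPER_Z_END = (-4.53, -5.01, -5.03, -4.63, -3.87)
PAPER_FRACTIONS = (0.3, 0.4, 0.5, 0.6, 0.7)
PAPER_FLIGHT_TIMES = (3.0, 3.5)


@dataclass(frozen=True)
class DesignProblem:
    """Specification of one inverse-design problem.

    Exactly one of {z_init, x_end, z_end} is freed (``free``); the other
    two are supplied in ``fixed``.  The root of the zero-error condition
    is searched for over ``search_interval`` (metres).
    """

    target_fraction: float
    flight_time: float
    fixed: dict[str, float]
    free: str = "z_init"
    search_interval: tuple[float, float] = (10.0, 40.0)
    g: float = STANDARD_GRAVITY
    ball_radius: float = SOCCER_BALL_RADIUS
    side: str = "right"

    def __post_init__(self) -> None:
        if not (0 < self.target_fraction < 1):
            raise ValidationError("target_fraction must lie in (0, 1)")
        if self.free not in _FREE_PARAMS:
            raise ValidationError(f"free parameter must be one of {_FREE_PARAMS}")
        expected = set(_FREE_PARAMS) - {self.free}
        if set(self.fixed) != expected:
            raise ValidationError(
                f"fixed must supply exactly {sorted(expected)}, got {sorted(self.fixed)}"
            )
        lo, hi = self.search_interval
        if not lo < hi:
            raise ValidationError("search_interval must be increasing")


def _zero_error_residual(z_init: float, x_end: float, z_end: float, tau: float) -> float:
    """rho'(tau)/rho(tau) + 1/(1-tau); zero iff the GS error is zero at tau."""
    x = x_end * tau
    z = z_init + (z_end - z_init) * tau
    rho2 = x * x + z * z
    if rho2 < 1e-18:
        raise DesignInfeasibleError("ground track passes through the eye")
    drho_rho = (x * x_end + z * (z_end - z_init)) / rho2
    return drho_rho + 1.0 / (1.0 - tau)


def design_trajectory(problem: DesignProblem, n_scan: int = 400) -> TrajectorySpec:
    """Solve for the free endpoint parameter so the GS error is zero at
    ``target_fraction`` of the flight.

    The zero-error condition is scanned on ``n_scan`` points across the
    search interval; each bracketing sign change is refined by Brent's
    method to 1e-10 m.  If several roots exist the smallest is returned
    and a multiplicity warning issued.  The returned spec is verified
    through the full optic-projection pipeline.

    Raises
    ------
    DesignInfeasibleError
        If the condition never changes sign over the interval (e.g. a
        head-on geometry, for which the model is exact throughout and
        the error never crosses zero).
    """
    tau = problem.target_fraction

    def residual(p: float) -> float:
        params = dict(problem.fixed)
        params[problem.free] = p
        return _zero_error_residual(
            params["z_init"], params["x_end"], params["z_end"], tau
        )

    lo, hi = problem.search_interval
    step = (hi - lo) / n_scan
    roots: list[float] = []
    prev_p, prev_r = lo, residual(lo)
    for i in range(1, n_scan + 1):
        p = lo + i * step
        r = residual(p)
        if prev_r == 0.0:
            roots.append(prev_p)
        elif prev_r * r < 0:
            roots.append(float(brentq(residual, prev_p, p, xtol=1e-10)))
        prev_p, prev_r = p, r
    if not roots:
        raise DesignInfeasibleError(
            f"zero-error condition has no root for {problem.free} in "
            f"[{lo}, {hi}] at fraction {tau}"
        )
    if len(roots) > 1:
        warnings.warn(
            f"multiple roots {roots} for free parameter {problem.free}; "
            "returning the smallest",
            stacklevel=2,
        )
    params = dict(problem.fixed)
    params[problem.free] = roots[0]
    spec = TrajectorySpec(
        z_init=params["z_init"],
        x_end=params["x_end"],
        z_end=params["z_end"],
        flight_time=problem.flight_time,
        g=problem.g,
        ball_radius=problem.ball_radius,
        side=problem.side,
        gs_rel=tau,
    )
    achieved = privileged_time(spec) / spec.flight_time
    if abs(achieved - tau) >= 1e-4:
        raise DesignInfeasibleError(
            f"verification failed: achieved fraction {achieved:.6f} != {tau}"
        )
    return spec


def paper_trajectory_set(include_sides: bool = False) -> list[TrajectorySpec]:
    """The published experimental trajectory set.

    Five endpoint triples, each designed for zero GS error at 30-70% of
    flight time, crossed with the two flight durations (3 and 3.5 s):
    10 specs, or 20 labelled left/right variants with
    ``include_sides=True``.  ``traj_id`` encodes the design fraction
    (``gs30`` ... ``gs70``); duration and side are carried in their own
    fields.
    """
    specs = []
    for T in PAPER_FLIGHT_TIMES:
        for z_init, x_end, z_end, frac in zip(
            PAPER_Z_INIT, PAPER_X_END, PAPER_Z_END, PAPER_FRACTIONS
        ):
            spec = TrajectorySpec(
                z_init=z_init,
                x_end=x_end,
                z_end=z_end,
                flight_time=T,
                gs_rel=frac,
                side="right",
                traj_id=f"gs{int(round(frac * 100))}",
            )
            if include_sides:
                specs.extend([spec.mirrored(), spec])
            else:
                specs.append(spec)
    return specs


def verify_trajectory_set(specs: list[TrajectorySpec], tol: float = 0.05):
    """Privileged-time verification table for a trajectory set.

    Returns a DataFrame with one row per spec: labelled fraction, the
    privileged time recovered through the full optic pipeline, the
    nominal time ``gs_rel * T``, and whether they agree within ``tol``
    seconds.
    """
    import pandas as pd

    rows = []
    for spec in specs:
        t_star = privileged_time(spec)
        nominal = (spec.gs_rel or float("nan")) * spec.flight_time
        rows.append(
            {
                "traj_id": spec.traj_id,
                "side": spec.side,
                "flight_time_s": spec.flight_time,
                "gs_rel": spec.gs_rel,
                "privileged_time_s": t_star,
                "nominal_time_s": nominal,
                "abs_dev_s": abs(t_star - nominal),
                "ok": abs(t_star - nominal) < tol,
            }
        )
    return pd.DataFrame(rows)
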