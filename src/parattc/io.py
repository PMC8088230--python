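"""Canonical CSV I/O.

CSV is the package's single interchange format.  Angles are stored in
degrees and times in seconds at microsecond precision; booleans as 0/1.
Two schemas exist: trajectory sets and trial tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError
from .geometry import TrajectorySpec

TRIAL_COLUMNS = [
    "participant",
    "block",
    "trial",
    "traj_id",
    "gs_rel",
    "side",
    "flight_time",
    "t_visible",
    "beta_gaze",
    "gamma_dot_gaze",
    "beta_ball",
    "gamma_ball",
    "response_time",
    "hit",
    "correct_controller",
]

_TRIAL_FLOATS = [
    "gs_rel",
    "flight_time",
    "t_visible",
    "beta_gaze",
    "gamma_dot_gaze",
    "beta_ball",
    "gamma_ball",
    "response_time",
]
_TRIAL_BOOLS = ["hit", "correct_controller"]

TRAJECTORY_COLUMNS = [
    "traj_id",
    "gs_rel",
    "z_init_m",
    "x_end_m",
    "z_end_m",
    "flight_time_s",
    "g_ms2",
    "ball_radius_m",
    "side",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table; booleans as 0/1, floats at 1e-6 precision."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {', '.join(missing)}")
    out = trials[TRIAL_COLUMNS].copy()
    for col in _TRIAL_BOOLS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table, validating the schema.

    Raises :class:`FormatError` naming the first missing column, or on
    truncated rows (nulls in any required field).
    """
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trial table missing column: {col}")
    df = df[TRIAL_COLUMNS]
    if len(df) and df.isnull().any().any():
        bad = df.columns[df.isnull().any()].tolist()
        raise FormatError(f"trial table contains null/truncated values in: {bad}")
    for col in _TRIAL_FLOATS:
        df[col] = df[col].astype(float)
    for col in _TRIAL_BOOLS:
        df[col] = df[col].astype(int).astype(bool)
    df["block"] = df["block"].astype(int)
    df["trial"] = df["trial"].astype(int)
    return df


def write_trajectories(specs: list[TrajectorySpec], path: str | Path) -> None:
    """Serialise a trajectory set to CSV."""
    rows = [
        {
            "traj_id": s.traj_id or "",
            "gs_rel": s.gs_rel if s.gs_rel is not None else "",
            "z_init_m": s.z_init,
            "x_end_m": s.x_end,
            "z_end_m": s.z_end,
            "flight_time_s": s.flight_time,
            "g_ms2": s.g,
            "ball_radius_m": s.ball_radius,
            "side": s.side,
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[TrajectorySpec]:
    """Read a trajectory set from CSV."""
    df = pd.read_csv(path)
    for col in TRAJECTORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trajectory table missing column: {col}")
    specs = []
    for _, row in df.iterrows():
        gs_rel = row["gs_rel"]
        specs.append(
            TrajectorySpec(
                z_init=float(row["z_init_m"]),
                x_end=float(row["x_end_m"]),
                z_end=float(row["z_end_m"]),
                flight_time=float(row["flight_time_s"]),
                g=float(row["g_ms2"]),
                ball_radius=float(row["ball_radius_m"]),
                side=str(row["side"]),
                gs_rel=None if pd.isna(gs_rel) else float(gs_rel),
                traj_id=None if pd.isna(row["traj_id"]) else str(row["traj_id"]),
            )
        )
    return specs


def spec_lookup(specs: list[TrajectorySpec]) -> dict[tuple, TrajectorySpec]:
    """Index a trajectory set by (traj_id, flight_time, side)."""
    return {(s.traj_id, s.flight_time, s.side): s for s in specs}
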