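"""Synthetic-observer behavioral generator.

Produces trial-level data with the statistical structure the behavioral
pipeline assumes, emulating the interception-timing experiment: on each
trial a ball flies a designed parabolic trajectory for 3 s (or, on one
trial in six, 3.5 s); the observer sees the first 300 ms, looks away,
chooses when to look back (opening a 400-ms midflight visibility
window), and finally presses a button at the moment they judge the ball
returns to eye level.  A response within +/-50 ms of the true flight
time counts as a hit.

The generative model per trial:

* preferred viewing time ``t_visible ~ Normal(base + slope*gs_rel, sd)``
  clamped to [0.5, T - 0.7] s — participants belong to an *early*
  (mean reappearance < 1.5 s) or *late* viewer class;
* gaze at reappearance linearly coupled to the ball's angular position
  with participant-specific gain, intercept and noise;
* the prediction is consumed at ``t_pred = t_visible + 0.2`` s (the
  midpoint of the 400-ms visibility window);
* the response is a convex pull of a mode-dependent target toward the
  frequent 3-s duration (central-tendency weight ``w``) plus Gaussian
  noise whose SD grows linearly with the time left between prediction
  and response (prediction decay):

      response = (1-w)*target + w*3.0 + intercept + Normal(0, sd0 + k*(T - t_pred))

  with target = t_pred + TTC_GS(t_pred) (mode ``gs``), the true flight
  time (mode ``true_ttc``), or a fixed constant, optionally per
  duration (mode ``constant_map``).

In mode ``gs``, the model output is only a usable estimate while it is
valid: past the privileged time the GS prediction collapses toward and
below zero, and no observer reports a contact in the past.  When the
prediction falls below ``GS_VALID_MIN_S`` the synthetic observer falls
back on the frequent experienced duration (3 s) as its target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .design import paper_trajectory_set
from .geometry import TrajectorySpec, ball_state
from .gs_model import gs_ttc_at
from .optics import project_optics

RESPONSE_MODES = ("gs", "true_ttc", "constant_map")
VIEWER_CLASSES = ("early", "late")

HIT_WINDOW_S = 0.05  # +/- window around the true flight time
PREDICTION_LAG_S = 0.2  # midpoint of the 400 ms visibility window
TVIS_MIN_S = 0.5  # 300 ms initial visibility + look-down latency
TVIS_MARGIN_S = 0.7  # 400 ms window ending 300 ms before eye-level return
FREQUENT_DURATION_S = 3.0
GS_VALID_MIN_S = 0.2  # below this the GS output is treated as invalid


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic participant."""

    participant_id: str
    viewer_class: str  # "early" or "late"
    tvis_base: float  # s: mean preferred viewing time at gs_rel = 0
    tvis_gsrel_slope: float  # s per unit design fraction
    tvis_sd: float  # s
    beta_gain: float  # deg gaze per deg ball azimuth
    beta_intercept: float  # deg
    beta_noise_sd: float  # deg
    gamma_gain: float  # (deg/s gaze rate) per deg ball elevation
    gamma_intercept: float  # deg/s
    gamma_noise_sd: float  # deg/s
    response_mode: str
    response_center: float | dict  # constant_map target (scalar or {T: value})
    response_intercept: float  # s: participant-level response offset
    response_sd0: float  # s: response SD at zero prediction span
    decay_rate: float  # s of SD per s between prediction and contact
    central_tendency_w: float  # pull toward the frequent 3-s duration

    def __post_init__(self) -> None:
        if self.viewer_class not in VIEWER_CLASSES:
            raise ConfigError(f"viewer_class must be in {VIEWER_CLASSES}")
        if self.response_mode not in RESPONSE_MODES:
            raise ConfigError(f"response_mode must be in {RESPONSE_MODES}")
        for name in ("tvis_sd", "beta_noise_sd", "gamma_noise_sd", "response_sd0"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.central_tendency_w <= 1.0):
            raise ConfigError("central_tendency_w must lie in [0, 1]")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial (angles in degrees, times in seconds)."""

    participant: str
    block: int
    trial: int
    traj_id: str
    gs_rel: float
    side: str
    flight_time: float
    t_visible: float
    beta_gaze: float
    gamma_dot_gaze: float
    beta_ball: float
    gamma_ball: float
    response_time: float
    hit: bool
    correct_controller: bool


@dataclass(frozen=True)
class ObserverConfig:
    """Hyperparameters of the synthetic cohort and session design.

    Defaults reproduce the experiment's conditions: 12 participants
    (7 early / 5 late viewers), 6 blocks of 120 trials, 5 trajectory
    geometries presented 24 times per block (20 test trials at 3 s and
    4 control trials at 3.5 s, a 5:1 ratio), sides balanced.
    """

    n_participants: int = 12
    n_early: int = 7
    n_blocks: int = 6
    trials_main: int = 20  # per trajectory per block at T = 3 s
    trials_control: int = 4  # per trajectory per block at T = 3.5 s
    # viewing-window policy hyperpriors
    early_tvis_mean: float = 1.0  # s
    late_tvis_mean: float = 2.0  # s
    tvis_base_sd: float = 0.15  # s, between participants
    tvis_gsrel_slope_mean: float = 0.118  # s per unit gs_rel
    tvis_gsrel_slope_sd: float = 0.02
    tvis_sd: float = 0.15  # s, within participant
    # gaze coupling hyperpriors (degrees)
    beta_gain_mean: float = 0.95
    beta_gain_sd: float = 0.05
    beta_intercept_sd: float = 1.0
    beta_noise_sd: float = 2.0
    gamma_gain_mean: float = 0.5
    gamma_gain_sd: float = 0.05
    gamma_intercept_sd: float = 1.0
    gamma_noise_sd: float = 3.0
    # response model
    response_mode: str = "gs"
    response_center: float | dict = FREQUENT_DURATION_S
    response_intercept_sd: float = 0.03  # s, between participants
    response_sd0: float = 0.08  # s
    decay_rate: float = 0.04  # s SD per s of prediction span
    central_tendency_w: float = 0.1
    p_correct_controller: float = 0.98

    def __post_init__(self) -> None:
        if self.n_participants < 0 or not (0 <= self.n_early <= self.n_participants):
            raise ConfigError(
                f"invalid class proportions: {self.n_early} early of "
                f"{self.n_participants} participants"
            )
        if self.response_mode not in RESPONSE_MODES:
            raise ConfigError(f"response_mode must be in {RESPONSE_MODES}")
        if not (0 <= self.p_correct_controller <= 1):
            raise ConfigError("p_correct_controller must lie in [0, 1]")


def sample_participants(
    n: int, config: ObserverConfig | None = None, seed: int | None = 0
) -> list[ObserverParams]:
    """Draw ``n`` participants from the cohort hyperpriors.

    The first ``n_early`` (scaled to ``n``) are early viewers, the rest
    late, matching labelling by mean preferred viewing time.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    config = config or ObserverConfig()
    if config.n_participants and n == config.n_participants:
        n_early = config.n_early
    else:
        n_early = min(n, int(round(n * config.n_early / max(config.n_participants, 1))))
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        early = i < n_early
        base_mean = config.early_tvis_mean if early else config.late_tvis_mean
        out.append(
            ObserverParams(
                participant_id=f"s_{i + 1:02d}",
                viewer_class="early" if early else "late",
                tvis_base=max(0.1, rng.normal(base_mean, config.tvis_base_sd)),
                tvis_gsrel_slope=rng.normal(
                    config.tvis_gsrel_slope_mean, config.tvis_gsrel_slope_sd
                ),
                tvis_sd=config.tvis_sd,
                beta_gain=rng.normal(config.beta_gain_mean, config.beta_gain_sd),
                beta_intercept=rng.normal(0.0, config.beta_intercept_sd),
                beta_noise_sd=config.beta_noise_sd,
                gamma_gain=rng.normal(config.gamma_gain_mean, config.gamma_gain_sd),
                gamma_intercept=rng.normal(0.0, config.gamma_intercept_sd),
                gamma_noise_sd=config.gamma_noise_sd,
                response_mode=config.response_mode,
                response_center=config.response_center,
                response_intercept=rng.normal(0.0, config.response_intercept_sd),
                response_sd0=config.response_sd0,
                decay_rate=config.decay_rate,
                central_tendency_w=config.central_tendency_w,
            )
        )
    return out


def _response_target(
    params: ObserverParams, spec: TrajectorySpec, t_pred: float
) -> float:
    if params.response_mode == "gs":
        ttc = gs_ttc_at(spec, t_pred)
        if not math.isfinite(ttc) or ttc < GS_VALID_MIN_S:
            return FREQUENT_DURATION_S  # invalid model output: fall back
        return t_pred + ttc
    if params.response_mode == "true_ttc":
        return spec.flight_time
    center = params.response_center
    if isinstance(center, dict):
        # per-duration constants; keys may arrive as str from config files
        for key, val in center.items():
            if math.isclose(float(key), spec.flight_time):
                return float(val)
        raise ConfigError(
            f"constant_map has no entry for flight time {spec.flight_time}"
        )
    return float(center)


def simulate_trial(
    params: ObserverParams,
    spec: TrajectorySpec,
    rng: np.random.Generator,
    block: int = 1,
    trial: int = 1,
    p_correct_controller: float = 0.98,
) -> TrialRecord:
    """Simulate one trial of the timing task."""
    T = spec.flight_time
    mu = params.tvis_base + params.tvis_gsrel_slope * (spec.gs_rel or 0.0)
    t_vis = float(np.clip(rng.normal(mu, params.tvis_sd), TVIS_MIN_S, T - TVIS_MARGIN_S))
    optic = project_optics(ball_state(spec, t_vis), spec.ball_radius)
    beta_ball = math.degrees(optic.beta)
    gamma_ball = math.degrees(optic.gamma)
    beta_gaze = (
        params.beta_gain * beta_ball
        + params.beta_intercept
        + rng.normal(0.0, params.beta_noise_sd)
    )
    gamma_dot_gaze = (
        params.gamma_gain * gamma_ball
        + params.gamma_intercept
        + rng.normal(0.0, params.gamma_noise_sd)
    )
    t_pred = t_vis + PREDICTION_LAG_S
    target = _response_target(params, spec, t_pred)
    w = params.central_tendency_w
    sd = params.response_sd0 + params.decay_rate * max(T - t_pred, 0.0)
    response = (
        (1.0 - w) * target
        + w * FREQUENT_DURATION_S
        + params.response_intercept
        + rng.normal(0.0, sd)
    )
    return TrialRecord(
        participant=params.participant_id,
        block=block,
        trial=trial,
        traj_id=spec.traj_id or "traj",
        gs_rel=spec.gs_rel if spec.gs_rel is not None else float("nan"),
        side=spec.side,
        flight_time=T,
        t_visible=t_vis,
        beta_gaze=beta_gaze,
        gamma_dot_gaze=gamma_dot_gaze,
        beta_ball=beta_ball,
        gamma_ball=gamma_ball,
        response_time=response,
        hit=abs(response - T) <= HIT_WINDOW_S,
        correct_controller=bool(rng.random() < p_correct_controller),
    )


def _block_schedule(
    specs: list[TrajectorySpec], config: ObserverConfig, rng: np.random.Generator
) -> list[TrajectorySpec]:
    """Trial order of one block: per geometry, main and control trials
    with sides balanced, shuffled together."""
    by_key: dict[tuple, dict[str, TrajectorySpec]] = {}
    for s in specs:
        by_key.setdefault((s.traj_id, s.flight_time), {})[s.side] = s
    geometries = sorted({tid for tid, _ in by_key})
    durations = sorted({T for _, T in by_key})
    if len(durations) != 2:
        raise ConfigError("trajectory set must contain exactly two flight durations")
    t_main, t_ctrl = durations[0], durations[1]
    block: list[TrajectorySpec] = []
    for tid in geometries:
        for T, n_trials in ((t_main, config.trials_main), (t_ctrl, config.trials_control)):
            sides = by_key[(tid, T)]
            for j in range(n_trials):
                side = "left" if j % 2 == 0 else "right"
                block.append(sides.get(side) or next(iter(sides.values())))
    perm = rng.permutation(len(block))
    return [block[i] for i in perm]


def generate_dataset(
    config: ObserverConfig | None = None,
    seed: int | None = 0,
    specs: list[TrajectorySpec] | None = None,
    participants: list[ObserverParams] | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic session table.

    Default configuration: 12 participants x 6 blocks x 120 trials =
    8640 rows, with a 5:1 ratio of 3-s to 3.5-s flights.  A single
    seeded generator drives participant sampling and then trial draws
    in a fixed iteration order (participant-major, then block, then
    trial), so row-level reproducibility survives any later filtering.
    """
    config = config or ObserverConfig()
    if specs is None:
        specs = paper_trajectory_set(include_sides=True)
    if participants is None:
        participants = (
            sample_participants(config.n_participants, config, seed)
            if config.n_participants > 0
            else []
        )
    rng = np.random.default_rng(None if seed is None else [seed, 1])
    rows = []
    for params in participants:
        for block in range(1, config.n_blocks + 1):
            schedule = _block_schedule(specs, config, rng)
            for idx, spec in enumerate(schedule, start=1):
                rows.append(
                    asdict(
                        simulate_trial(
                            params,
                            spec,
                            rng,
                            block=block,
                            trial=idx,
                            p_correct_controller=config.p_correct_controller,
                        )
                    )
                )
    from .io import TRIAL_COLUMNS

    if not rows:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
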