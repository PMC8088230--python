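"""Behavioral analysis pipeline for trial tables.

Implements, end to end, the statistical treatment applied to the timing
experiment: grouped IQR outlier filtering of response times; linear
mixed models with a participant random intercept, fit by full maximum
likelihood so that likelihood-ratio tests on fixed effects are valid;
the gaze-prediction, viewing-time and response-time analyses; Deming
(errors-in-variables) regression of responses against GS-model
predictions; a proximity-to-privileged-time median split; and
per-participant performance metrics.

All analyses operate on the canonical trial table (see
:mod:`parattc.io`) and are invariant to row order and to left/right
mirroring of trajectories.  Flight duration enters models as a 0/1
indicator (0 = 3 s, 1 = 3.5 s) so its coefficient is the mean
response-time difference in seconds; the design fraction ``gs_rel``
enters as a numeric fraction (0.3-0.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .geometry import TrajectorySpec
from .gs_model import gs_ttc_at, privileged_time
from .observer import PREDICTION_LAG_S

__all__ = [
    "MixedModelResult",
    "LRTResult",
    "DemingFit",
    "filter_outliers",
    "fit_random_intercept_lmm",
    "likelihood_ratio_test",
    "gaze_prediction_analysis",
    "viewing_time_analysis",
    "response_time_analysis",
    "deming_regression",
    "correspondence_analysis",
    "proximity_split_analysis",
    "performance_metrics",
]


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class MixedModelResult:
    """A fitted random-intercept linear mixed model (full ML)."""

    formula: str
    fixed: pd.DataFrame  # index: term; columns: estimate, se, t, ci_low, ci_high
    re_var: float  # participant random-intercept variance
    resid_var: float
    llf: float
    bic: float
    nobs: int
    n_fixed: int
    singular: bool

    def coef(self, term: str) -> float:
        return float(self.fixed.loc[term, "estimate"])


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between nested mixed models."""

    chi_square: float
    df: int
    p_value: float
    bic_null: float
    bic_test: float


@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables linear fit."""

    slope: float
    intercept: float
    variance_ratio: float
    n: int
    participant: str | None = None
    trajectory: str | None = None


# --------------------------------------------------------------------------
# data preparation


def prepare_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add derived model columns: the 0/1 duration indicator ``ttc01``
    and the prediction time ``t_pred`` (midpoint of the visibility
    window, 200 ms after reappearance)."""
    out = trials.copy()
    t_main = out["flight_time"].min()
    out["ttc01"] = (out["flight_time"] > t_main + 1e-9).astype(float)
    out["t_pred"] = out["t_visible"] + PREDICTION_LAG_S
    return out


def filter_outliers(
    trials: pd.DataFrame, min_group_size: int = 4
) -> tuple[pd.DataFrame, dict]:
    """Grouped 1.5-IQR filter on response time.

    Within each (participant, trajectory, flight duration) group, rows
    with response time outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are
    dropped.  Groups smaller than ``min_group_size`` are kept untouched
    with a warning.  Returns the kept rows (original order) and a
    removal report.
    """
    keys = ["participant", "traj_id", "flight_time"]
    keep = pd.Series(True, index=trials.index)
    skipped = 0
    for _, idx in trials.groupby(keys, sort=False).groups.items():
        rt = trials.loc[idx, "response_time"]
        if len(rt) < min_group_size:
            skipped += 1
            continue
        q1, q3 = rt.quantile([0.25, 0.75])
        iqr = q3 - q1
        keep.loc[idx] = (rt >= q1 - 1.5 * iqr) & (rt <= q3 + 1.5 * iqr)
    if skipped:
        warnings.warn(
            f"{skipped} group(s) smaller than {min_group_size} skipped by the "
            "outlier filter",
            stacklevel=2,
        )
    n_removed = int((~keep).sum())
    report = {
        "n_total": int(len(trials)),
        "n_removed": n_removed,
        "pct_removed": 100.0 * n_removed / len(trials) if len(trials) else 0.0,
        "n_groups_skipped": skipped,
    }
    return trials[keep], report


# --------------------------------------------------------------------------
# mixed models


def fit_random_intercept_lmm(
    trials: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str = "participant",
) -> MixedModelResult:
    """Fit ``response ~ fixed + (1 | group)`` by full maximum likelihood.

    ``fixed`` is a list of formula terms (e.g. ``["ttc01"]`` or
    ``["ttc01 * gs_rel"]``); an empty list fits the intercept-only null
    model.  BIC is computed from the ML log-likelihood with the fixed
    effects plus the two variance components as parameters.  A
    boundary (zero) random-intercept variance is flagged as singular.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if trials[group].nunique() < 2:
        raise ValidationError("mixed model needs >= 2 participants")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data=trials, groups=trials[group])
        res = model.fit(reml=False)
    fe = res.fe_params
    se = res.bse_fe
    ci = res.conf_int().loc[fe.index]
    table = pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "t": fe / se,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    re_var = float(res.cov_re.iloc[0, 0]) if res.k_re > 0 else 0.0
    re_var = max(re_var, 0.0)
    n = int(res.nobs)
    k = len(fe) + 2  # fixed effects + random-intercept and residual variances
    llf = float(res.llf)
    return MixedModelResult(
        formula=f"{formula} + (1 | {group})",
        fixed=table,
        re_var=re_var,
        resid_var=float(res.scale),
        llf=llf,
        bic=-2.0 * llf + k * np.log(n),
        nobs=n,
        n_fixed=len(fe),
        singular=re_var < 1e-8,
    )


def likelihood_ratio_test(null: MixedModelResult, test: MixedModelResult) -> LRTResult:
    """LRT of nested random-intercept models fit to the same data."""
    if null.nobs != test.nobs:
        raise ValidationError("models were fit to different numbers of rows")
    if null.n_fixed >= test.n_fixed:
        raise ValidationError("null model must have fewer fixed effects")
    if not set(null.fixed.index) <= set(test.fixed.index):
        raise ValidationError("null fixed effects are not nested in the test model")
    chi2 = max(0.0, 2.0 * (test.llf - null.llf))
    df = test.n_fixed - null.n_fixed
    return LRTResult(
        chi_square=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0,
        bic_null=null.bic,
        bic_test=test.bic,
    )


# --------------------------------------------------------------------------
# the experiment's analyses


@dataclass(frozen=True)
class GazeAnalysis:
    beta_test: MixedModelResult
    beta_lrt: LRTResult
    gamma_test: MixedModelResult
    gamma_lrt: LRTResult
    participant_slopes: pd.DataFrame  # per participant: beta_slope, gamma_slope


def gaze_prediction_analysis(trials: pd.DataFrame) -> GazeAnalysis:
    """Could the observers predict the ball's position?

    Horizontal gaze direction at reappearance is regressed on the
    ball's azimuth, and the vertical gaze rate on the ball's elevation,
    each with a participant random intercept, and compared against
    intercept-only null models.  Per-participant ordinary least-squares
    slopes are returned for both relations.
    """
    beta_test = fit_random_intercept_lmm(trials, "beta_gaze", ["beta_ball"])
    beta_null = fit_random_intercept_lmm(trials, "beta_gaze", [])
    gamma_test = fit_random_intercept_lmm(trials, "gamma_dot_gaze", ["gamma_ball"])
    gamma_null = fit_random_intercept_lmm(trials, "gamma_dot_gaze", [])
    slopes = []
    for pid, grp in trials.groupby("participant"):
        b = np.polyfit(grp["beta_ball"], grp["beta_gaze"], 1)[0]
        g = np.polyfit(grp["gamma_ball"], grp["gamma_dot_gaze"], 1)[0]
        slopes.append({"participant": pid, "beta_slope": b, "gamma_slope": g})
    return GazeAnalysis(
        beta_test=beta_test,
        beta_lrt=likelihood_ratio_test(beta_null, beta_test),
        gamma_test=gamma_test,
        gamma_lrt=likelihood_ratio_test(gamma_null, gamma_test),
        participant_slopes=pd.DataFrame(slopes),
    )


@dataclass(frozen=True)
class ViewingTimeAnalysis:
    test: MixedModelResult
    lrt: LRTResult
    summary: pd.DataFrame  # mean t_visible per participant x duration x gs_rel


def viewing_time_analysis(trials: pd.DataFrame) -> ViewingTimeAnalysis:
    """When do participants prefer to look at the ball?

    Preferred viewing time is modelled as duration x design-fraction
    (``t_visible ~ ttc01 * gs_rel + (1 | participant)``; four fixed
    effects including the interaction) against the intercept-only null
    (a 3-df LRT).
    """
    data = prepare_trials(trials)
    test = fit_random_intercept_lmm(data, "t_visible", ["ttc01 * gs_rel"])
    null = fit_random_intercept_lmm(data, "t_visible", [])
    summary = (
        data.groupby(["participant", "flight_time", "gs_rel"], as_index=False)[
            "t_visible"
        ]
        .agg(["mean", "std"])
        .rename(columns={"mean": "t_visible_mean", "std": "t_visible_sd"})
    )
    return ViewingTimeAnalysis(
        test=test, lrt=likelihood_ratio_test(null, test), summary=summary
    )


@dataclass(frozen=True)
class ResponseTimeAnalysis:
    test: MixedModelResult
    lrt: LRTResult


def response_time_analysis(trials: pd.DataFrame) -> ResponseTimeAnalysis:
    """Is response time affected by flight duration?

    ``response_time ~ ttc01 + (1 | participant)`` vs the intercept-only
    null.  With the 0/1 coding, the ``ttc01`` coefficient is the mean
    response-time difference between the 3.5-s and 3-s flights in
    seconds, and the intercept the mean response in the 3-s condition.
    """
    data = prepare_trials(trials)
    test = fit_random_intercept_lmm(data, "response_time", ["ttc01"])
    null = fit_random_intercept_lmm(data, "response_time", [])
    return ResponseTimeAnalysis(test=test, lrt=likelihood_ratio_test(null, test))


# --------------------------------------------------------------------------
# Deming regression and GS correspondence


def deming_regression(
    x,
    y,
    variance_ratio: float = 1.0,
    participant: str | None = None,
    trajectory: str | None = None,
) -> DemingFit:
    """Closed-form errors-in-variables fit of y on x.

    With delta the assumed ratio of error variances, the slope is

        b = [s_yy - d*s_xx + sqrt((s_yy - d*s_xx)^2 + 4*d*s_xy^2)] / (2*s_xy)

    and the intercept ``mean(y) - b*mean(x)``.  delta = 1 gives
    orthogonal regression, symmetric under exchange of x and y
    (swapping inverts the slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("deming_regression needs >= 3 paired points")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx <= 0:
        raise ValidationError("x has zero variance")
    if abs(sxy) < 1e-300:
        raise ValidationError("undefined slope: zero covariance between x and y")
    d = variance_ratio
    b = (syy - d * sxx + np.sqrt((syy - d * sxx) ** 2 + 4 * d * sxy**2)) / (2 * sxy)
    return DemingFit(
        slope=float(b),
        intercept=float(np.mean(y) - b * np.mean(x)),
        variance_ratio=d,
        n=len(x),
        participant=participant,
        trajectory=trajectory,
    )


def _gs_prediction_columns(
    trials: pd.DataFrame, specs: list[TrajectorySpec]
) -> pd.DataFrame:
    """Attach x = TTC_GS(t_pred) and y = response - t_pred per trial."""
    from .io import spec_lookup

    data = prepare_trials(trials)
    lookup = spec_lookup(specs)
    x = np.empty(len(data))
    for i, (tid, T, side, tp) in enumerate(
        zip(data["traj_id"], data["flight_time"], data["side"], data["t_pred"])
    ):
        spec = lookup.get((tid, T, side)) or lookup.get(
            (tid, T, "left" if side == "right" else "right")
        )
        if spec is None:
            raise ValidationError(f"no trajectory spec for ({tid}, {T}, {side})")
        x[i] = gs_ttc_at(spec, float(tp))
    data["gs_prediction"] = x
    data["response_since_pred"] = data["response_time"] - data["t_pred"]
    return data


@dataclass(frozen=True)
class CorrespondenceAnalysis:
    fits: pd.DataFrame  # per participant x trajectory Deming fits
    pooled_slope: float
    pooled_ci: tuple[float, float]
    across_trajectory: MixedModelResult


def correspondence_analysis(
    trials: pd.DataFrame,
    specs: list[TrajectorySpec],
    variance_ratio: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrespondenceAnalysis:
    """Are the responses consistent with the GS-model predictions?

    Per participant and trajectory, a Deming fit of the response time
    since the prediction moment on the GS prediction at that moment.
    The pooled slope is the mean over fits; its 95% CI comes from a
    participant-level nonparametric bootstrap (percentile interval).
    The across-trajectory effect is a random-intercept model of the
    response since prediction on the design fraction.
    """
    data = _gs_prediction_columns(trials, specs)
    fits = []
    for (pid, tid), grp in data.groupby(["participant", "traj_id"]):
        try:
            fit = deming_regression(
                grp["gs_prediction"],
                grp["response_since_pred"],
                variance_ratio,
                participant=pid,
                trajectory=tid,
            )
        except ValidationError:
            continue
        fits.append(
            {
                "participant": pid,
                "traj_id": tid,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "n": fit.n,
            }
        )
    fits_df = pd.DataFrame(fits)
    per_participant = fits_df.groupby("participant")["slope"].mean()
    pooled = float(fits_df["slope"].mean())
    rng = np.random.default_rng(seed)
    pids = per_participant.index.to_numpy()
    boot = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.choice(pids, size=len(pids), replace=True)
        boot[b] = per_participant.loc[sample].mean()
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    across = fit_random_intercept_lmm(data, "response_since_pred", ["gs_rel"])
    return CorrespondenceAnalysis(
        fits=fits_df, pooled_slope=pooled, pooled_ci=ci, across_trajectory=across
    )


@dataclass(frozen=True)
class ProximitySplit:
    mean_error_closer: float
    mean_error_far: float
    t_statistic: float
    df: float
    p_value: float
    n_closer: int
    n_far: int


def proximity_split_analysis(
    trials: pd.DataFrame, specs: list[TrajectorySpec]
) -> ProximitySplit:
    """Does looking near the privileged time reduce temporal error?

    Per participant and trajectory, trials are median-split on the
    distance between the prediction moment and the trajectory's
    privileged time (ties to "closer").  The signed temporal error
    ``response_time - T`` is compared between groups with a Welch t
    test.
    """
    from .io import spec_lookup

    data = prepare_trials(trials)
    lookup = spec_lookup(specs)
    t_star: dict[tuple, float] = {}
    for (tid, T, side), spec in lookup.items():
        key = (tid, T)
        if key not in t_star:
            t_star[key] = privileged_time(spec)
    data["privileged"] = [
        t_star[(tid, T)] for tid, T in zip(data["traj_id"], data["flight_time"])
    ]
    data["distance"] = (data["t_pred"] - data["privileged"]).abs()
    data["signed_error"] = data["response_time"] - data["flight_time"]
    closer_mask = pd.Series(False, index=data.index)
    for _, idx in data.groupby(["participant", "traj_id"]).groups.items():
        med = data.loc[idx, "distance"].median()
        closer_mask.loc[idx] = data.loc[idx, "distance"] <= med
    closer = data.loc[closer_mask, "signed_error"]
    far = data.loc[~closer_mask, "signed_error"]
    welch = stats.ttest_ind(closer, far, equal_var=False)
    return ProximitySplit(
        mean_error_closer=float(closer.mean()),
        mean_error_far=float(far.mean()),
        t_statistic=float(welch.statistic),
        df=float(welch.df),
        p_value=float(welch.pvalue),
        n_closer=int(len(closer)),
        n_far=int(len(far)),
    )


# --------------------------------------------------------------------------
# performance metrics


def performance_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant performance summary.

    Hit probability, response-time SD, mean preferred viewing time and
    the resulting viewer class (early if the mean reappearance time is
    below 1.5 s), and the mean response time since the prediction
    moment — the quantities behind the hit-vs-precision and
    hit-vs-prediction-span summaries.
    """
    data = prepare_trials(trials)
    rows = []
    for pid, grp in data.groupby("participant"):
        mean_tvis = float(grp["t_visible"].mean())
        rows.append(
            {
                "participant": pid,
                "n_trials": len(grp),
                "hit_prob": float(grp["hit"].mean()),
                "response_sd": float(grp["response_time"].std(ddof=1)),
                "mean_t_visible": mean_tvis,
                "viewer_class": "early" if mean_tvis < 1.5 else "late",
                "mean_time_since_prediction": float(
                    (grp["response_time"] - grp["t_pred"]).mean()
                ),
            }
        )
    return pd.DataFrame(rows)


def performance_by_duration(trials: pd.DataFrame) -> pd.DataFrame:
    """Hit probability and response-time summaries per participant and
    flight duration."""
    return (
        trials.groupby(["participant", "flight_time"], as_index=False)
        .agg(
            hit_prob=("hit", "mean"),
            response_mean=("response_time", "mean"),
            response_sd=("response_time", "std"),
            n=("response_time", "size"),
        )
    )
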