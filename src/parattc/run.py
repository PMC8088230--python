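"""End-to-end orchestration: build the trajectory set, simulate a
session, run every analysis, and write a self-describing report bundle."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, write_config
from .design import paper_trajectory_set, verify_trajectory_set
from .errors import PipelineStageError
from .gs_model import cue_discriminability
from .io import read_trajectories, write_trajectories, write_trials
from .observer import generate_dataset
from . import pipeline


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return inner

    return wrap


def _lmm_rows(label: str, res: pipeline.MixedModelResult) -> list[dict]:
    rows = []
    for term, row in res.fixed.iterrows():
        rows.append(
            {
                "model": label,
                "formula": res.formula,
                "term": term,
                "estimate": row["estimate"],
                "se": row["se"],
                "t": row["t"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
                "re_var": res.re_var,
                "llf": res.llf,
                "bic": res.bic,
                "nobs": res.nobs,
                "singular": res.singular,
            }
        )
    return rows


def _lrt_row(label: str, lrt: pipeline.LRTResult) -> dict:
    return {
        "comparison": label,
        "chi_square": lrt.chi_square,
        "df": lrt.df,
        "p_value": lrt.p_value,
        "bic_null": lrt.bic_null,
        "bic_test": lrt.bic_test,
    }


def run_paper_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full study pipeline under ``config``.

    Stages: trajectory set construction and privileged-time
    verification; synthetic dataset generation; outlier filtering; the
    gaze, viewing-time, response-time, correspondence, proximity and
    performance analyses; cue discriminability at the mean last-visible
    frame.  Deterministic under the config seed; every output directory
    records the config, seed and package version.
    """
    seed = config.require_seed()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    paths: dict[str, Path] = {}

    specs = _stage("trajectory_set")(
        lambda: paper_trajectory_set(include_sides=True)
        if config.trajectories == "paper"
        else read_trajectories(config.trajectories)
    )()
    paths["trajectories"] = out / "trajectories.csv"
    write_trajectories(specs, paths["trajectories"])

    verification = _stage("privileged_time_verification")(verify_trajectory_set)(
        [s for s in specs if s.side == "right"]
    )
    paths["privileged_times"] = out / "privileged_times.csv"
    verification.to_csv(paths["privileged_times"], index=False, float_format="%.6f")

    trials = _stage("generate_dataset")(generate_dataset)(
        config.observer, seed=seed, specs=specs
    )
    paths["trials"] = out / "trials.csv"
    write_trials(trials, paths["trials"])

    filtered, removal = _stage("outlier_filter")(pipeline.filter_outliers)(trials)
    paths["filtered"] = out / "filtered.csv"
    write_trials(filtered, paths["filtered"])

    gaze = _stage("gaze_analysis")(pipeline.gaze_prediction_analysis)(filtered)
    viewing = _stage("viewing_time_analysis")(pipeline.viewing_time_analysis)(filtered)
    response = _stage("response_time_analysis")(pipeline.response_time_analysis)(filtered)
    corr = _stage("correspondence_analysis")(pipeline.correspondence_analysis)(
        filtered, specs, seed=seed
    )
    prox = _stage("proximity_split")(pipeline.proximity_split_analysis)(filtered, specs)
    metrics = _stage("performance_metrics")(pipeline.performance_metrics)(filtered)

    # cue differences between durations at the cohort-mean viewing time
    def _cues():
        rows = []
        by_key = {(s.traj_id, s.flight_time): s for s in specs if s.side == "right"}
        t_vis_mean = float(filtered["t_visible"].mean())
        for tid in sorted({s.traj_id for s in specs}):
            s3, s35 = by_key[(tid, 3.0)], by_key[(tid, 3.5)]
            t3 = min(t_vis_mean + 0.4, s3.flight_time - 0.3)
            t35 = min(t_vis_mean + 0.4, s35.flight_time - 0.3)
            for c in cue_discriminability(s3, s35, (t3, t35)):
                rows.append(
                    {
                        "traj_id": tid,
                        "cue": c.cue,
                        "rel_diff_pct": c.rel_diff_pct,
                        "discriminable": c.discriminable,
                    }
                )
        return pd.DataFrame(rows)

    cues = _stage("cue_discriminability")(_cues)()

    lmm_rows = (
        _lmm_rows("gaze_beta", gaze.beta_test)
        + _lmm_rows("gaze_gamma_dot", gaze.gamma_test)
        + _lmm_rows("viewing_time", viewing.test)
        + _lmm_rows("response_time", response.test)
        + _lmm_rows("correspondence_across_traj", corr.across_trajectory)
    )
    lrt_rows = [
        _lrt_row("gaze_beta_vs_null", gaze.beta_lrt),
        _lrt_row("gaze_gamma_dot_vs_null", gaze.gamma_lrt),
        _lrt_row("viewing_time_vs_null", viewing.lrt),
        _lrt_row("response_time_vs_null", response.lrt),
    ]
    paths["lmm_results"] = out / "lmm_results.csv"
    pd.DataFrame(lmm_rows).to_csv(paths["lmm_results"], index=False, float_format="%.6f")
    paths["lrt_results"] = out / "lrt_results.csv"
    pd.DataFrame(lrt_rows).to_csv(paths["lrt_results"], index=False, float_format="%.6f")
    paths["deming_fits"] = out / "deming_fits.csv"
    corr.fits.to_csv(paths["deming_fits"], index=False, float_format="%.6f")
    paths["metrics"] = out / "metrics.csv"
    metrics.to_csv(paths["metrics"], index=False, float_format="%.6f")
    paths["cue_discriminability"] = out / "cue_discriminability.csv"
    cues.to_csv(paths["cue_discriminability"], index=False, float_format="%.6f")

    paths["config"] = out / "config.yaml"
    write_config(config, paths["config"])
    summary = {
        "package_version": __version__,
        "seed": seed,
        "n_trials": int(len(trials)),
        "outlier_removal": removal,
        "pooled_deming_slope": corr.pooled_slope,
        "pooled_deming_ci": list(corr.pooled_ci),
        "proximity_split": dataclasses.asdict(prox),
        "runtime_s": round(time.time() - t0, 2),
    }
    paths["run_log"] = out / "run.json"
    paths["run_log"].write_text(json.dumps(summary, indent=2))
    return paths
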