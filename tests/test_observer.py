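import numpy as np
import pandas as pd
import pytest

from parattc import (
    ObserverConfig,
    TrajectorySpec,
    generate_dataset,
    gs_ttc_at,
    sample_participants,
    simulate_trial,
)
from parattc.errors import ConfigError
from parattc.observer import TVIS_MIN_S, TVIS_MARGIN_S


def noiseless(params, **overrides):
    from dataclasses import replace

    return replace(
        params,
        tvis_sd=0.0,
        beta_noise_sd=0.0,
        gamma_noise_sd=0.0,
        response_sd0=0.0,
        decay_rate=0.0,
        response_intercept=0.0,
        central_tendency_w=0.0,
        **overrides,
    )


class TestSampleParticipants:
    def test_default_class_mix(self):
        cohort = sample_participants(12, ObserverConfig(), seed=3)
        classes = [p.viewer_class for p in cohort]
        assert classes.count("early") == 7
        assert classes.count("late") == 5

    def test_deterministic_under_seed(self):
        a = sample_participants(5, seed=42)
        b = sample_participants(5, seed=42)
        assert a == b

    def test_all_late_config(self):
        config = ObserverConfig(n_participants=12, n_early=0)
        cohort = sample_participants(12, config, seed=0)
        assert all(p.viewer_class == "late" for p in cohort)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigError):
            ObserverConfig(n_participants=4, n_early=9)
        with pytest.raises(ConfigError):
            sample_participants(0)


class TestSimulateTrial:
    def test_true_ttc_noise_free_is_exact_hit(self, spec_gs50):
        params = noiseless(
            sample_participants(1, seed=0)[0], response_mode="true_ttc"
        )
        rec = simulate_trial(params, spec_gs50, np.random.default_rng(0))
        assert rec.response_time == pytest.approx(3.0, abs=1e-12)
        assert rec.hit

    def test_constant_map_ignores_duration(self, spec_gs50):
        """The fixed-criterion null: identical responses for both flights."""
        params = noiseless(
            sample_participants(1, seed=0)[0],
            response_mode="constant_map",
            response_center=3.0,
        )
        r3 = simulate_trial(params, spec_gs50, np.random.default_rng(1))
        r35 = simulate_trial(
            params, spec_gs50.with_flight_time(3.5), np.random.default_rng(1)
        )
        assert r3.response_time == pytest.approx(r35.response_time, abs=1e-12)

    def test_gs_mode_uses_model_prediction(self, spec_gs50):
        """Noise-free gs response equals t_pred + TTC_GS(t_pred); with the
        viewing window at 0.75 s the fraction-domain oracle at
        tau = 0.95/3 gives ~0.95 + 2.22 = 3.17 s."""
        params = noiseless(
            sample_participants(1, seed=0)[0],
            response_mode="gs",
            tvis_base=0.75,
            tvis_gsrel_slope=0.0,
        )
        rec = simulate_trial(params, spec_gs50, np.random.default_rng(0))
        assert rec.t_visible == pytest.approx(0.75, abs=1e-12)
        expected = 0.95 + gs_ttc_at(spec_gs50, 0.95)
        assert rec.response_time == pytest.approx(expected, abs=1e-12)
        # independent fraction-domain value: T*(phi' - phi*rho'/rho) at tau = 0.95/3
        assert rec.response_time == pytest.approx(3.174, abs=0.01)

    def test_viewing_window_clamped(self, spec_gs50):
        params = noiseless(sample_participants(1, seed=0)[0], tvis_base=9.0)
        rec = simulate_trial(params, spec_gs50, np.random.default_rng(0))
        assert rec.t_visible == pytest.approx(3.0 - TVIS_MARGIN_S)
        params = noiseless(params, tvis_base=-5.0)
        rec = simulate_trial(params, spec_gs50, np.random.default_rng(0))
        assert rec.t_visible == pytest.approx(TVIS_MIN_S)

    def test_hit_rule(self, spec_gs50):
        params = noiseless(
            sample_participants(1, seed=0)[0],
            response_mode="constant_map",
            response_center=3.049,
        )
        assert simulate_trial(params, spec_gs50, np.random.default_rng(0)).hit
        params = noiseless(params, response_center=3.051)
        assert not simulate_trial(params, spec_gs50, np.random.default_rng(0)).hit


class TestGenerateDataset:
    def test_default_session_arithmetic(self):
        trials = generate_dataset(ObserverConfig(), seed=5)
        assert len(trials) == 8640  # 12 participants x 6 blocks x 120
        assert (trials["flight_time"] > 3.25).sum() == 1440  # 1 in 6 control
        assert trials.groupby("participant").size().eq(720).all()

    def test_block_composition(self):
        trials = generate_dataset(ObserverConfig(n_participants=2, n_early=1, n_blocks=1), seed=5)
        block = trials[trials["participant"] == "s_01"]
        per_traj = block.groupby(["traj_id", "flight_time"]).size()
        assert set(per_traj[per_traj.index.get_level_values(1) == 3.0]) == {20}
        assert set(per_traj[per_traj.index.get_level_values(1) == 3.5]) == {4}
        sides = block.groupby(["traj_id", "flight_time", "side"]).size()
        assert sides.groupby(level=[0, 1]).nunique().eq(1).all()  # balanced

    def test_reproducible_under_seed(self, small_config):
        a = generate_dataset(small_config, seed=9)
        b = generate_dataset(small_config, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort(self):
        trials = generate_dataset(ObserverConfig(n_participants=0, n_early=0), seed=1)
        assert len(trials) == 0
        assert "response_time" in trials.columns

    def test_gs_mode_regression_slope_near_one(self):
        """With early viewing (valid model region) and small noise,
        regressing response - t_pred on TTC_GS(t_pred) per trajectory
        gives slope ~ 1 — the generative structure behind the
        response/prediction correspondence."""
        config = ObserverConfig(
            n_participants=4, n_early=4, n_blocks=2,
            early_tvis_mean=0.9, tvis_base_sd=0.05, tvis_sd=0.1,
            response_sd0=0.02, decay_rate=0.0, central_tendency_w=0.0,
            response_intercept_sd=0.0,
        )
        trials = generate_dataset(config, seed=21)
        from parattc import paper_trajectory_set
        from parattc.pipeline import _gs_prediction_columns

        data = _gs_prediction_columns(trials, paper_trajectory_set(include_sides=True))
        slopes = []
        for _, grp in data.groupby(["traj_id", "flight_time"]):
            slopes.append(np.polyfit(grp["gs_prediction"], grp["response_since_pred"], 1)[0])
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)

    def test_gaze_gain_recovery(self):
        """Generated gaze variables reproduce the configured coupling
        gains at the default cohort size."""
        config = ObserverConfig(
            beta_gain_mean=0.8, beta_gain_sd=0.0, gamma_gain_mean=0.6, gamma_gain_sd=0.0,
            beta_intercept_sd=0.0, gamma_intercept_sd=0.0,
        )
        trials = generate_dataset(config, seed=13)
        beta_slope = np.polyfit(trials["beta_ball"], trials["beta_gaze"], 1)[0]
        gamma_slope = np.polyfit(trials["gamma_ball"], trials["gamma_dot_gaze"], 1)[0]
        assert beta_slope == pytest.approx(0.8, abs=0.02)
        assert gamma_slope == pytest.approx(0.6, abs=0.02)
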