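import math

import numpy as np
import pytest
from scipy.optimize import brentq

from parattc import (
    TrajectorySpec,
    cue_discriminability,
    gs_error_profile,
    gs_ttc_at,
    privileged_fraction,
    privileged_time,
)
from parattc.errors import NoPrivilegedTimeError, UndefinedRatioError


def oracle_ttc(spec, t):
    """Independent flight-fraction-domain prediction:
    TTC = T*(phi'(tau) - phi(tau)*rho'(tau)/rho(tau)), phi = tau - tau^2,
    with rho computed directly from the endpoint parameters."""
    T = spec.flight_time
    tau = t / T
    x = spec.x_end * tau
    z = spec.z_init + (spec.z_end - spec.z_init) * tau
    rho = math.hypot(x, z)
    drho = (x * spec.x_end + z * (spec.z_end - spec.z_init)) / rho
    phi = tau - tau * tau
    dphi = 1.0 - 2.0 * tau
    return T * (dphi - phi * drho / rho)


def oracle_crossing_condition(spec, tau):
    """rho'(tau)/rho(tau) + 1/(1 - tau): zero at the privileged fraction."""
    x = spec.x_end * tau
    z = spec.z_init + (spec.z_end - spec.z_init) * tau
    rho2 = x * x + z * z
    return (x * spec.x_end + z * (spec.z_end - spec.z_init)) / rho2 + 1 / (1 - tau)


class TestGsTtc:
    def test_launch_prediction_equals_flight_duration(self, paper_set):
        for spec in paper_set:
            assert gs_ttc_at(spec, 1e-4) == pytest.approx(spec.flight_time, abs=1e-3)

    def test_head_on_exact_throughout(self, head_on_spec):
        """For a ball landing on the observer the model signals the true
        remaining time during the whole flight (until the ball is near)."""
        T = head_on_spec.flight_time
        for t in np.arange(0.0, T, 0.01):
            d = head_on_spec.z_init * (1 - t / T)  # ground-track distance
            if d <= 1.0:
                break
            assert abs(gs_ttc_at(head_on_spec, float(t)) - (T - t)) < 1e-3

    def test_matches_fraction_domain_oracle(self, spec_gs50):
        for t in (0.3, 0.75, 1.2, 1.5, 2.0, 2.4):
            assert gs_ttc_at(spec_gs50, t) == pytest.approx(
                oracle_ttc(spec_gs50, t), abs=2e-4
            )

    def test_midflight_overestimation_example(self, spec_gs50):
        # oracle value at t = 0.75 s: prediction 2.400 s vs 2.25 s true
        assert gs_ttc_at(spec_gs50, 0.75) == pytest.approx(2.400, abs=2e-3)


class TestErrorProfile:
    def test_zero_error_at_launch_then_positive_then_negative(self, spec_gs50):
        profile = gs_error_profile(spec_gs50, dt=0.01)
        errors = {round(p.t, 3): p.error for p in profile}
        assert abs(errors[0.0]) < 1e-4  # exact up to the (r/d)^2 size term
        assert errors[0.75] == pytest.approx(0.15, abs=0.01)  # overestimation
        assert errors[2.5] < 0  # severe underestimation late in flight

    def test_head_on_errors_negligible(self, head_on_spec):
        profile = gs_error_profile(head_on_spec, dt=0.01)
        assert all(abs(p.error) < 1e-3 for p in profile if p.t <= 2.7)

    def test_sign_convention_is_overestimation_positive(self, spec_gs50):
        p = gs_error_profile(spec_gs50, dt=0.25)[3]  # t = 0.75 s
        assert p.error == p.ttc_gs - p.ttc_true
        assert p.ttc_gs > p.ttc_true


class TestPrivilegedTime:
    def test_printed_set_times(self, paper_set):
        """The designed trajectories have zero model error at
        [0.9, 1.2, 1.5, 1.8, 2.1] s (3-s flights) and
        [1.05, 1.4, 1.75, 2.1, 2.45] s (3.5-s flights)."""
        expected = {
            3.0: [0.9, 1.2, 1.5, 1.8, 2.1],
            3.5: [1.05, 1.4, 1.75, 2.1, 2.45],
        }
        for T, times in expected.items():
            got = [privileged_time(s) for s in paper_set if s.flight_time == T]
            assert got == pytest.approx(times, abs=0.05)

    def test_agrees_with_independent_crossing_condition(self, paper_set):
        """Grid+bisection on the closed-form condition, run independently
        of the package, finds the same crossing."""
        for spec in paper_set:
            tau_star = brentq(
                lambda tau: oracle_crossing_condition(spec, tau), 0.05, 0.95
            )
            assert privileged_fraction(spec) == pytest.approx(tau_star, abs=1e-3)

    def test_condition_value_at_design_fraction(self, spec_gs30):
        # hand evaluation: rho'/rho at tau = 0.3 equals -1/0.7
        tau = 0.3
        x = spec_gs30.x_end * tau
        z = spec_gs30.z_init + (spec_gs30.z_end - spec_gs30.z_init) * tau
        rho2 = x * x + z * z
        drho_rho = (x * spec_gs30.x_end + z * (spec_gs30.z_end - spec_gs30.z_init)) / rho2
        assert drho_rho == pytest.approx(-1.4287, abs=1e-3)
        assert drho_rho == pytest.approx(-1 / 0.7, abs=1e-3)

    def test_scale_invariance_across_durations(self, paper_set):
        """Same ground track => same privileged fraction for 3 and 3.5 s."""
        by_id = {}
        for s in paper_set:
            by_id.setdefault(s.traj_id, []).append(privileged_fraction(s))
        for fracs in by_id.values():
            assert abs(fracs[0] - fracs[1]) < 1e-3

    def test_head_on_has_no_crossing(self, head_on_spec):
        with pytest.raises(NoPrivilegedTimeError):
            privileged_time(head_on_spec)

    def test_mirror_invariance(self, spec_gs50):
        assert privileged_time(spec_gs50) == pytest.approx(
            privileged_time(spec_gs50.mirrored()), abs=1e-9
        )


class TestCueDiscriminability:
    def test_launch_elevation_rate_between_durations(self, spec_gs50):
        """gamma_dot at launch scales with T at equal launch depth:
        a (3.5 - 3)/3 = 16.7% change, beyond the 5% Weber threshold."""
        long = spec_gs50.with_flight_time(3.5)
        cues = {c.cue: c for c in cue_discriminability(spec_gs50, long, (1e-6, 1e-6))}
        gd = cues["gamma_dot"]
        assert gd.rel_diff_pct == pytest.approx(100 * 0.5 / 3, abs=0.1)
        assert gd.discriminable

    def test_identical_flights_not_discriminable(self, spec_gs50):
        cues = cue_discriminability(spec_gs50, spec_gs50, (1.0, 1.0))
        assert all(c.rel_diff_pct == pytest.approx(0.0, abs=1e-9) for c in cues)
        assert not any(c.discriminable for c in cues)

    def test_zero_reference_cue_is_undefined(self, spec_gs50):
        # gamma is exactly zero at launch
        long = spec_gs50.with_flight_time(3.5)
        with pytest.raises(UndefinedRatioError):
            cue_discriminability(spec_gs50, long, (0.0, 0.0))

    def test_all_cues_discriminable_at_typical_viewing_time(self, paper_set):
        """At a representative last-visible frame every cue, and the
        composite model output separate the two durations; the combined
        GS output amplifies the duration difference well beyond any
        single cue's threshold."""
        by_id = {}
        for s in paper_set:
            by_id.setdefault(s.traj_id, {})[s.flight_time] = s
        for pair in by_id.values():
            cues = {c.cue: c for c in cue_discriminability(pair[3.0], pair[3.5], (1.4, 1.4))}
            assert cues["theta"].discriminable
            assert cues["gamma"].discriminable
            assert cues["gs_output"].discriminable
            assert cues["gs_output"].rel_diff_pct > 20.0
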