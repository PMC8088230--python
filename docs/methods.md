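# Methods

## The task and the model

An observer watches a ball launched from ~25 m away on a parabolic
trajectory that returns to eye level after 3 s (or, on one trial in
six, 3.5 s). Visibility is restricted to the first 300 ms and a single
400-ms midflight window that the observer opens by looking up; the
observer then presses a button at the judged moment of return. The
scientific question is whether the remaining time to contact (TTC) is
estimated from the optic variables available in the chosen window, and
whether observers seek out the moments at which those variables are
most informative.

The TTC estimator at the package's core combines two context priors —
gravitational acceleration `g` and physical ball size `s = 2r` — with
three monocular optic variables: the angular size `θ`, the elevation
angle `γ` of the ball above eye level, and its rate of change `γ̇`:

    TTC_GS = (2/g) · (s/θ) · (γ̇ / cos γ)

`s/θ` estimates the eye–ball distance from retinal size, division by
`cos γ` converts it to horizontal distance, and `2/g` turns the
elevation rate into seconds. For a ball landing on the observer
(head-on) the estimate equals the true remaining time throughout the
flight; we verify this identity to 1 ms in the tests. For laterally
offset trajectories the estimator is exact at launch, overestimates
early, crosses zero error once — the *privileged time* — and then
underestimates severely.

### The fraction-domain reduction

Writing τ = t/T and ρ(τ) for the horizontal (ground-track) distance,
the model output reduces (up to the O((r/d)²) angular-size term) to

    TTC_GS = T · (φ′(τ) − φ(τ)·ρ′(τ)/ρ(τ)),    φ(τ) = τ − τ²,

so zero error at τ\* is equivalent to ρ′(τ\*)/ρ(τ\*) = −1/(1 − τ\*), a
condition on the ground-track endpoints alone. Two consequences drive
the package:

* **Scale invariance** — the privileged *fraction* is the same for any
  flight duration over the same ground track, which is why the
  experimental set shows fractions 30–70% for both 3 and 3.5 s flights.
* **Inverse design** — prescribing τ\* gives one scalar equation in the
  endpoint parameters; fixing two of {z_init, x_end, z_end} and
  bracketing the third solves it. This reproduces the published launch
  depths (23.49…27.47 m) to well under 0.1 m.

The implementation evaluates the model only through the full 3-D
kinematics → optic projection path; the reduction above is used as an
independent oracle in the tests and as the inner condition of the
design solver, whose output is always re-verified through the full
pipeline.

## Numerical choices

* Angular size is `θ = 2·arctan(r/d)`, so `s/θ ≈ d` with relative error
  below `(r/d)²/3` (~6·10⁻⁶ at these distances); this convention makes
  the head-on identity hold to the stated 1 ms.
* `γ̇` is computed analytically as `(ẏρ − yρ̇)/d²`; a central finite
  difference of `γ` serves as the test oracle, never the implementation.
* `privileged_time` scans the error on a 1-ms grid over (0.05 T,
  0.95 T), takes the first positive→negative crossing (the profile also
  touches zero at launch, which is excluded), and refines it with
  Brent's method to 1e−9 s. Head-on geometries raise a dedicated
  no-crossing error.
* Error profiles stop at T − 1 ms to avoid the shrinking-distance
  regime irrelevant to offset trajectories.
* The design solver scans 400 points of the search interval for sign
  changes and refines each with Brent's method (1e−10 m); with several
  roots it returns the smallest and warns. All geometry is computed on
  |x|, so left/right mirrors are exactly equivalent.
* Cue discriminability reports the proportion of change of each cue
  (θ, γ, γ̇ and the composite model output) from its 3-s-flight value,
  against a 5% Weber threshold; a zero reference cue (e.g. γ at launch)
  is an error, not a zero.

## The synthetic observer

No behavioral dataset is distributed with the original study, so the
package generates trial tables with the statistical structure the
analyses assume. Defaults reproduce the session design: 12
participants × 6 blocks × 120 trials (8640 rows), five trajectory
geometries per block at 24 presentations each (20 at 3 s, 4 at 3.5 s —
the 5:1 ratio), sides balanced, a ±50 ms hit criterion.

Per trial: the preferred viewing time is Normal(base + 0.118·GSrel,
0.15 s), clamped to [0.5, T − 0.7] s; participants split into *early*
(7, base ≈ 1.0 s) and *late* (5, base ≈ 2.0 s) viewers, the 1.5-s
boundary used for classification. Gaze at reappearance is a linear
function of the ball's angular position plus noise (the generative
analogue of the gaze-prediction regressions). The prediction is
consumed at `t_pred = t_visible + 0.2 s` (the window midpoint) and the
response is

    response = (1 − w)·target + w·3.0 + intercept + N(0, σ₀ + k·(T − t_pred))

with central-tendency weight `w = 0.1` pulling toward the frequent 3-s
duration, σ₀ = 0.08 s, and prediction-decay rate `k = 0.04` s/s chosen
so hit probabilities land in realistic ranges (~0.1–0.35) with late
viewers more precise than early ones. The target is, per response
mode, the model-based estimate `t_pred + TTC_GS(t_pred)`, the true
flight time, or a fixed constant (optionally one per duration — used to
calibrate the cohort to prescribed per-duration means).

One deliberate deviation from a literal model-based target: past the
privileged time the GS output collapses toward and below zero and is
not a usable estimate — taken literally it would make late viewers
respond before their own viewing window. The synthetic observer
therefore treats model outputs below 0.2 s as invalid and falls back on
the frequent experienced duration. This choice is what produces the
empirically observed pattern of late viewers having lower response
variability and higher hit rates, while leaving the analysis side
untouched (the correspondence analysis regresses on the raw model
prediction).

What the generator does **not** emulate: continuous head/eye
kinematics, eccentricity-dependent reliability of γ, depth compression
of stereoscopic displays, learning across blocks. Passing
parameter-recovery tests therefore shows the pipeline recovers known
generative effects of this structure — not that human data would show
them.

## Statistical pipeline

* Outlier filter: within participant × trajectory × duration, responses
  outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are dropped (groups under 4
  trials skipped with a warning). The default synthetic session loses
  ~2% of trials, the order observed in real sessions.
* Mixed models: random-intercept linear mixed models via statsmodels
  MixedLM, fit by **full maximum likelihood** so likelihood-ratio tests
  on fixed effects are valid. BIC = −2ℓ + k·log n with k = fixed
  effects + 2 variance components. Flight duration enters as a 0/1
  indicator, so its coefficient is the mean response-time difference in
  seconds; GSrel enters as the numeric fraction 0.3–0.7 (the original
  report does not state its predictor coding, so no numerical match of
  that coefficient is claimed). A zero random-intercept variance is
  flagged singular and the fit coincides with pooled OLS.
* Deming regression: closed-form errors-in-variables slope with error
  variance ratio δ = 1 (orthogonal) by default, since the method but
  not δ is specified in the original analysis.
* Correspondence with the model: per participant × trajectory, a Deming
  fit of response-since-prediction on the model prediction at the same
  moment; the pooled slope CI is a participant-level nonparametric
  bootstrap (1000 resamples, percentile interval); the across-trajectory
  effect is a random-intercept model on GSrel.
* Proximity split: per participant × trajectory median split on
  |t_pred − privileged time| (ties to "closer"), Welch t on the signed
  error `response − T`.
* No multiple-testing correction is applied anywhere (none is applied
  in the original analysis).

## Simulation sizes

Deterministic checks run on millisecond grids (≤ 3500 evaluations per
flight). Stochastic checks use: full 8640-trial sessions for the
calibrated response-time recovery (10 replicates in the acceptance
script, 3 in the test suite); 4–6 participant × 1–3 block sessions for
pipeline unit tests; and 100 replicates of 10 × 40-row random-intercept
datasets for the CI-coverage property. These sizes are the package's
own defaults for a laptop-scale run.

## Known limitations

* The GS model is implemented for launch-and-land-at-eye-level
  parabolas only (the geometry of the task); arbitrary launch heights
  would change the φ(τ) factor.
* The inverse design exposes which endpoint parameter is freed rather
  than guessing the original tailoring procedure (one equation, three
  unknowns — the published triples are one solution family).
* The synthetic observer's decay constant `k` and the invalid-output
  fallback threshold are behavioral free parameters, constrained only
  qualitatively; conclusions about real observers cannot be read off
  the generator.
* Reported χ², BIC and coefficient values from the original human
  dataset are structural references only; that dataset is not
  distributed and is not reproduced here.
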