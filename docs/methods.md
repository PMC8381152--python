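# Methods

`enerloop` is a simulation test-bed for closed-loop regulation of a latent
"cognitive energy" state inferred from cortisol. It couples four models: a
pulsatile cortisol generator (the virtual patient), a state-space model
linking cortisol features to the latent state, hypothetical medication
dynamics, and a knowledge-based fuzzy controller. This note records the
models, the defaults, and the design choices that were genuinely open.

## Virtual patient

Cortisol secretion is a marked point process driving a linear two-compartment
cascade,

    dCort1/dt = -zeta1 Cort1 + n(t)
    dCort2/dt =  zeta1 Cort1 - zeta2 Cort2,      y_k = Cort2(k) + psi_k,

with `n(t)` a train of impulses whose inter-arrival times are gamma
distributed and whose amplitudes are Gaussian. The system is discretized
*exactly* on the 1-minute grid (matrix exponential of the 2x2 generator), so
the noise-free single-pulse response equals the bi-exponential closed form to
machine precision and superposition holds exactly; there is no Euler error
for tests to absorb.

Cohorts:

| cohort | gaps (min) | amplitudes (ug/dL/min) |
|---|---|---|
| healthy | gamma, mean 83.1, sd 11.3 | harmonic mean, baseline 6.1, cv 0.1 |
| cushing_no_circadian | gamma, mean 59, sd 11 | flat, 38 +/- 2.5 |
| cushing_circadian | gamma, mean 59, sd 11 | harmonic, baseline 38.5, cv 2.5/38 |

The harmonic amplitude mean uses two circadian harmonics (periods 1440 and
720 min). `CohortSpec` stores the gap law by its first two moments and
converts to gamma shape/scale internally; the healthy default corresponds to
shape 54 with the second parameter read as a rate per hour — an explicit,
config-overridable interpretation, since the shape/rate/scale convention for
that pair is ambiguous. Amplitude draws are resampled until positive
(negative secretion is unphysical) and the harmonic mean is floored at
0.1 ug/dL/min where the harmonics would push it non-positive.

Compartment rates default to `zeta1 = 0.12/min`, `zeta2 = 0.035/min` (plasma
half-life about 20 min) with measurement-noise variance 0.05 (ug/dL)^2; these
are physiologically plausible package defaults, not literature estimates, and
are per-subject configurable. Study subjects get a reproducible +/-10%
multiplicative jitter on `zeta1`, `zeta2` and the amplitude baseline.

Envelopes: local maxima/minima of the noisy measurement are located with a
60-min minimum separation, interpolated piecewise-linearly, extended flat at
the edges, and combined pointwise (max/min) so `R >= S` holds by
construction. The binary pulse-event series `c_k` marks ground-truth
secretion minutes; optional miss-rate/jitter corruption emulates an imperfect
upstream pulse detector. Real-time deconvolution of secretion times from raw
cortisol is out of scope.

## State-space model and decoder

The latent state follows

    x_k = rho x_{k-1} + u_k + I_k + eps_k,
    I_k = sum_{i=1,2} alpha_i sin(2 pi i k/1440) + beta_i cos(2 pi i k/1440),

observed through one Bernoulli channel, `P(c_k=1) = 1/(1+exp(-(gamma0 +
gamma1 x_k)))`, and two linear-Gaussian channels `R_k = r0 + r1 x_k + v_k`,
`S_k = s0 + s1 x_k + w_k`. `u_k` is the control input; `|rho| < 1` is
enforced so the unforced recursion is stationary.

**Filtering.** The prediction step is linear; the update maximises the
per-step posterior, solving

    (x - x_pred)/var_pred = gamma1 (c - p(x)) + r1 (R - r0 - r1 x)/sigma_v2
                          + s1 (S - s0 - s1 x)/sigma_w2

by Newton iteration (|dx| < 1e-10, at most 50 iterations; the posterior
log-density is strictly concave so the root is unique; an expanding-bracket
bisection is the fallback). The posterior variance is the inverse curvature
at the solution. With `gamma1 = 0` this is exactly the two-observation
Kalman update — the disambiguation used throughout the tests. Missing
channels simply drop their terms (infinite observation variance). The
initial condition is `x0 = 0` with the stationary prior variance
`sigma_eps2/(1 - rho^2)`.

**Smoothing and EM.** Offline estimation iterates an approximate E-step (the
MAP filter above plus an RTS-form backward pass on its Gaussian
approximations) and closed-form M-steps: joint least squares for
`(rho, alpha_i, beta_i)` from the smoothed first/second/lag-one moments,
residual moments for the variances, envelope regressions for `(r0, s0, s1)`,
and a Newton ascent with 15-node Gauss–Hermite quadrature for
`(gamma0, gamma1)`. Two deliberate constraints:

* **Scale anchor.** `r1` is held at 1, measuring the state in
  upper-envelope units; without an anchor the state scale, `gamma1`, `r1`
  and `s1` are jointly unidentifiable.
* **Observation-variance floor** (`min_obs_var`, pipeline default
  0.25 (ug/dL)^2). An envelope interpolated through the extrema of a noisy
  signal is smooth by construction, and unconstrained EM exploits that,
  driving one envelope variance toward zero and welding the state estimate
  to that envelope. Besides being an overconfident reading of an
  interpolation artifact, this destroys the control path: the filter then
  ignores its prediction step, through which medications act. The floor
  keeps the channel honest about extraction error.

Convergence is declared on the relative change of the one-step predictive
log-likelihood (also the returned trace). Because the E-step is approximate
the trace is a surrogate; it is required to be non-decreasing up to a
relative slack (1e-6 on model-generated data, 1e-3 in the cortisol pipeline,
where the state-space model is knowingly misspecified for the simulator's
output), and a larger decrease raises an error. Parameter recovery on
7200-sample simulations from a known model lands `rho` within ~0.01 and the
envelope slopes within a few percent — comfortably inside the 0.1 / 20%
gates the tests enforce.

## Medication dynamics and system identification

Each agent is a second-order cascade `z1 -> z2` with infusion rate `theta1`,
clearance rate `theta2` and sign `eta` (+1 excitatory, -1 inhibitory); a dose
is an impulse `q* delta(t - tau*)`, so the state response is the
bi-exponential kernel. Two independent computations of the response (exact
state recursion; regressor form `y = A y0 + B q`) agree to 1e-9 and
cross-check each other in the tests.

Identification minimises `J = 1/2 ||y - A y0 - B q||^2` under the
single-impulse constraint `||q||_0 = 1`: an outer Nelder–Mead multi-start
over log-rates wraps an exact inner step — because the columns of `B` are
shifts of one kernel, the exhaustive position scan with closed-form
least-squares amplitude reduces to a cross-correlation plus suffix sums.
The bi-exponential kernel is invariant under
`(theta1, theta2, q) -> (theta2, theta1, q theta1/theta2)`; results are
canonicalized to `theta1 > theta2` (prompt infusion, slower clearance),
without which noisy fits land on either branch with a dose off by
`theta1/theta2`.

Defaults: `theta1 = 0.5/min` for both agents (prompt onset);
`theta2 = 0.003/min` for the daytime stimulant (~4 h effective action) and
`0.002/min` for the bedtime inhibitor (~6 h), so a single dose of each covers
the waking day and the night respectively. These are hypothetical agents;
pharmacokinetic realism is a non-goal.

## Fuzzy controller

A Mamdani controller maps (time of day, state estimate) to a signed dose:
min for AND and implication, max for aggregation, centroid defuzzification
on a 1001-point grid over `[-q_max, q_max]`, dead band 1% of `q_max`.
Twelve rules cover four active time labels (early/late morning, early/late
evening) x three state labels (Low/Medium/High); the Night and Afternoon
labels carry no rules. Time sets are trapezoids whose support equals their
nominal interval (night 0–5 h, early morning 5–9, late morning 9–13,
afternoon 13–17, early evening 17–20, late evening 20–24) with 1-h shoulders
inside the interval — a label only activates once its period has begun, so
first-eligible-minute dosing lands at ~05:00 and ~20:00 rather than inside a
boundary crossfade. Output sets are seven symmetric triangles NB…PB with
shoulder ends.

Personalization: Low/Medium/High are placed at the 25th/50th/75th
percentiles of the subject's healthy-reference open-loop filtered state
(Low and High saturate beyond their percentile), and `q_max` is that
reference inter-quartile range — a full-strength dose moves the state by
about one healthy circadian swing.

Scheduling: the controller is consulted every minute of the controlled
period; outputs inside the dead band are ignored; positive outputs request
the excitatory agent and are honored only in the morning labels, negative
outputs request the inhibitory agent and are honored only in the late-evening
label (a bedtime agent — dosing it earlier would peak and partially clear
before the night it is meant to quiet). A per-day ledger allows at most one
dose of each class, hence at most two per day. Accepted doses superpose
their response curves into `u`, which the filter itself consumes — the
decoder and controller share the same control signal.

## Runs and metrics

A closed-loop run is open-loop (u = 0) before the activation day (default:
day 3 of 5) and controlled thereafter. Three balance metrics are computed
over the controlled days only, for the open- and closed-loop runs of the
same subject/seed, with `improvement = 100 (closed - open)/|open|`:

* day–night difference: mean state 06:00–16:00 minus mean state 22:00–04:00;
* wake growth: state rise across 04:00–08:00 (15-min means at endpoints);
* sleep drop: state fall across 20:00–24:00 (same endpoint treatment).

Windows are configurable; the day window follows the stated daytime-peak
interval and the others are the package's choices. The cohort study runs 10
subjects x 2 Cushing cohorts at 5 days each and reports per-subject metrics
plus median/quartiles. Problem sizes throughout (5-day horizons, 7200-sample
EM studies, 10 subjects, 3-seed repeats) are the package's standard
configuration and keep a full study to a few minutes on one core.

## What the generator does and does not show

The virtual patient reproduces pulsatility, circadian amplitude modulation,
cohort-level moment differences, and day-to-day stochastic variability. It
does not model assay drift, missing samples, posture/meal/stress responses,
medication effects on cortisol itself (doses act on the latent state through
the filter, not on the hormone), or inter-compartment nonlinearity. Passing
tests therefore demonstrate internal consistency of the architecture and
recoverability of its parameters under the stated laws — not clinical
validity. The improvement percentages depend on the medication defaults and
membership geometry above; the robust claim, checked across subjects and
seeds, is directional (all median improvements positive), not the specific
magnitudes.

## Known limitations

* The EM E-step is a Gaussian/MAP approximation; its predictive
  log-likelihood is a surrogate and can oscillate at ~1e-4 relative near
  convergence on off-model data.
* The event channel is weakly informative at realistic pulse rates
  (~1/80 min), so the envelopes dominate the state estimate.
* Single-impulse identification assumes one dose per identification window;
  multi-dose interaction is linear superposition only.
* The controller's rule base is fixed; no rule learning or long-acting-agent
  revisions.
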