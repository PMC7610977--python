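# Methods

This note documents the models, numerical choices and design decisions
behind `myoprop`, in the spirit of a methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task geometry and control law

The workspace is planar, with the origin at the start point, +x
rightward, +y toward the targets, and angles counterclockwise from +x.
Defaults: start zone Ø 3.6 cm, cursor Ø 1.8 cm, targets Ø 2.4 cm at 45°,
75°, 105° and 135° on an 8.6 cm ring, display rate 75 frames/s.

Cursor position is the DoA vector sum `x = Σ y_n,i · L · DoA_i` with unit
DoAs at 45° and 135°. Choices:

* **Length gain `L` = ring radius (8.6 cm).** The physical cm-per-unit
  activation scaling is a free parameter of any such interface; equating
  it to the ring radius makes the comfortable-contraction level the
  natural task amplitude (one muscle at `y_n = 1` exactly reaches a
  lateral target). It is configurable (`gain_length_cm`).
* **Clamping.** Normalized activations are clamped at 0 before the
  mapping — rectified EMG below the rest level cannot pull the cursor
  backward past the start — but not clamped above 1, so overshoot beyond
  the ring is possible. The online pipeline applies the same one-sided
  clamp.
* **1D mode.** For targets collinear with a DoA the other muscle's
  contribution is zeroed, confining the cursor to the target ray.

With the default orthogonal DoAs the mismatch of a 2D trial equals the
Euclidean norm of the activation error — a convenient identity the
synthetic-subject calibration exploits.

## EMG processing

The envelope is the causal mean of the rectified signal over the
preceding 750 ms (rectangular window), evaluated on the 75 Hz display
frame grid rather than at the 2500 S/s acquisition rate, because that is
where the control loop consumes it. At stream start the window truncates
to the available samples; a frame before the first sample is an error.
Calibration takes the offset as the mean of the raw rest segment and the
rest/comfortable levels as time-averaged envelopes of the
offset-corrected segments; a contraction level not exceeding the rest
level raises a calibration failure. Band-pass filtering (30 Hz–1 kHz) of
real recordings is treated as applied upstream by the acquisition
hardware.

The synthesizer produces amplitude-modulated band-limited Gaussian noise.
Because the rectified mean of a zero-mean Gaussian is `σ·√(2/π)`, the
instantaneous σ is the target envelope times `√(π/2)`; the band-passed
carrier is normalized to unit variance empirically (per realization, so
the stream is reproducible for a fixed seed). The synthesize → envelope →
normalize round trip recovers a piecewise-constant activation within
±0.05, verified by test.

## Manipulandum model

The handle is a planar point mass (1 kg) with viscous damping (5 N·s/cm)
under PID control toward the cursor (or its mirror image `(x, y) →
(−x, y)` in the incongruent protocol). The real device's parallelogram
arm kinematics, motor torques and encoder quantization are out of scope:
only the fidelity of the delivered feedback signal matters to the
analysis, and the published device characteristics are not reproduction
targets.

Numerical choices:

* **Derivative on the measurement** (−Kd·v rather than Kd·de/dt), which
  avoids derivative kick on reference steps.
* **Anti-windup**: the error integrator freezes on any axis whose force
  output is saturated.
* **Semi-implicit Euler with implicit viscous term.** Taking damping
  implicitly makes the update unconditionally stable in the damping/mass
  ratio; with the explicit form, light plants (used to verify the
  first-order closed-form limit) diverge at 75 Hz.
* **Default gains** Kp = 200, Ki = 60, Kd = 25, force limit 300 were
  chosen for smooth tracking of task-speed (≲ 1 Hz) references, giving a
  mean cursor–handle distance of roughly 1.7 cm and a positive (causal)
  lag on a 0.5 Hz circular reference.
* **Lag estimation** is the argmax of the axis-summed cross-covariance
  over integer frame lags within ±0.5 s, ties resolved toward the
  smallest absolute lag, reported in ms as `frames/75·1000`; the median
  over trials is aggregated. Constant trajectories have undefined
  correlation and are reported as missing.

## Trial state machine

The frame grid spans [−0.5 s, 2.0 s) around target appearance: 38
pre-cue frames (0.5 s at 75 Hz rounds 37.5 up), 75 movement frames, 75
hold frames. Cue tones (660 Hz at t = 0, 880 Hz at t = 1 s, 250 ms) are
recorded as timestamped events only. The score counts hold frames with
`|target − cursor|₂ < r_target + r_cursor`; exact tangency does not
count (strict inequality). A subject that cannot keep the cursor in the
start zone within a 10 s timeout yields an invalid trial that is
rescheduled once at the end of its block — the original protocol only
states that the task waited for the start criterion, so this termination
rule is an explicit invention of the simulator.

The handle never feeds back into the cursor; all random draws happen
before the handle simulation, so cursor trajectories are bit-identical
with the manipulandum enabled or disabled (verified by test). Cohort
generation therefore skips the handle by default and enables it only for
tracking-fidelity studies.

Schedules satisfy, in every test block of 24 trials, VF+PF × target = 3
and PF/VF/noFB × target = 1; the within-block order is a uniform seeded
shuffle (the constraint, not the shuffling algorithm, is prescribed), and
familiarization targets are balanced in shuffled groups of four.

## Metrics

Target mismatch is the hold-phase mean cursor–target distance normalized
by the start–target distance. Polar errors use the start point as
origin; radial error is normalized by the target radius vector
(`|r_c − r_t| / r_t`) so that on the target ray — hence for all 1D
trials — it coincides with the mismatch exactly (identity checked to
1e-12). Angular error is wrapped to [0°, 180°]; frames with cursor radius
below 5% of the ring radius have no well-defined angle and are excluded
from angular window means (the angle at the origin is undefined; the
exclusion radius is our documented choice). Time windows are half-open
([0, 0.5), [0.5, 1), [1, 1.5), [1.5, 2) s) so the 150 post-cue frames
partition exactly.

## Synthetic subjects

A subject is a first-order feedback controller in activation space — the
simplest structure that expresses all four condition contrasts. All of
its equations are this package's construction; the things it must
reproduce are behavioural regularities, not fitted human data (none are
available).

Per trial `k` with required activation `u*`:

* plan: `u_plan = u* + bias + ε`, `ε ~ N(0, σ(k)² I)`,
  `σ(k) = σ_∞ + (σ₀ − σ_∞)·e^{−(k−1)/τ_learn}`, clamped at 0;
* execution: `u = max(0, u_ff + c)` where `u_ff` ramps to `u_plan` at
  rate `g_ff` (exact exponential discretization, stable for any rate) and
  the correction integrates `dc = G·(u* − u)·dt + σ_exec·√dt·ε_t`;
* feedback gains: `G(VF+PF) = g_v + c_v·g_p·w_p`, `G(VF) = g_v`,
  `G(PF) = g_p·w_p`, `G(noFB) = 0`. The **vision-precedence factor**
  `c_v` (0.3) down-weights the proprioceptive channel when a visible
  cursor allows direct cursor–target matching; without it the model
  predicts a clear VF+PF-over-VF advantage in overall mismatch, which is
  not what such experiments find;
* learning: the proprioceptive association weight `w_p ∈ [0, 1]` grows
  by `η` on every trial with proprioceptive feedback, multiplied by
  `mirror_penalty` when the feedback is mirrored *and* vision is present
  (incongruent proprioception is down-weighted while vision is
  available, but learnable when it is the only error signal); the bias
  decays with `τ_learn` and is corrected against the terminal activation
  error at rate `η_T` (the end-of-trial display is available in every
  condition, giving slow improvement even without on-line feedback).

Learner defaults (frozen after a one-time calibration so that the four
qualitative condition findings hold at the standard cohort sizes):
σ₀ = 0.40 (±10% per subject), σ_∞ = 0.22, τ_learn = 90 trials (log-normal
20% spread), |bias| = 0.35 (random direction), g_ff = 8 /s, g_v = 3.5 /s,
g_p = 2.0 /s, c_v = 0.3, w_p(0) = 0.02, η = 0.003, mirror_penalty = 0.15,
η_T = 0.01, σ_exec = 0.25, rest noise 0.01. Units: activations are
normalized (1 = comfortable contraction), gains 1/s, τ in trials.

**Non-learners** are modelled as tonic co-contraction of both muscles
(bias uniform in [0.6, 1.1] per component), large non-decaying planning
noise (σ = 0.6) and feedback gains attenuated 50-fold, with no cross-trial
learning. Co-contraction, not random error, is the failure mode because
the one-sided activation clamp caps how large *undershoot* errors can
appear: a purely noisy non-learner saturates near the exclusion
threshold, whereas over-activation is unbounded and robustly exceeds it.
At these settings the standard exclusion rule (mean visual-feedback
mismatch over trials 121–240 strictly greater than 0.8) flags exactly
the simulated non-learners across seeds, and no learner, as verified by
test.

Subjects are seeded from the cohort seed by `SeedSequence` spawning (one
child per subject, split into schedule, trial-noise and parameter
streams), so a cohort is byte-identical for a fixed seed. The default
cohort sizes are 21 (protocol 1) and 19 (protocols 2 and 3), with a 10%
default non-learner fraction rounded to a count.

What the generator emulates: condition-ordered accuracy
(noFB > PF > VF ≈ VF+PF), exponential learning curves, a
proprioceptive-association benefit that requires prior paired exposure,
delayed integration of mirrored feedback, slow no-feedback improvement
from terminal feedback, and non-learners. What it does not emulate: the
transient performance drop in the visual condition when new feedback
conditions first appear; within-trial submovement structure and reaction
times; signal-dependent (amplitude-proportional) EMG noise in the
activation loop (the raw-EMG synthesizer has it, the subject model uses
additive noise); carry-over of subjects between protocols 2 and 3 (each
cohort is fresh, as the new muscle pair must be learned anew); and any
quantitative match to human effect sizes. Passing tests therefore
certify the pipeline's correctness and the stated qualitative structure,
not human performance levels.

## Statistical pipeline

* **Exclusion** is strict (`> 0.8`) and idempotent.
* **Learning curves** pool trials of retained subjects per condition per
  24-trial block (mean and SEM).
* **Exponential fits** use `m(b) = a + b·e^{−(b−b₀)/τ}` and a
  two-exponential variant for the condition present from trial 1; the
  functional forms are our choice (the convention in the field names
  only "exponential"). Fitting is bounded nonlinear least squares with a
  multi-start τ grid; fit significance is an F-test against the constant
  model. For flat data the (amplitude, τ) split is unidentifiable — the
  F-test is the meaningful output there, and tests assert flatness of
  the fitted curve rather than a particular parameter decomposition.
* **Block-paired t-tests** pair trials by (subject, target) within each
  block, requiring exactly one trial per condition per key; a missing or
  duplicated pairing raises an error naming the offending key. Normality
  of the differences is checked with Shapiro–Wilk and failures are
  *warnings*, not gates (the t-tests are reported regardless). The
  per-test level is 0.05 divided by the number of blocks in the family
  (15 in protocol 1 — printing as 0.0033 at two significant figures — 5
  in protocols 2 and 3). Identical samples give t = 0, p = 1 rather than
  an undefined statistic.
* **Resampled VF+PF tests** pick one of the three matching VF+PF trials
  per (subject, target, block) key uniformly at random, run the pooled
  paired t-test, and repeat 500 times with an RNG stream independent of
  the cohort's; the p-value distribution is returned. Under a null
  cohort the per-resample rejection rate is the t-test's nominal rate;
  because resamples within a cohort share data, validity checks average
  the rejection fraction over many independent cohorts and use the
  binomial interval at the cohort count, which is conservative.

Both pooled and per-dimension (1D/2D) analyses are possible by filtering
the summary table's `is_2d` column; the pipeline itself does not force
either choice.

## Problem sizes in the test suite

The suite verifies the statistical properties at sizes chosen to keep a
full run under a minute while leaving the checks well-powered: 200
simulated null cohorts for the family-wise error bound (compared against
the one-sided 95% binomial acceptance limit, since the observed rate of a
correctly calibrated procedure fluctuates around 0.049), 200 null
cohorts × 500 resamples for the resampling test's nominal rate, 20 seeds
for curve-fit recovery, and full-size default cohorts (21/19/19 subjects,
fixed seeds) for the qualitative condition findings. The qualitative
findings are operationalized as explicit margins on pooled condition
means: late protocol-1 ordering with noFB − PF > 0.10, PF − VF > 0.02 and
|VF − (VF+PF)| < 0.03 (the equivalence band, 3% of the normalized error
scale); an early PF benefit < −0.15 in protocol 1 but absent (|Δ| < 0.08)
at the start of protocol 2, emerging later (> 0.05); and a mirrored-PF
early benefit at least 0.08 weaker than the congruent one, with a late
benefit > 0.03.

## Known limitations

* The subject model's feedback term acts directly in activation space
  with a known `u*`; it abstracts away the visuomotor transformation a
  real subject must perform, so reaction-time and path-curvature
  phenomena are out of reach.
* The manipulandum model is a point mass; its fidelity numbers
  characterize this simulation, not any physical device.
* Learning-curve forms are phenomenological; τ estimates are only
  comparable within this model family.
* The score's floor/ceiling censoring makes it a poor primary metric —
  it is computed and stored, but the mismatch drives all analyses, for
  exactly that reason.
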