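# Methods

This note documents the models implemented in `ofcppf`, the defaults and
why they were chosen, what the synthetic closed-loop subject does and
does not emulate, and the numerical choices that matter.

## Architecture

The package implements a spike-event-resolution closed-loop decoder
adaptation (CLDA) architecture with four interacting pieces:

1. **Cursor prior** (`dynamics`): the linear model
   `x_t = A x_{t−1} + B u_{t−1} + w_t` over `x = [pos, vel]` in cm and
   cm/s, bin width Δ = 0.005 s.  A has an identity position block with Δ
   coupling to velocity and a scalar persistence `a` on velocity; B
   injects the 2D control into velocity scaled by Δ; `W = diag(0,0,w,w)`.
   Any zero-velocity state is a fixed point of A, so instructed targets
   are preserved by the prior.  `fit_dynamics_ml` recovers `(a, w)` from
   uniformly sampled velocities by per-dimension AR(1) regression through
   the origin with sufficient statistics pooled across the two dimensions
   (the estimator is exact ML under the model; pooling reflects the
   isotropy of the model's noise).

2. **Subject model / intention estimation** (`ofc`): infinite-horizon
   LQG.  State cost `diag(1, 1, w_v, w_v)` around the target state,
   control cost `w_r I₂`.  The cost is written around the shifted error
   `e = x − x*`; because `A x* = x*`, the cross terms vanish and the
   standard LQR reduction applies.  The default intention model is
   instant-OFC (`a = 0`, `w_v = 0`): with this dynamics the control
   directly sets the intended velocity, so a control cost alone enforces
   both stopping and effort.  The naturalistic variant (fitted `a`,
   `w_v > 0`) is available through the same entry points.

3. **Encoding and adaptation** (`point_process`, `param_filter`): binary
   spike events with log-linear velocity tuning
   `λ = exp(β + αᵀv)`, conditionally independent units.  Per-unit
   parameter posteriors are Gaussian, propagated by a random-walk
   prediction (`cov += Q`) and a point-process information update with
   the shared regressor `s = [1, ṽ]` built from the OFC-inferred intended
   velocity.  Units never interact, so the ensemble update is a batched
   rank-one (Sherman–Morrison) operation.

4. **Decoding and assistance** (`kin_decoder`, `assist`): a *velocity*
   point-process filter — only the velocity block is updated by spikes;
   position is the exact integral of decoded velocity, and its
   covariance rows/columns are held at zero (position is deterministic
   given decoded velocities).  During assisted training the prediction
   uses the feedback-controlled prior `(A − B L_a) x + B L_a x*`; the
   intensities in the update are evaluated at the one-step-predicted
   velocity with the previous bin's parameter estimates.  Workspace
   clamping is applied after the update.

## Riccati solver

Steady-state gains are computed by a structure-preserving doubling
recursion on (A, B R⁻¹Bᵀ, Q), which squares the effective horizon each
pass and converges quadratically.  A plain one-step Riccati recursion is
used as the independent oracle in the tests; it agrees entrywise to
1e-6, but is impractical as the primary solver because weak-assistance
gains (large τ) produce closed loops with spectral radius ≈ 1 − Δ/τ²,
requiring millions of one-step passes.  Convergence is declared on the
*relative* fixed-point residual `‖P − Riccati(P)‖_F / ‖P‖_F < 1e-8`
(tolerance 1e-10 inside the solver); the residual is normalized because
P scales with `w_r = τ⁴`, which spans sixteen orders of magnitude over
the assistance schedule, making an absolute criterion meaningless at the
weak end.  Gains solved for the instant-OFC cost (singular state cost)
are handled by the same route.

## Numerical choices

- Per-bin spike probability capped at `λΔ ≤ 0.98`, keeping the Bernoulli
  approximation valid and the information updates bounded.
- Multi-spike bins are clipped to 1 and counted; a diagnostic warning
  fires when more than 0.6% of spikes land in occupied bins (the
  empirical rarity threshold at 5 ms bins).
- Parameter posteriors are updated in covariance form via the rank-one
  identity; symmetry is re-imposed after every update.  Positive
  definiteness is checked by Cholesky on construction.
- The SmoothBatch GLM (Poisson log-likelihood on λΔ with offset log Δ,
  the small-Δ limit of the Bernoulli model) is fit with statsmodels;
  spike-free batches carry the previous estimate forward with a flag.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| Δ | 0.005 s | spike-event bin width |
| decoder `a` | 0.97 | velocity persistence per bin (~170 ms correlation time) |
| decoder `w` | 1.0 (cm/s)²/bin | velocity prior noise |
| intention `w_r` | 1.25e-5 | instant-OFC control cost |
| assist ladder τ | 0.4, 0.6, 0.9 s | most → least assistive |
| assist timing | 120 s/level, 120 s test | first assist period ≈ 6 min |
| test threshold | 5 trials/min | non-assisted rate that stops assistance |
| Q | 1e-7 I₃ per bin | parameter random-walk noise (learning rate) |
| initial param cov | 1e-2 I₃ | broad relative to tuning magnitudes |
| units | 20 | baselines 5–25 sp/s, depths 0.05–0.15 /(cm/s), PDs uniform |
| motor noise | 1.5 cm/s | white noise on the subject's intended velocity |
| workspace | 24 × 24 cm | positions clamped, normal velocity zeroed at walls |
| task | 8 targets, 13 cm ring, 1.2 cm radius, 250 ms holds, 10 s timeout | center-out family |

The intention-estimation control cost was chosen so that the closed-loop
policy completes a 6.5 cm reach in roughly 1–1.5 s with peak speeds near
10 cm/s — naturalistic cursor kinematics for this task geometry.  The
decoder prior `(a, w)` was chosen the same way: with the default encoder
it supports reach times around 1.5 s and steady-state rates around 12–15
trials/min, the proficient-control regime for this task.  The assistance
ladder was placed where assistance is *useful but not sufficient*: at
the strongest default level (τ = 0.4) the prior alone completes trials
at roughly 11/min — clearly above zero (so a poor decoder still supports
engagement) yet clearly below engaged performance (so the chance-level
comparison is informative).  All of these are configuration, exposed on
`SimulatorConfig`.

## The synthetic subject

The closed-loop "brain" observes the displayed (decoded) cursor
noiselessly and instantaneously, forms an intended velocity through its
own instant-OFC policy toward the instructed target plus white motor
noise, and its ground-truth units spike from the log-linear model of
that intention.  By default the brain's policy cost equals the
architecture's intention-estimation cost: the intention estimator is, by
construction, a good model of this subject.  Configuration allows a
mismatched brain (different `w_r`, different motor noise) to study
robustness.

What this subject does **not** emulate: neural plasticity or any change
of the encoder over time; engagement dynamics (it never loses
motivation — assisted training is therefore not *necessary* for
convergence here, unlike with a real subject); feedback delays and
visual noise; history-dependent (refractory/bursting) spiking; position
or acceleration tuning; non-stationary baselines.  Passing tests
therefore demonstrate that the estimation and control machinery is
correct and that the architecture's comparative properties (spike-event
vs batch, OFC vs CursorGoal, assisted vs not) hold in closed loop under
the model's own assumptions — not that the same effect sizes would be
obtained in vivo.

Decoder initializations mirror the experimental seeds: a
"visual-feedback" seed (the true encoder, measured imperfectly: PDs
jittered by 20°, depths log-normally perturbed, baselines perturbed) and
an arbitrary seed obtained by permuting that seed across units.

## Task and session conventions

Trials are self-paced: the subject returns the cursor to the start
target, holds 250 ms, a peripheral target appears (this is trial
initiation), and the reach must arrive within the timeout and hold
250 ms.  Holds are strict — leaving the target before the hold elapses
fails the trial immediately, with no re-entry.  A short (0.2 s)
inter-trial interval carries no instructed target; parameter adaptation
runs only while an instructed target exists.  In the target-jump task a
jump trial redirects the target 500 ms after the cursor leaves the
center; in the target-to-target task each trial starts at the previous
trial's end target.  Adaptation runs for a configurable duration
(default: the whole session); the experiments freeze parameters
explicitly when evaluating trained decoders.

Behavioral metrics follow the standard conventions: success rate in
2-min windows (non-overlapping or sliding at 1 s); steady-state success
rate over the best sliding 10-min window (1 s grid); percent correct,
reach time and movement error over the best contiguous 100 trials;
convergence time as the first time the sliding windowed rate reaches 90%
of its session maximum.  The parameter-distance diagnostic is the plain
per-component-group Euclidean distance (mean over units of `|Δβ|` and of
`‖Δα‖`); because its absolute scale is convention-dependent, the
experiments report start/end ratios rather than absolute values.

## Problem sizes

The simulation experiments use 20-unit ensembles and 10-minute sessions
(120,000 bins) with 5 seeds for recovery and robustness studies, 10
matched pairs for the adaptation-time-scale comparison, and 20
disengaged runs of 2 minutes for chance-level distributions.  These
sizes give stable medians while keeping a full run of the experiment
suite in the tens of minutes on one core.

## Known limitations

- The parameter filter's Gaussian approximation is exercised in the
  small-update regime (per-bin information ≪ prior information); the
  grid-Laplace agreement test quantifies exactly this regime.
- The chance-level distribution at strong assistance is narrow (the
  assisted prior dominates), so its 99th percentile is estimated from 20
  runs with correspondingly coarse resolution.
- `parameter_distance` is a stand-in diagnostic; its normalization is a
  package convention.
- The assisted-training restart rule (which level to resume at after a
  failed test) is configuration (default: the middle level); no claim is
  made that this matches any particular experimental protocol.
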