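# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the simulator does and does not emulate, and the numerical
choices a user should know before trusting or extending the results.

## Model structure

### Generative assumptions

A reach is a point-to-point movement of a planar two-link arm. The subject
sees a cursor: the hand path rotated about the movement start by the total
visuomotor rotation in play. Two rotation sources are modelled:

* **body rotation θ_b** — a miscalibration carried by the subject
  (proprioceptive/postural). It is part of every movement, so it is always
  relevant and always subject to adaptation. It decays per filter update with
  forgetting factor `a_b` and receives process noise `σ_b²`.
* **world rotation θ_w** — an externally imposed rotation (the experimental
  manipulation). It enters the observation only when it is *relevant*
  (λ = 1). Its forgetting factor is pinned at `a_w = 0.99999`, so a learned
  world estimate is effectively permanent on experimental time scales; this
  is the model's long-term memory.

The observation is the cursor position and velocity sampled along the path,
with isotropic Gaussian noise (σ_pos = 0.01 m per sample; velocity noise
σ_vel = 0.04 m/s, i.e. the position scale carried to velocity units over a
tenth of the movement time).

### Relevance inference

Relevance is a binary Markov variable with transition matrix
`[[0.999, 0.001], [0.001, 0.999]]`: the prior for each movement is the
previous posterior contracted toward 0.5 by the factor
m₁₁+m₂₂−1 = 0.998. Once per movement the whole observed path is reduced to
θ_y — the planar Procrustes angle that best maps the *body-only* predicted
path onto the observation (closed form: atan2 of summed cross/dot products of
origin-centred samples). Two likelihood densities over θ_y are then compared.

Under λ = 1, the world rotation could be anything except negligibly small, so
the prior over rotations is `(1 − exp(−θ²/2σ_θ²))/Z` on (−π, π]. Convolving
with the observation model N(θ; θ_y, σ_θ²) via the Gaussian product identity
gives

    L1(θ_y) = (1 − exp(−θ_y²/4σ_θ²)/√2) / Z,
    Z = 2π − √(2π) σ_θ erf(π/(√2 σ_θ)).

Z is computed exactly; the common 2π approximation changes likelihood ratios
only in the third significant digit. Under λ = 0 the prior is N(0, σ_θ²) and
the convolution gives `L0(θ_y) = N(θ_y; 0, 2σ_θ²)`. Both closed forms are
verified against adaptive quadrature of their defining integrals in the test
suite (truncation of the Gaussian tails outside (−π, π] is below 1e−300 for
every angle used). σ_θ = 2.5°, the angle subtended at arm's length by the
positional observation noise. The likelihoods cross at |θ_y| ≈ 9.8°: below
that, evidence drives relevance down; above it, up — the crossing acts as the
model's "this cannot be me" threshold.

On error-clamp trials the display is pinned to the straight reference, the
evidence is uninformative, and both likelihoods are held at 0.5; the
posterior then relaxes toward 0.5 geometrically with ratio 0.998 per
movement. When the robot handle is not held (inter-session "natural"
movements) a visuomotor rotation is impossible and relevance is forced to 0.

### Gated estimation

The filter state is p = [θ_b, θ_w] with covariance P. Per update:
propagation `p ← A p`, `P ← A P Aᵀ + Q`; then a measurement update against
the observed path segment. The measurement Jacobian is the analytic
derivative of the rotated planned path with respect to the rotation angle;
both parameters enter as a summed rotation, so the two columns are equal.

The update is gated by the movement's posterior relevance λ̂:

* λ̂ = 1: standard EKF update (gain K = P Hᵀ (H P Hᵀ + R)⁻¹).
* λ̂ = 0: the world row of K is zeroed; the world estimate and the world
  row/column of P are left untouched. Because freezing a row/column of an
  updated covariance can make the 2×2 matrix indefinite, the body variance is
  floored at P_bw²/P_ww — the filter cannot become more certain about the
  body than the retained cross-covariance permits.
* 0 < λ̂ < 1: convex combination of the two branch results (parameters and
  covariance separately), symmetrized, with an eigenvalue floor at zero as a
  safety net (it does not engage in normal operation). The endpoints are
  exact by construction; the interpolation rule in between is a design
  choice — alternatives (e.g. blending gains instead of covariances) change
  nothing at the endpoints and were found not to change the phenomenology,
  consistent with the fast (2–3 movement) relevance transitions that make
  intermediate λ̂ rare.

Planning uses the *prior* relevance: the reach is counter-rotated by
`θ_b + P(λ=1|prior) · θ_w`. The predicted observation against which residuals
are formed uses the same movement-start compensation: the model predicts the
consequences of the commands it actually issued, and mid-movement estimate
updates only shape the next movement. This choice makes clamp-trial residuals
exactly zero (so clamp decay is pure forgetting, monotone by construction);
predicting from the continuously updated state instead lets the filter
re-attribute the body estimate's within-movement decay to the world parameter
(a slow upward creep of θ_w early in a clamp block).

Estimates are updated 6 times per movement on 6 equal path segments;
relevance once per movement from the whole path.

### Plant

Two-link planar arm (no gravity): segment lengths 0.33/0.34 m, masses
1.93/1.52 kg, inertias 0.0141/0.0188 kg·m², COM at 0.165/0.19 m, joint
viscosity 0.2 N·m·s/rad — a standard adult set; all configurable, and nothing
in the tests depends on the specific values. Reaches are 0.1 m, 0.5 s,
center-out to 8 targets drawn uniformly per trial; the reference is a
minimum-jerk profile through 8 equally spaced via points. Control is
inverse-dynamics feedforward (joint trajectory from analytic IK,
derivatives by central differences) plus joint-space PD feedback
(kp = 25 N·m/rad, kd = 3 N·m·s/rad — near critical damping for this arm);
integration is fixed-step RK4 at 1 ms (numba-compiled). Rotations are applied
about the movement start. The angular reach error is read out at the sample
of peak tangential speed (endpoint readout selectable).

## Free parameters and calibration

Four constants are free: `a_b`, `σ_b`, `σ_w` (per update) and the initial
covariance scale. They are not identifiable from first principles, so they
were fixed by `scripts/calibrate.py`, which scores candidate sets on the
paradigm-level phenomenology under one fixed configuration:

| constant | shipped | role |
|---|---|---|
| `a_b` | 0.98 /update | body forgetting; sets washout speed and the body's sustainable share |
| `σ_b` | 0.175°/update | body process noise; body Kalman gain (fast) |
| `σ_w` | 0.033°/update | world process noise; world gain (slow integrator) |
| `p0_scale` | 10 (P₀ = 10·Q) | initial uncertainty; near the filter's steady state |

The constraints pull in different directions and the shipped values sit in
the (not very large) region satisfying all of them: the world must be fast
enough to bring errors under the 5° criterion within an 80-trial block, yet
slow enough that a 20-trial counter-block cannot reverse it (else no
rebound); the body must be strong enough that relevance collapses partway
through a full-length counter-block (else the A-B-A day-2 behaviour is not
naive-like), yet weak enough that it cannot track a gradual ramp completely
(else relevance never engages and the gradual world estimate is zero).
P₀ = 10·Q rather than a much larger multiple keeps the first movements of a
naive run on the same smooth exponential as the rest of the block instead of
producing a one-trial step. A broad-then-fine grid search was run once and
the winner frozen; `python scripts/calibrate.py --fine` reproduces the final
neighbourhood table.

Block-length defaults (80 adaptation, 80 washout, 20 counter, 100 clamp,
linear ramp over 50 trials + 30 plateau, 300 natural movements between
sessions, day-start relevance 0.75, 5° criterion) are configurable; trial
counts are nominal since the inference is invariant to jointly rescaling the
per-update constants with time.

## What the simulator does and does not emulate

The synthetic experiments reproduce the *structure* of the classic protocols:
abrupt/gradual onsets, robot-held washout, multi-day sessions with overnight
de-adaptation, error clamps, counter-blocks. Passing tests show that the
gating mechanism produces savings, interference, rebound, washout asymmetry
and the gradual/abrupt credit split under idealized conditions. They do not
show quantitative fits to human data: there are no muscle dynamics, no
signal-dependent noise, no feedback delays, no trial-to-trial planning
variability beyond observation noise, targets are isotropic, and the error
measure is noiseless (observation noise corrupts only what the model sees,
not what the experimenter records). Force-field dynamics are not modelled;
clamp comparisons to force-channel experiments are made through the
visuomotor analogue. Only one world parameter exists, so multi-disturbance
consolidation phenomena are out of scope by construction.

## Numerical choices and degenerate inputs

* Observations are sampled at 60 Hz (every 17th integration sample); the
  innovation solve per segment is a ~20×20 Cholesky-sized problem.
* Procrustes angle: a path with all samples at the origin returns a
  degenerate flag and the movement is treated as uninformative (likelihoods
  0.5).
* `update_relevance` guards against a vanishing evidence denominator (cannot
  occur with the shipped closed forms).
* Integrator divergence (unstable gains) raises a simulation error naming the
  trial; covariance health is enforced as described above (min eigenvalue
  ≥ −1e−12 is the tested contract).
* Angles are radians internally and degrees in every file, CLI and record
  field; angle wrap keeps θ_y in (−π, π].
* Full determinism: a run is a pure function of (config, seed); one
  `numpy.random.Generator` drives target selection and observation noise.

## Known limitations

* The relevance threshold (~4σ_θ) makes small-rotation experiments (≲10°)
  adapt almost purely through the body parameter; the model then predicts no
  long-term retention, a strong and testable (possibly wrong) prediction.
* The convex-combination gate is one of several defensible blends; behaviour
  at intermediate relevance is heuristic.
* With matched-length A and B blocks the world estimate over-reverses
  somewhat rather than landing exactly at zero; day-2 behaviour is still
  naive-like because relevance collapses during B, but the end-of-B world
  value is sensitive to the body-capacity constant.
* Performance: ~3 ms per simulated movement (single CPU) after JIT warm-up;
  the first import of the kernels costs a few seconds of compilation.
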