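# Methods

## Model and conventions

The body is a tree of `N_B` rigid links joined by `n = N_B − 1` one-DoF
(revolute or prismatic) joints; link 0 is the floating base (the pelvis
in the human use case) with no parent joint, and joint `i` is the parent
joint of link `i` after a breadth-first topological re-indexing. Each
link carries a spatial inertia (mass, first moment, rotational inertia
at the link frame); a URDF-subset reader and a JSON dump cover model
I/O. Named frames (feet, sensors) attach rigidly to links.

All 6-vectors stack the **linear block first, then the angular block**,
matching the `(ȯ, ω)` / `(f, m)` pairing of the quantities being
fused. A transform `T = (R, o)` holds the child pose in the parent
frame; the motion adjoint is `X = [[R, S(o)R], [0, R]]` and the force
adjoint its inverse-transpose `X* = [[R, 0], [S(o)R, R]]` (power
invariance). Gravity defaults to `[0, 0, −9.81] m/s²` and is
configurable everywhere it enters.

The system configuration is `q = (q_b, s)` with `q_b` the base pose; the
system velocity `ν = (ᴵv_B, ṡ)` uses the *mixed* base velocity
`(ᴵȯ_B, ᴵω_B)` — the most natural representation for the quantities an
IMU suit exposes — with explicit converters to the body twist used
internally by the recursions.

## Two acceleration representations

The estimator works with the **proper sensor acceleration**
`α_g = (ᴸR_I (ᴵö_L − ᴵg), ᴸR_I ᴵω̇_L)`: the quantity an ideal
accelerometer + differentiated gyro pack mounted at the link frame
reads. It relates to the proper body acceleration `a_g` (derivative of
the body twist minus gravity) by a velocity product:

    α_g = a_g + w(v),   w(v) = (ω × v_lin, 0)

This identity follows from differentiating `v_lin = ᴸR_I ᴵȯ_L` with
`Ṙ = S(ω)R`; the sign of the correction is fixed by that derivation and
is verified in tests against both the inverse-dynamics oracle and a
finite-difference check. Because the gravity offset maps consistently
across links, `α_g` propagates down the tree with the same joint terms
as the true spatial acceleration:

    α_L = ᴸX_λ α_λ + S_J s̈_J + v_L × S_J ṡ_J + w(v_L) − ᴸX_λ w(v_λ)

and the Newton–Euler balance written in `α_g` absorbs all
linear-velocity products into the angular-only bias
`(0, ω) ×* M (0, ω)` (an algebraic identity, exercised by the
simulator-consistency tests). Link twists `v_L` are obtained by
propagating the estimated base velocity and joint rates, so every bias
term is computable from available kinematics.

## The stacked estimation problem

Per sample, the unknowns are

    d = [ α_0, 𝕗ˣ_0, …, α_{N_B−1}, 𝕗ˣ_{N_B−1} | 𝕗_1 … 𝕗_n | s̈_1 … s̈_n ]

of length `12 N_B + 7n` — torques are deliberately *not* unknowns; they
are read off the posterior joint wrenches as `τ_J = S_Jᵀ 𝕗_J`.

**Dynamics system** `D d + b_D = e_D`, 12 rows per link: six
acceleration-propagation rows and six Newton–Euler rows, sparse with the
tree's pattern. For the base link, which has no propagation equation,
the acceleration rows anchor `α_B` to its value computed from the base
kinematics (`w(v_B)` plus the known base proper acceleration). When no
base acceleration is available the anchor degrades to the quasi-static
`w(v_B)` alone, appropriate for near-static trials; the corresponding
`Σ_D` rows should then be inflated. In the pipeline the base
acceleration is produced by Savitzky–Golay differentiation of the
contact-derived base velocity, so the full anchor is always used.

**Measurement system** `Y d + b_Y = y`, one block per channel:

* `imu` (3 rows): an accelerometer triad at `(ᴸR_S, ᴸo_S)` on link L
  reads `ᔆR_L [(1 | −S(ᴸo_S)) α_L + (S(ω_L)² ᴸo_S, 0)]` — rigid-body
  transport of the proper sensor acceleration, derived from the same
  relation that drives the position calibration. Angular accelerations
  are *not* measured (gyro rates are used only through the bias terms);
  their information comes from the propagation rows.
* `ft` (6 rows): a force/torque sensor at model frame F on link L
  measures `ᶠX*_L 𝕗ˣ_L` — identity when the sensor frame coincides with
  the link frame.
* `joint_acc` (1 row): selects `s̈_J` (the differentiated joint-angle
  channel).
* `null_wrench` (6 rows): a zero pseudo-measurement on the external
  wrench of a link known to be contact-free. Without these the external
  wrenches of unsensed links are unobservable (only the balance rows and
  the weak prior touch them) and the posterior mean cannot reach the
  true solution even with perfect data; pinning known-zero contacts is
  the standard remedy in this family of stochastic inverse-dynamics
  estimators and is part of the default channel layout.

**Posterior.** With `e_D ~ N(0, Σ_D)`, `y | d ~ N(Yd + b_Y, Σ_y)` and
prior `d ~ N(μ_d, Σ_d)`, everything is jointly Gaussian and

    Σ_d|y = (Dᵀ Σ_D⁻¹ D + Σ_d⁻¹ + Yᵀ Σ_y⁻¹ Y)⁻¹
    μ_d|y = Σ_d|y (Yᵀ Σ_y⁻¹ (y − b_Y) − Dᵀ Σ_D⁻¹ b_D + Σ_d⁻¹ μ_d)

which is the standard Gaussian fusion of the dynamics constraint with
the prior (`Σ̄_D⁻¹ = Dᵀ Σ_D⁻¹ D + Σ_d⁻¹`, `μ̄_D = Σ̄_D (Σ_d⁻¹ μ_d −
Dᵀ Σ_D⁻¹ b_D)`) followed by conditioning on the measurements. Any
consistent fusion parameterisation yields the same posterior; this is
the canonical one.

### Covariances

All covariances are diagonal by default and are *variances per row*:

| quantity | default | meaning |
|---|---|---|
| `Σ_y` | 1e-4 per channel | sensor trust (lower = more trust) |
| `Σ_y` null-wrench | 1e-6 | near-certain zero contact |
| `Σ_D` | 1e-6 | model (rigid-body) trust |
| `Σ_d` | 1e+4, `μ_d = 0` | uninformative prior on d |

Lowering a channel's variance provably lowers that channel's posterior
residual (trust monotonicity, tested); the sensible operating range for
the sensor and model variances is 1e-6…1e-4.

### Numerics

The information matrix is assembled sparsely. Below 500 unknowns it is
densified and factorised by Cholesky — which doubles as the
positive-definiteness check; above, a sparse LU factorisation solves the
mean and selected covariance columns (torque variances need only the
6×6 joint-wrench blocks, obtained by solving for unit columns). The
whole-body scale (67 links, |d| = 1266) runs a sample in well under a
second this way. Samples are estimated independently; the only
cross-sample operations in the pipeline are the Savitzky–Golay
differentiations.

## Kinematics pipeline

* **Pairwise IK.** Each joint angle minimises the squared intrinsic-ZYX
  Euler-angle error between the measured and model parent-to-child
  rotations, subject to the joint limits (the Euler sequence is a
  package choice; the error metric family is fixed but the sequence is
  not). A coarse grid scan handles the multiple minima of large
  rotations, a bounded scalar minimisation refines, and near-ties break
  toward the previous sample's angle (mid-limits for the first sample).
  Prismatic joints are rejected: a relative orientation carries no
  information about a translation.
* **Differentiation.** `scipy.signal.savgol_filter`, order 3, default
  window 9 at 50 Hz, `mode="interp"` (one-sided polynomial fits at the
  edges). Exact on cubics; on a unit 1 Hz sinusoid the centered kernel's
  closed-form error amplitude is 1.03e-3, which the tests pin down via
  an independently derived Vandermonde kernel. The window length is a
  package default (only the polynomial order is dictated by the use
  case); widen it for smoother, laggier derivatives.
* **Base velocity.** Stance feet are treated as holonomically
  constrained to zero velocity. Single support solves the square 6×6
  system `J_b v = −J_s ṡ` directly (the mixed-representation `J_b` is
  unimodular, so conditioning is benign; an ill-conditioned or rank-
  deficient stack raises with the condition number). Double support
  solves the stacked 12×6 least-squares problem by orthogonal
  decomposition with rank tolerance 1e-8·σ_max.
* **Contact classification.** Per sample: double support if
  `|RF_fz − LF_fz| ≤ T`, else the larger channel wins. The self-tuned
  threshold is `scale · mean(RF_fz + LF_fz)`; with `scale = 1` the
  threshold is near body weight and labels almost everything double
  support, so the scale is exposed (0.5 is a practical value for gait)
  rather than hard-coding a tuning the method leaves open. No hysteresis
  by default; an optional minimum-duration filter exists but is off.

## Sensor-position calibration

Stacking the per-sample regressor rows and solving by SVD gives the
sensor offset; singular values below 1e-8·σ_max are treated as zero and
fewer than three surviving directions raises an unobservability error
naming the null direction(s). Samples with both |ω| and |ω̇| below
1e-3 are dropped — purely static rows carry no position information but
inject noise. The synthetic protocol (oscillation about two
non-parallel axes) is a package choice; any motion exciting three
independent directions works.

## What the synthetic generator does and does not emulate

`simulate_trajectory` anchors the active stance foot as the kinematic
root: joint sinusoids under a C² window (`sin⁴`) that freezes motion in
double support drive the rest of the tree, so stance switches happen at
rest and the zero-velocity contact constraint holds to machine
precision. All derivatives are analytic (product rule on the window),
never numeric, so ground-truth accelerations are exact and simulator
error cannot masquerade as estimator error. Stance wrenches are
computed to balance the whole-body momentum rate — uniquely in single
support, by minimum-norm allocation in the statically indeterminate
double support (any allocation is valid ground truth; minimum-norm is
reproducible). One consequence of the anchored design: double-support
phases are static. Measurements are the exact measurement model plus
i.i.d. Gaussian noise from a single seed.

Not emulated: soft-tissue artifact, sensor bias/drift, orientation
estimation error in the IMU suit's own fusion, foot rolling contact,
aerial phases. Passing tests therefore demonstrate correctness of the
estimation machinery under its stated noise model, not robustness to
the unmodelled error sources of real recordings.

The default test model is a 5-link biped (pelvis + two 2-link legs,
1–10 kg links, pitch-axis hips and knees) so the full pipeline runs in
seconds; a 67-link, 66-DoF builder exercises the production problem
size (|d| = 1266) with no physiological fidelity claimed. Acceptance
computations use 10 s at 50 Hz (500 samples) for the oracle-equivalence
check, 500-sample calibration trials, 100 Monte-Carlo replicates for
the consistency checks and 100 samples at the 67-link scale — sizes
chosen so each stage's property is measured well away from its
tolerance while the whole script stays around a minute.

## Known limitations

* The base-acceleration anchor row makes the estimator only as good as
  the differentiated base velocity on dynamic trials; a base IMU channel
  mitigates this (and is part of the default layout) but the anchor
  covariance is a real tuning knob on fast motions.
* Per-sample independence wastes the temporal smoothness of human
  motion by design (the method's contract); a smoother would change the
  posterior semantics.
* Contact classification assumes at least one foot is always loaded; no
  aerial phase, and no recovery of the base *position* drift.
* Double-support wrench ground truth is one member of the
  indeterminate set; estimators regularised differently can disagree on
  the wrench split while agreeing on torques.
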