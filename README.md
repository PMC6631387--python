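# mapdyn

Simultaneous floating-base estimation of whole-body human kinematics and
joint torques from wearable sensing.

## The problem

Joint torques cannot be measured on a human. In gait analysis,
ergonomics and physical human–robot interaction they must be *estimated*
by fusing what wearable sensors do provide — per-link accelerometer
readings and orientations from an IMU suit, ground-reaction wrenches
from force/torque-instrumented shoes, and joint accelerations obtained
by differentiating joint angles — with a rigid multi-body model of the
person. Fixing the model to the ground breaks down as soon as the
support foot changes (every gait cycle), so the estimator here treats
the pelvis as a *floating base* whose pose and 6-D velocity are
themselves recovered from the data, and the support switching is handled
by a contact classifier instead of by re-rooting the model.

`mapdyn` implements the full stack:

* **spatial / model / dynamics** — 6-D spatial-vector algebra, a
  URDF-subset reader for tree models of rigid links and one-DoF joints,
  and a recursive Newton–Euler inverse-dynamics oracle cross-checked
  against the assembled equations of motion
  `M(q) ν̇ + h(q, ν) = B τ + Σₖ J_Cₖᵀ 𝕗ₖˣ`;
* **calibration** — least-squares recovery of each sensor's position on
  its host link from spin trials, via the rigid-body regressor
  `(S(ω̇) + S(ω)²) R_L · ᴸo_S = R_S a_S − (ö_L − g)`;
* **kinematics** — per-joint angles from link-pairwise inverse
  kinematics on measured relative orientations, Savitzky–Golay joint
  velocities/accelerations, and the floating-base velocity as the
  least-squares solution of the stance-foot constraint
  `J_b ᴵv_B + J_s ṡ = 0` (single foot or the 12-row two-foot stack);
* **contact** — double/left/right support labels from the vertical shoe
  forces against a self-tuned threshold;
* **estimator** — the core: all per-sample unknowns are stacked in
  `d = [per-link (α_g, 𝕗ˣ) | per-joint 𝕗, s̈] ∈ R^{12N_B + 7n}`, the
  Newton–Euler and acceleration-propagation constraints become a linear
  system `D d + b_D = 0` and the sensors a second system
  `Y d + b_Y = y`; with Gaussian covariances Σ_D, Σ_y and a prior
  N(μ_d, Σ_d), the posterior is Gaussian with

      Σ_d|y = (Dᵀ Σ_D⁻¹ D + Σ_d⁻¹ + Yᵀ Σ_y⁻¹ Y)⁻¹
      μ_d|y = Σ_d|y (Yᵀ Σ_y⁻¹ (y − b_Y) − Dᵀ Σ_D⁻¹ b_D + Σ_d⁻¹ μ_d)

  and joint torques follow as the projection `τ_J = S_Jᵀ 𝕗_J` with
  variance `S_Jᵀ Σ(𝕗_J) S_J`;
* **synthetic** — a simulator producing rigid-body-consistent
  trajectories, sensor streams and exact ground truth (stance feet are
  anchored as the kinematic root, so contact constraints hold to machine
  precision), standing in for recordings that no public dataset
  provides.

## Worked example

Simulate a 2.8 s walking-like trial on the built-in 5-link biped
(pelvis + two 2-link legs), corrupt the sensor streams with realistic
noise, and run the estimator end to end:

```python
import numpy as np
from mapdyn import (TrajectorySpec, simulate_trajectory, make_biped_model,
                    default_channels, generate_measurements,
                    KinematicStreams, run_estimation, PriorConfig)

model = make_biped_model()
spec = TrajectorySpec(model, schedule=[("double", 0.4), ("right", 0.8),
                                       ("double", 0.4), ("left", 0.8),
                                       ("double", 0.4)], seed=3)
gt = simulate_trajectory(spec)                  # 140 samples at 50 Hz
channels = default_channels(model, ["RF", "LF"])
y = generate_measurements(gt, channels, noise_std=0.01, seed=1)

streams = KinematicStreams(gt.times, gt.s, gt.s_dot,
                           np.array([s.base_position for s in gt.states]),
                           np.array([s.base_rotation for s in gt.states]))
run = run_estimation(model, streams, y, channels, gt.contacts,
                     PriorConfig(sigma_D=1e-6, sigma_d=1e4))

rmse = np.sqrt(((run.tau - gt.tau) ** 2).mean(axis=0))
for j, joint in enumerate(model.joints):
    print(f"{joint.name:7s} tau RMSE {rmse[j]:6.4f} Nm   "
          f"mean posterior std {np.sqrt(run.tau_variance[:, j]).mean():6.4f} Nm")
```

Output:

```
hip_r   tau RMSE 0.3100 Nm   mean posterior std 0.0125 Nm
hip_l   tau RMSE 0.3188 Nm   mean posterior std 0.0125 Nm
knee_r  tau RMSE 0.2364 Nm   mean posterior std 0.0084 Nm
knee_l  tau RMSE 0.2638 Nm   mean posterior std 0.0083 Nm
```

The torque error of a few tenths of a N·m is dominated not by sensor
noise (which the posterior standard deviation reflects) but by the
Savitzky–Golay differentiation of the contact-derived base velocity —
the one numerically differentiated quantity in the pipeline. Feeding
the true base acceleration instead drops the error to the 1e-11 N·m
level (see the oracle-equivalence test).

The same pipeline is scriptable from the shell:

```bash
mapdyn simulate --out trial --seed 3 --noise-std 0.01
mapdyn classify --log trial/forces.csv --scale 0.5 --out trial/labels.csv
mapdyn estimate --model trial/model.json --joints trial/joints_true.csv \
    --base trial/base.csv --forces trial/forces.csv \
    --measurements trial/measurements.csv --out results
```

## Scope

Per-sample (no temporal smoothing), offline estimation with Gaussian
noise models; one-DoF revolute/prismatic joints in a tree topology.
Generating person-specific models from anthropometric tables, online
operation, and inertial-parameter identification are out of scope.
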