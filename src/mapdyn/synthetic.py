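"""Rigid-body-consistent synthetic trajectories, sensor streams and
ground truth.

No public recordings exist for the wearable-sensing experiments this
estimator targets, so every stage is exercised against simulated data:
joint trajectories are smooth analytic signals (differentiated in closed
form, never numerically), stance feet are *anchored* — the stance frame
is the kinematic root, so its velocity is exactly zero and the contact
constraint holds to machine precision — and contact wrenches are
computed to balance the whole-body dynamics (minimum-norm allocation in
double support, which is statically indeterminate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import DOUBLE, LEFT, RIGHT, ContactSet, VerticalForcePair
from .dynamics import (LinkKinematics, rerooted_kinematics,
                       rnea_from_kinematics, state_from_kinematics)
from .estimator import (DLayout, MeasurementChannel, build_measurement_system,
                        channel_variances)
from .model import Joint, Link, MultiBodyModel, SystemState
from .spatial import (GRAVITY, SpatialInertia, SpatialTransform, crf,
                      force_adjoint, rotation_about_axis)

# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _box_inertia(mass: float, lx: float, ly: float, lz: float) -> np.ndarray:
    return np.diag([mass / 12.0 * (ly ** 2 + lz ** 2),
                    mass / 12.0 * (lx ** 2 + lz ** 2),
                    mass / 12.0 * (lx ** 2 + ly ** 2)])


def make_chain_model(n_links: int, seed: int = 0,
                     prismatic_fraction: float = 0.2) -> MultiBodyModel:
    """Deterministic serial chain with mixed joint types and offsets."""
    rng = np.random.default_rng(seed)
    links, joints = [], []
    for i in range(n_links):
        mass = float(rng.uniform(1.0, 8.0))
        com = rng.normal(scale=0.05, size=3)
        links.append(Link(f"link{i}", SpatialInertia.from_com(
            mass, com, _box_inertia(mass, 0.1, 0.1, 0.3))))
        if i == 0:
            continue
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot_axis = rng.normal(size=3)
        rot_axis /= np.linalg.norm(rot_axis)
        origin = SpatialTransform(
            rotation_about_axis(rot_axis, rng.uniform(-np.pi, np.pi)),
            rng.normal(scale=0.2, size=3))
        kind = "prismatic" if rng.random() < prismatic_fraction else "revolute"
        joints.append(Joint(f"joint{i}", f"link{i - 1}", f"link{i}", kind,
                            axis, origin, (-1.5, 1.5)))
    return MultiBodyModel(links, joints)


def make_biped_model() -> MultiBodyModel:
    """Default test model: pelvis base plus two 2-link legs (5 links).

    Link masses are desk-scale (1-10 kg); hips and knees are revolute
    about the pitch (y) axis; foot frames ``RF``/``LF`` sit at the distal
    end of each shank.  No physiological fidelity is claimed — the model
    exists so that the full pipeline runs in seconds.
    """
    pelvis = Link("pelvis", SpatialInertia.from_com(
        9.0, [0.0, 0.0, 0.05], _box_inertia(9.0, 0.25, 0.3, 0.15)))
    links = [pelvis]
    joints = []
    for side, sign in (("r", -1.0), ("l", 1.0)):
        thigh = Link(f"thigh_{side}", SpatialInertia.from_com(
            6.0, [0.0, 0.0, -0.2], _box_inertia(6.0, 0.12, 0.12, 0.4)))
        shank = Link(f"shank_{side}", SpatialInertia.from_com(
            3.0, [0.0, 0.0, -0.2], _box_inertia(3.0, 0.08, 0.08, 0.4)))
        links += [thigh, shank]
        joints.append(Joint(f"hip_{side}", "pelvis", f"thigh_{side}",
                            "revolute", [0.0, 1.0, 0.0],
                            SpatialTransform(np.eye(3), [0.0, sign * 0.12,
                                                         0.0]),
                            (-1.4, 1.4)))
        joints.append(Joint(f"knee_{side}", f"thigh_{side}", f"shank_{side}",
                            "revolute", [0.0, 1.0, 0.0],
                            SpatialTransform(np.eye(3), [0.0, 0.0, -0.4]),
                            (-2.2, 1.0)))
    model = MultiBodyModel(links, joints)
    model.add_frame("RF", "shank_r", SpatialTransform(np.eye(3),
                                                      [0.0, 0.0, -0.42]))
    model.add_frame("LF", "shank_l", SpatialTransform(np.eye(3),
                                                      [0.0, 0.0, -0.42]))
    return model


def make_humanoid_scale_model(n_links: int = 67, seed: int = 7
                              ) -> MultiBodyModel:
    """Branching tree at the scale of a whole-body human model.

    Used only to exercise the estimator at its production problem size
    (|d| = 12*67 + 7*66 = 1266); link properties are plausible in
    magnitude but carry no anthropometric meaning.
    """
    rng = np.random.default_rng(seed)
    links = [Link("link0", SpatialInertia.from_com(
        10.0, [0, 0, 0.03], _box_inertia(10.0, 0.2, 0.3, 0.2)))]
    joints = []
    for i in range(1, n_links):
        mass = float(rng.uniform(0.3, 4.0))
        links.append(Link(f"link{i}", SpatialInertia.from_com(
            mass, rng.normal(scale=0.02, size=3),
            _box_inertia(mass, 0.06, 0.06, 0.2))))
        parent = int(rng.integers(max(0, i - 6), i))  # shallow branching
        axis = np.zeros(3)
        axis[int(rng.integers(3))] = 1.0
        joints.append(Joint(f"joint{i}", f"link{parent}", f"link{i}",
                            "revolute", axis,
                            SpatialTransform(np.eye(3),
                                             rng.normal(scale=0.1, size=3)),
                            (-1.5, 1.5)))
    model = MultiBodyModel(links, joints)
    leaves = [i for i in range(n_links) if not model.children(i)]
    model.add_frame("RF", model.links[leaves[0]].name,
                    SpatialTransform(np.eye(3), [0, 0, -0.1]))
    model.add_frame("LF", model.links[leaves[-1]].name,
                    SpatialTransform(np.eye(3), [0, 0, -0.1]))
    return model


# ---------------------------------------------------------------------------
# trajectory specification and simulation
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySpec:
    """What to simulate.

    ``schedule`` is a list of ``(label, duration_s)`` segments with labels
    ``double`` / ``right`` / ``left``; joints oscillate sinusoidally
    inside single-support segments under a C^2 window that freezes all
    motion in double support, so stance switches happen at rest and the
    anchored-foot constraint stays exact.  Joint parameters default to
    seeded values inside the joint limits.
    """

    model: MultiBodyModel
    schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [(DOUBLE, 1.0)])
    rate: float = 50.0
    seed: int = 0
    amplitude: np.ndarray | None = None       # [rad]
    frequency: np.ndarray | None = None       # [Hz]
    phase: np.ndarray | None = None
    offset: np.ndarray | None = None
    right_frame: str = "RF"
    left_frame: str = "LF"
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())

    def __post_init__(self):
        n = self.model.n_joints
        rng = np.random.default_rng(self.seed)
        limits = self.model.joint_limits() if n else np.zeros((0, 2))
        lo = np.clip(limits[:, 0], -np.pi, None)
        hi = np.clip(limits[:, 1], None, np.pi)
        if self.offset is None:
            self.offset = 0.5 * (lo + hi)
        if self.amplitude is None:
            self.amplitude = 0.3 * np.minimum(hi - self.offset,
                                              self.offset - lo)
        if self.frequency is None:
            self.frequency = rng.uniform(0.5, 1.5, n)
        if self.phase is None:
            self.phase = rng.uniform(0.0, 2.0 * np.pi, n)
        for name in ("amplitude", "frequency", "phase", "offset"):
            setattr(self, name,
                    np.broadcast_to(np.asarray(getattr(self, name), float),
                                    (n,)).copy())
        labels = [seg[0] for seg in self.schedule]
        for a, b in zip(labels, labels[1:]):
            if a != DOUBLE and b != DOUBLE and a != b:
                raise ValueError(
                    "inconsistent schedule: single-support segments "
                    f"{a!r} -> {b!r} must be separated by double support")


def _window(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C^2 bump sin^4(pi u) with value and two derivatives w.r.t. u."""
    s, c = np.sin(np.pi * u), np.cos(np.pi * u)
    b = s ** 4
    db = 4.0 * np.pi * s ** 3 * c
    ddb = 4.0 * np.pi ** 2 * s ** 2 * (3.0 * c ** 2 - s ** 2)
    return b, db, ddb


@dataclass
class GroundTruth:
    """Simulated trial with every quantity the estimator could want."""

    model: MultiBodyModel
    times: np.ndarray
    states: list[SystemState]
    kinematics: list[LinkKinematics]
    contacts: ContactSet
    d: np.ndarray                       # (T, 12 N_B + 7 n)
    tau: np.ndarray                     # (T, n)
    ext_wrenches: np.ndarray            # (T, N_B, 6) link frames
    balance_residual: np.ndarray        # (T,) max |base residual|

    def __len__(self) -> int:
        return self.times.size

    @property
    def s(self) -> np.ndarray:
        return np.array([st.s for st in self.states])

    @property
    def s_dot(self) -> np.ndarray:
        return np.array([st.s_dot for st in self.states])

    @property
    def s_ddot(self) -> np.ndarray:
        return np.array([st.s_ddot for st in self.states])


def _segment_table(spec: TrajectorySpec) -> list[tuple[str, float, float]]:
    table, t0 = [], 0.0
    for label, dur in spec.schedule:
        table.append((label, t0, t0 + dur))
        t0 += dur
    return table


def _joint_signals(spec: TrajectorySpec, t: float,
                   segments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = spec.model.n_joints
    for label, t0, t1 in segments:
        if t0 <= t < t1 or (t == t1 == segments[-1][2]):
            if label == DOUBLE:
                return spec.offset.copy(), np.zeros(n), np.zeros(n)
            dur = t1 - t0
            u = (t - t0) / dur
            b, db, ddb = _window(np.array(u))
            th = 2.0 * np.pi * spec.frequency * (t - t0) + spec.phase
            thd = 2.0 * np.pi * spec.frequency
            A = spec.amplitude
            s = spec.offset + A * np.sin(th) * b
            sd = A * (thd * np.cos(th) * b + np.sin(th) * db / dur)
            sdd = A * (-thd ** 2 * np.sin(th) * b
                       + 2.0 * thd * np.cos(th) * db / dur
                       + np.sin(th) * ddb / dur ** 2)
            return s, sd, sdd
    raise ValueError(f"time {t} outside the schedule")


def _allocate_contacts(model: MultiBodyModel, kin: LinkKinematics,
                       frames: list[str]) -> np.ndarray:
    """External wrenches (link frames) balancing the whole-body motion.

    Solves the base balance for the stance wrenches: unique in single
    support, minimum-norm in double support.
    """
    NB = model.n_links
    ext = np.zeros((NB, 6))
    free = rnea_from_kinematics(model, kin, ext)
    needed = free.base_residual                   # base frame
    T0 = kin.poses[0].inverse()
    blocks = []
    hosts = []
    for f in frames:
        link, T_LF = model.resolve_frame(f)
        T_0F = T0.compose(kin.poses[link]).compose(T_LF)
        blocks.append(force_adjoint(T_0F))
        hosts.append((link, T_LF))
    A = np.hstack(blocks)
    if A.shape[1] == 6:
        fc = np.linalg.solve(A, needed)
    else:
        fc = np.linalg.pinv(A) @ needed
    for k, (link, T_LF) in enumerate(hosts):
        ext[link] += force_adjoint(T_LF) @ fc[6 * k:6 * k + 6]
    return ext


def simulate_trajectory(spec: TrajectorySpec) -> GroundTruth:
    """Simulate a stance-anchored trial and assemble its ground truth.

    The active stance foot is the kinematic root: joint trajectories
    drive the rest of the tree (floating base included) so the contact
    constraint is satisfied exactly.  External wrenches at the stance
    feet balance the Newton–Euler equations; the returned ``d`` satisfies
    the stacked dynamics system to machine precision at every sample.
    """
    model = spec.model
    segments = _segment_table(spec)
    T = int(round(segments[-1][2] * spec.rate))
    times = np.arange(T) / spec.rate
    layout = DLayout(model)
    frames_of = {DOUBLE: [spec.right_frame, spec.left_frame],
                 RIGHT: [spec.right_frame], LEFT: [spec.left_frame]}

    # initial anchor: stance frame pose computed with the base at identity
    first_anchor = frames_of[segments[0][0]][0]
    s0, _, _ = _joint_signals(spec, 0.0, segments)
    ref = SystemState(np.zeros(3), np.eye(3), s0)
    from .dynamics import frame_pose
    anchor_frame = first_anchor
    anchor_pose = frame_pose(model, ref, anchor_frame)

    states, kins, labels = [], [], []
    NB, n = model.n_links, model.n_joints
    d = np.zeros((T, layout.size))
    tau = np.zeros((T, n))
    ext_all = np.zeros((T, NB, 6))
    resid = np.zeros(T)
    prev_kin: LinkKinematics | None = None
    for t_idx, t in enumerate(times):
        label = next(l for l, t0, t1 in segments
                     if t0 <= t < t1 or t1 == segments[-1][2])
        frames = frames_of[label]
        if anchor_frame not in frames:
            # stance switch: re-anchor on the (currently static) new foot
            new_anchor = frames[0]
            link, T_LF = model.resolve_frame(new_anchor)
            anchor_pose = prev_kin.poses[link].compose(T_LF)
            anchor_frame = new_anchor
        s, sd, sdd = _joint_signals(spec, t, segments)
        kin = rerooted_kinematics(model, anchor_frame, anchor_pose,
                                  s, sd, sdd, spec.gravity)
        state = state_from_kinematics(model, kin, s, sd, sdd, spec.gravity)
        ext = _allocate_contacts(model, kin, frames)
        res = rnea_from_kinematics(model, kin, ext)
        d[t_idx] = layout.pack(kin.alpha_g, ext, res.joint_wrenches, sdd)
        tau[t_idx] = res.tau
        ext_all[t_idx] = ext
        resid[t_idx] = np.abs(res.base_residual).max()
        states.append(state)
        kins.append(kin)
        labels.append(label)
        prev_kin = kin
    contacts = ContactSet(np.array(labels, dtype=object),
                          spec.right_frame, spec.left_frame)
    return GroundTruth(model, times, states, kins, contacts, d, tau,
                       ext_all, resid)


def simulate_free_floating(model: MultiBodyModel, duration: float = 1.0,
                           rate: float = 50.0, seed: int = 0,
                           gravity: np.ndarray = GRAVITY,
                           free_fall: bool = False) -> GroundTruth:
    """Free (unconstrained) motion: analytic base trajectory, sinusoidal
    joints; whatever wrench the motion requires is applied to the base as
    an external wrench so the ground truth stays dynamically consistent.
    With ``free_fall=True`` the body instead falls rigidly under gravity
    (frozen joints, base acceleration = g): no wrench is required
    anywhere, so all external and joint wrenches vanish.
    """
    rng = np.random.default_rng(seed)
    n = model.n_joints
    T = int(round(duration * rate))
    times = np.arange(T) / rate
    layout = DLayout(model)

    amp_p = rng.uniform(0.05, 0.2, 3)
    f_p = rng.uniform(0.3, 0.8, 3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    amp_th, f_th = rng.uniform(0.2, 0.6), rng.uniform(0.3, 0.8)
    limits = model.joint_limits() if n else np.zeros((0, 2))
    off = 0.5 * (np.clip(limits[:, 0], -np.pi, None)
                 + np.clip(limits[:, 1], None, np.pi))
    amp = 0.3 * (np.clip(limits[:, 1], None, np.pi) - off)
    f_j = rng.uniform(0.5, 1.5, n)
    ph = rng.uniform(0, 2 * np.pi, n)
    if free_fall:
        amp_p = np.zeros(3)
        amp_th = 0.0
        amp = np.zeros(n)

    from .dynamics import link_kinematics
    states, kins, labels = [], [], []
    d = np.zeros((T, layout.size))
    tau = np.zeros((T, n))
    ext_all = np.zeros((T, model.n_links, 6))
    for ti, t in enumerate(times):
        wp = 2 * np.pi * f_p
        pos = amp_p * np.sin(wp * t)
        vel = amp_p * wp * np.cos(wp * t)
        acc = -amp_p * wp ** 2 * np.sin(wp * t)
        if free_fall:
            pos = 0.5 * gravity * t ** 2
            vel = gravity * t
            acc = gravity.copy()
        wth = 2 * np.pi * f_th
        th, thd, thdd = (amp_th * np.sin(wth * t), amp_th * wth
                         * np.cos(wth * t), -amp_th * wth ** 2
                         * np.sin(wth * t))
        R = rotation_about_axis(axis, th)
        wj = 2 * np.pi * f_j
        s = off + amp * np.sin(wj * t + ph)
        sd = amp * wj * np.cos(wj * t + ph)
        sdd = -amp * wj ** 2 * np.sin(wj * t + ph)
        state = SystemState(pos, R, s,
                            base_velocity=np.concatenate([vel, axis * thd]),
                            s_dot=sd,
                            base_acceleration=np.concatenate(
                                [acc, axis * thdd]),
                            s_ddot=sdd)
        kin = link_kinematics(model, state, gravity)
        res0 = rnea_from_kinematics(model, kin,
                                    np.zeros((model.n_links, 6)))
        ext = np.zeros((model.n_links, 6))
        ext[0] = res0.base_residual
        d[ti] = layout.pack(kin.alpha_g, ext, res0.joint_wrenches, sdd)
        tau[ti] = res0.tau
        ext_all[ti] = ext
        states.append(state)
        kins.append(kin)
        labels.append(DOUBLE)
    contacts = ContactSet(np.array(labels, dtype=object))
    return GroundTruth(model, times, states, kins, contacts, d, tau,
                       ext_all, np.zeros(T))


# ---------------------------------------------------------------------------
# measurement generation
# ---------------------------------------------------------------------------


def default_channels(model: MultiBodyModel, contact_frames: list[str],
                     imu_variance: float = 1e-4,
                     ft_variance: float = 1e-4,
                     joint_acc_variance: float = 1e-4,
                     null_wrench_variance: float = 1e-6,
                     imu_mounts: dict[str, SpatialTransform] | None = None
                     ) -> list[MeasurementChannel]:
    """The sensor layout the experiments emulate: one accelerometer per
    link, a 6-axis FT sensor per contact frame, a differentiated
    acceleration channel per joint, and zero-wrench pseudo-measurements
    on every link that hosts no contact frame."""
    imu_mounts = imu_mounts or {}
    contact_links = {model.resolve_frame(f)[0] for f in contact_frames}
    channels = []
    for i, link in enumerate(model.links):
        channels.append(MeasurementChannel(
            "imu", link.name, imu_variance,
            imu_mounts.get(link.name, SpatialTransform.identity())))
    for f in contact_frames:
        channels.append(MeasurementChannel("ft", f, ft_variance))
    for j in model.joints:
        channels.append(MeasurementChannel("joint_acc", j.child,
                                           joint_acc_variance))
    for i, link in enumerate(model.links):
        if i not in contact_links:
            channels.append(MeasurementChannel("null_wrench", link.name,
                                               null_wrench_variance))
    return channels


def generate_measurements(gt: GroundTruth,
                          channels: list[MeasurementChannel],
                          noise_std: float | np.ndarray = 0.0,
                          seed: int = 0) -> np.ndarray:
    """Sensor streams from the ground truth: ``y_t = Y d_t + b_Y`` plus
    i.i.d. zero-mean Gaussian noise (per-row std, scalar broadcast).
    ``noise_std=0`` reproduces the measurement model exactly; identical
    seeds give identical streams."""
    rng = np.random.default_rng(seed)
    m = sum(c.n_rows for c in channels)
    noise_std = np.broadcast_to(np.asarray(noise_std, float), (m,))
    if np.any(noise_std < 0):
        raise ValueError("noise_std must be non-negative")
    y = np.zeros((len(gt), m))
    for t in range(len(gt)):
        Y, b_Y = build_measurement_system(gt.model, channels, gt.states[t])
        y[t] = Y @ gt.d[t] + b_Y
    y += rng.normal(size=y.shape) * noise_std
    return y


def matched_noise_std(channels: list[MeasurementChannel]) -> np.ndarray:
    """Per-row noise std equal to the square root of each channel's
    configured variance (noise matched to the assumed covariance)."""
    return np.sqrt(channel_variances(channels))


# ---------------------------------------------------------------------------
# sensor-position calibration fixture
# ---------------------------------------------------------------------------


def generate_calibration_trial(offset, n_samples: int = 500,
                               seed: int = 0, noise_std: float = 0.0,
                               axes=((0.0, 0.0, 1.0), (1.0, 0.0, 0.0)),
                               spin_amplitude: float = 1.5,
                               spin_frequency: float = 1.0,
                               rate: float = 50.0,
                               gravity: np.ndarray = GRAVITY) -> list:
    """Calibration samples from a link spinning about two axes in turn.

    The host link oscillates about ``axes[0]`` for the first half of the
    trial and ``axes[1]`` for the second (link origin pinned), and the
    accelerometer reading is forward-generated from the rigid-body
    transport of the true sensor offset.  Gaussian noise of std
    ``noise_std`` [m/s^2] is added to the accelerometer channel only.
    """
    from .calibration import CalibrationSample
    from .spatial import skew

    offset = np.asarray(offset, float).reshape(3)
    rng = np.random.default_rng(seed)
    R_LS = rotation_about_axis(np.array([0.0, 1.0, 0.0]), 0.3)
    samples = []
    for k in range(n_samples):
        t = k / rate
        axis = np.asarray(axes[0] if k < n_samples // 2 else axes[1], float)
        axis = axis / np.linalg.norm(axis)
        w = 2.0 * np.pi * spin_frequency
        theta = spin_amplitude * np.sin(w * t)
        theta_d = spin_amplitude * w * np.cos(w * t)
        theta_dd = -spin_amplitude * w ** 2 * np.sin(w * t)
        R_L = rotation_about_axis(axis, theta)
        omega = axis * theta_d
        omega_dot = axis * theta_dd
        R_S = R_L @ R_LS
        o_world = R_L @ offset
        o_ddot_S = (skew(omega_dot) + skew(omega) @ skew(omega)) @ o_world
        a_S = R_S.T @ (o_ddot_S - gravity)
        a_S = a_S + rng.normal(scale=noise_std, size=3) if noise_std else a_S
        samples.append(CalibrationSample(a_S, omega, omega_dot, R_L, R_S,
                                         np.zeros(3)))
    return samples


# ---------------------------------------------------------------------------
# gait force fixture
# ---------------------------------------------------------------------------


def generate_gait_forces(schedule: list[tuple[str, float]],
                         body_weight: float = 700.0,
                         transition_time: float = 0.2,
                         rate: float = 50.0
                         ) -> tuple[np.ndarray, VerticalForcePair, ContactSet]:
    """Trapezoidal vertical-force traces for a stance schedule.

    Plateaus put the full weight on the stance foot (or half per foot in
    double support) with linear ramps of ``transition_time`` seconds at
    each segment change.  Returns (times, forces, true labels from the
    schedule) for validating the contact classifier.
    """
    share = {DOUBLE: (0.5, 0.5), RIGHT: (1.0, 0.0), LEFT: (0.0, 1.0)}
    labels_seq = [seg[0] for seg in schedule]
    for a, b in zip(labels_seq, labels_seq[1:]):
        if a != DOUBLE and b != DOUBLE and a != b:
            raise ValueError("inconsistent schedule: opposite single "
                             "supports must be separated by double support")
    total = sum(dur for _, dur in schedule)
    T = int(round(total * rate))
    times = np.arange(T) / rate
    rf = np.zeros(T)
    lf = np.zeros(T)
    labels = np.empty(T, dtype=object)
    t0 = 0.0
    prev_share = share[schedule[0][0]]
    for label, dur in schedule:
        t1 = t0 + dur
        mask = (times >= t0) & (times < t1 - 1e-12)
        tgt = share[label]
        tt = times[mask] - t0
        ramp = np.clip(tt / transition_time, 0.0, 1.0) if transition_time > 0 \
            else np.ones_like(tt)
        rf[mask] = body_weight * (prev_share[0]
                                  + (tgt[0] - prev_share[0]) * ramp)
        lf[mask] = body_weight * (prev_share[1]
                                  + (tgt[1] - prev_share[1]) * ramp)
        labels[mask] = label
        prev_share = tgt
        t0 = t1
    return times, VerticalForcePair(rf, lf), ContactSet(labels)
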