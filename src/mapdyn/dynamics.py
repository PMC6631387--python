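"""Forward kinematics, recursive Newton–Euler dynamics and mass matrix.

All per-link quantities are expressed in **body (link) frames** with the
(linear, angular) block ordering of :mod:`mapdyn.spatial`.  The system
velocity exposed by :class:`~mapdyn.model.SystemState` carries the mixed
base velocity ``(I_odot_B, I_w_B)``; conversion helpers below move
between the mixed and body representations.

Two acceleration representations appear throughout:

* the **proper body acceleration** ``a_g``: time derivative of the
  body-frame twist, minus gravity re-expressed in the link frame;
* the **proper sensor acceleration** ``alpha_g``: the quantity an ideal
  accelerometer/gyro pack rigidly mounted at the link frame reads —
  linear part ``L_R_I (I_oddot_L - I_g)``, angular part ``L_R_I I_wdot_L``.

They differ by a velocity product term::

    alpha_g = a_g + w(v),     w(v) = (omega x v_lin, 0)

which follows from differentiating ``v_lin = L_R_I I_odot_L``.  Both
propagate down the tree with the same joint terms because the gravity
offset is rotation-consistent across links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelError, MultiBodyModel, SystemState
from .spatial import (GRAVITY, SpatialTransform, crf, crm, force_adjoint,
                      motion_adjoint, rotation_adjoint, skew)

# ---------------------------------------------------------------------------
# velocity representation conversions
# ---------------------------------------------------------------------------


def mixed_to_body(base_rotation: np.ndarray, v_mixed: np.ndarray) -> np.ndarray:
    """Mixed base velocity (inertial coords) -> body twist (base coords)."""
    R = base_rotation
    return np.concatenate([R.T @ v_mixed[:3], R.T @ v_mixed[3:]])


def body_to_mixed(base_rotation: np.ndarray, v_body: np.ndarray) -> np.ndarray:
    R = base_rotation
    return np.concatenate([R @ v_body[:3], R @ v_body[3:]])


def mixed_accel_to_body(base_rotation: np.ndarray, v_mixed: np.ndarray,
                        a_mixed: np.ndarray) -> np.ndarray:
    """Derivative of the mixed velocity -> derivative of the body twist.

    With ``v_lin = R^T I_odot`` and ``R_dot = S(I_w) R``::

        a_body = ( R^T I_oddot - w_body x v_lin_body,  R^T I_wdot )
    """
    R = base_rotation
    vb = mixed_to_body(R, v_mixed)
    return np.concatenate([
        R.T @ a_mixed[:3] - np.cross(vb[3:], vb[:3]),
        R.T @ a_mixed[3:],
    ])


def body_accel_to_mixed(base_rotation: np.ndarray, v_body: np.ndarray,
                        a_body: np.ndarray) -> np.ndarray:
    R = base_rotation
    return np.concatenate([
        R @ (a_body[:3] + np.cross(v_body[3:], v_body[:3])),
        R @ a_body[3:],
    ])


def sensor_from_body_accel(a_g: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper body acceleration -> proper sensor acceleration."""
    out = np.array(a_g, dtype=float)
    out[:3] += np.cross(v[3:], v[:3])
    return out


def body_from_sensor_accel(alpha_g: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper sensor acceleration -> proper body acceleration (inverse)."""
    out = np.array(alpha_g, dtype=float)
    out[:3] -= np.cross(v[3:], v[:3])
    return out


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def link_poses(model: MultiBodyModel, state: SystemState
               ) -> list[SpatialTransform]:
    """Inertial pose I_T_L of every link."""
    state.check_dims(model)
    poses = [SpatialTransform(state.base_rotation, state.base_position)]
    poses += [None] * (model.n_links - 1)
    for i in range(1, model.n_links):
        joint = model.joint_of(i)
        poses[i] = poses[model.parent(i)].compose(joint.child_pose(
            state.s[i - 1]))
    return poses


def frame_pose(model: MultiBodyModel, state: SystemState,
               frame: str) -> SpatialTransform:
    link, T = model.resolve_frame(frame)
    return link_poses(model, state)[link].compose(T)


@dataclass
class LinkKinematics:
    """Per-link body-frame kinematics of the whole tree.

    ``v`` are body twists, ``a_g`` proper body accelerations and
    ``alpha_g`` proper sensor accelerations, one row per link.
    """

    poses: list[SpatialTransform]
    v: np.ndarray
    a_g: np.ndarray

    @property
    def alpha_g(self) -> np.ndarray:
        out = np.array(self.a_g)
        out[:, :3] += np.cross(self.v[:, 3:], self.v[:, :3])
        return out


def link_kinematics(model: MultiBodyModel, state: SystemState,
                    gravity: np.ndarray = GRAVITY) -> LinkKinematics:
    """Propagate twists and proper accelerations from the base outwards.

    Requires a full state (velocity and acceleration).
    """
    poses = link_poses(model, state)
    NB = model.n_links
    v = np.zeros((NB, 6))
    a = np.zeros((NB, 6))
    R0 = state.base_rotation
    v[0] = mixed_to_body(R0, state.base_velocity)
    a0 = mixed_accel_to_body(R0, state.base_velocity, state.nu_dot[:6])
    a[0] = a0 - np.concatenate([R0.T @ gravity, np.zeros(3)])
    for i in range(1, NB):
        joint = model.joint_of(i)
        p = model.parent(i)
        X = motion_adjoint(joint.child_pose(state.s[i - 1]).inverse())
        S = joint.motion_subspace
        v[i] = X @ v[p] + S * state.s_dot[i - 1]
        a[i] = (X @ a[p] + S * state.s_ddot[i - 1]
                + crm(v[i]) @ (S * state.s_dot[i - 1]))
    return LinkKinematics(poses, v, a)


def rerooted_kinematics(model: MultiBodyModel, anchor: str,
                        anchor_pose: SpatialTransform,
                        s: np.ndarray, s_dot: np.ndarray, s_ddot: np.ndarray,
                        gravity: np.ndarray = GRAVITY) -> LinkKinematics:
    """Whole-tree kinematics with a named frame held fixed in the world.

    The anchor frame has zero twist and zero spatial acceleration (its
    proper acceleration is the pure gravity offset); joint trajectories
    drive every other link, including the floating base.  This is how the
    synthetic generator builds stance-foot-consistent motion: the contact
    constraint holds exactly by construction.
    """
    host, T_LF = model.resolve_frame(anchor)
    NB = model.n_links
    poses: list[SpatialTransform | None] = [None] * NB
    v = np.zeros((NB, 6))
    a = np.zeros((NB, 6))  # proper body accelerations a_g
    poses[host] = anchor_pose.compose(T_LF.inverse())
    a[host, :3] = -(poses[host].rotation.T @ gravity)

    seen = [False] * NB
    seen[host] = True
    stack = [host]
    while stack:
        cur = stack.pop()
        neighbours = model.children(cur)
        if model.parent(cur) >= 0:
            neighbours.append(model.parent(cur))
        for nxt in neighbours:
            if seen[nxt]:
                continue
            seen[nxt] = True
            if model.parent(nxt) == cur:          # forward edge cur -> child
                j = model.joint_of(nxt)
                idx = nxt - 1
                T = j.child_pose(s[idx])
                X = motion_adjoint(T.inverse())
                S = j.motion_subspace
                poses[nxt] = poses[cur].compose(T)
                v[nxt] = X @ v[cur] + S * s_dot[idx]
                a[nxt] = (X @ a[cur] + S * s_ddot[idx]
                          + crm(v[nxt]) @ (S * s_dot[idx]))
            else:                                  # reverse edge cur -> parent
                j = model.joint_of(cur)
                idx = cur - 1
                T = j.child_pose(s[idx])
                Xup = motion_adjoint(T)
                S = j.motion_subspace
                poses[nxt] = poses[cur].compose(T.inverse())
                v[nxt] = Xup @ (v[cur] - S * s_dot[idx])
                a[nxt] = Xup @ (a[cur] - S * s_ddot[idx]
                                - crm(v[cur]) @ (S * s_dot[idx]))
            stack.append(nxt)
    return LinkKinematics(poses, v, a)


def state_from_kinematics(model: MultiBodyModel, kin: LinkKinematics,
                          s, s_dot, s_ddot,
                          gravity: np.ndarray = GRAVITY) -> SystemState:
    """Recover a full :class:`SystemState` from per-link kinematics."""
    R0 = kin.poses[0].rotation
    v0 = kin.v[0]
    a0 = kin.a_g[0] + np.concatenate([R0.T @ gravity, np.zeros(3)])
    return SystemState(
        base_position=kin.poses[0].origin,
        base_rotation=R0,
        s=s, s_dot=s_dot, s_ddot=s_ddot,
        base_velocity=body_to_mixed(R0, v0),
        base_acceleration=body_accel_to_mixed(R0, v0, a0),
    )


# ---------------------------------------------------------------------------
# recursive Newton–Euler and mass matrix
# ---------------------------------------------------------------------------


@dataclass
class RneaResult:
    """Inverse-dynamics result.

    ``tau`` joint torques [N m or N]; ``joint_wrenches`` the wrench each
    parent transmits to its child through the joint, in the child frame
    (row ``i-1`` for joint ``i``); ``base_residual`` the net wrench (base
    frame) left unbalanced at the floating base — zero iff the supplied
    external wrenches are consistent with the motion.
    """

    tau: np.ndarray
    joint_wrenches: np.ndarray
    base_residual: np.ndarray


def _net_wrenches(model: MultiBodyModel, kin: LinkKinematics) -> np.ndarray:
    """Per-link momentum rate: M a_g + v x* (M v), in link frames."""
    NB = model.n_links
    phi = np.zeros((NB, 6))
    for i in range(NB):
        M = model.links[i].inertia.matrix()
        phi[i] = M @ kin.a_g[i] + crf(kin.v[i]) @ (M @ kin.v[i])
    return phi


def _backward_pass(model: MultiBodyModel, kin: LinkKinematics,
                   external: np.ndarray) -> RneaResult:
    NB, n = model.n_links, model.n_joints
    phi = _net_wrenches(model, kin)
    f = np.zeros((NB, 6))           # wrench through the parent joint of link i
    tau = np.zeros(n)
    for i in range(NB - 1, 0, -1):
        joint = model.joint_of(i)
        total = phi[i] - external[i]
        for c in model.children(i):
            total += force_adjoint(_child_T(model, kin, c)) @ f[c]
        f[i] = total
        tau[i - 1] = joint.motion_subspace @ f[i]
    residual = phi[0] - external[0]
    for c in model.children(0):
        residual += force_adjoint(_child_T(model, kin, c)) @ f[c]
    return RneaResult(tau, f[1:], residual)


def _child_T(model: MultiBodyModel, kin: LinkKinematics,
             child: int) -> SpatialTransform:
    """Parent-to-child transform recovered from world poses."""
    return kin.poses[model.parent(child)].inverse().compose(kin.poses[child])


def rnea(model: MultiBodyModel, state: SystemState,
         external_wrenches: np.ndarray | None = None,
         gravity: np.ndarray = GRAVITY) -> RneaResult:
    """Recursive Newton–Euler inverse dynamics for the floating base tree.

    Parameters
    ----------
    external_wrenches : (N_B, 6) array, optional
        Wrench the environment applies to each link, expressed in the
        link's own frame.  Defaults to zero.

    Returns the joint torques, the internal joint wrenches and the base
    residual (see :class:`RneaResult`).  This is the ground-truth oracle
    the MAP estimator is validated against.
    """
    state.check_dims(model)
    if external_wrenches is None:
        external_wrenches = np.zeros((model.n_links, 6))
    external_wrenches = np.asarray(external_wrenches, float)
    if external_wrenches.shape != (model.n_links, 6):
        raise ModelError("external_wrenches must be (N_B, 6)")
    kin = link_kinematics(model, state, gravity)
    return _backward_pass(model, kin, external_wrenches)


def rnea_from_kinematics(model: MultiBodyModel, kin: LinkKinematics,
                         external_wrenches: np.ndarray) -> RneaResult:
    """Backward Newton–Euler pass on precomputed link kinematics."""
    return _backward_pass(model, kin, np.asarray(external_wrenches, float))


def crba(model: MultiBodyModel, state: SystemState) -> np.ndarray:
    """Composite-rigid-body mass matrix in body coordinates.

    Coordinates are ``nu_body = (base body twist, s_dot)``; the matrix is
    symmetric positive definite.  Implemented independently of the RNEA
    recursion so the two can cross-check each other.
    """
    state.check_dims(model)
    NB, n = model.n_links, model.n_joints
    # parent-to-child transforms at the current configuration
    T_up = [None] * NB
    for i in range(1, NB):
        T_up[i] = model.joint_of(i).child_pose(state.s[i - 1])
    Ic = [model.links[i].inertia.matrix().copy() for i in range(NB)]
    for i in range(NB - 1, 0, -1):
        p = model.parent(i)
        Xs = force_adjoint(T_up[i])
        Xm_inv = motion_adjoint(T_up[i].inverse())
        Ic[p] += Xs @ Ic[i] @ Xm_inv
    M = np.zeros((6 + n, 6 + n))
    M[:6, :6] = Ic[0]
    for i in range(1, NB):
        S = model.joint_of(i).motion_subspace
        F = Ic[i] @ S
        M[6 + i - 1, 6 + i - 1] = S @ F
        j = i
        while model.parent(j) != 0:
            F = force_adjoint(T_up[j]) @ F
            j = model.parent(j)
            M[6 + i - 1, 6 + j - 1] = model.joint_of(j).motion_subspace @ F
            M[6 + j - 1, 6 + i - 1] = M[6 + i - 1, 6 + j - 1]
        F = force_adjoint(T_up[j]) @ F
        M[:6, 6 + i - 1] = F
        M[6 + i - 1, :6] = F
    return M


def mass_matrix_and_bias(model: MultiBodyModel, state: SystemState,
                         gravity: np.ndarray = GRAVITY
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mass matrix M(q) and bias vector h(q, nu) in body coordinates.

    The equations of motion read ``M nu_dot + h = B tau + sum_k J_k^T f_k``
    with ``nu = (base body twist, s_dot)`` and body-frame contact
    Jacobians.  ``M`` comes from the composite-rigid-body assembly;
    ``h`` from a Newton–Euler pass at zero acceleration.
    """
    M = crba(model, state)
    zero_acc = SystemState(
        base_position=state.base_position,
        base_rotation=state.base_rotation,
        s=state.s, s_dot=state.s_dot,
        base_velocity=state.base_velocity,
        # mixed acceleration such that the body acceleration is zero
        base_acceleration=body_accel_to_mixed(
            state.base_rotation,
            mixed_to_body(state.base_rotation, state.base_velocity),
            np.zeros(6)),
        s_ddot=np.zeros(model.n_joints),
    )
    res = rnea(model, zero_acc, None, gravity)
    h = np.concatenate([res.base_residual, res.tau])
    return M, h


def body_jacobian(model: MultiBodyModel, state: SystemState,
                  frame: str) -> np.ndarray:
    """6x(6+n) Jacobian mapping nu_body to the frame's body twist."""
    link, T_LF = model.resolve_frame(frame)
    poses = link_poses(model, state)
    T_IF = poses[link].compose(T_LF)
    n = model.n_joints
    J = np.zeros((6, 6 + n))
    J[:, :6] = motion_adjoint(T_IF.inverse().compose(poses[0]))
    for i in model.path_to_base(link):
        if i == 0:
            break
        S = model.joint_of(i).motion_subspace
        X = motion_adjoint(T_IF.inverse().compose(poses[i]))
        J[:, 6 + i - 1] = X @ S
    return J
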