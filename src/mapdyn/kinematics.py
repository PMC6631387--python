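"""Joint-angle estimation, numerical differentiation and base velocity.

The kinematics pipeline turns orientation streams into a full system
state:

1. each joint angle is recovered per sample from the measured relative
   rotation of its link pair (a bounded 1-D rotation-error minimisation);
2. joint velocities/accelerations come from third-order Savitzky–Golay
   differentiation of the angle trajectories;
3. the floating-base velocity is the least-squares solution of the
   stance-foot zero-velocity constraint ``J_b v_B + J_s s_dot = 0``,
   using one foot's Jacobian in single support and the 12-row stack in
   double support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.signal import savgol_filter
from scipy.spatial.transform import Rotation as ScipyRotation

from .contact import ContactSet
from .dynamics import body_jacobian, link_poses
from .model import Joint, ModelError, MultiBodyModel, SystemState
from .spatial import rotation_adjoint


class IKError(RuntimeError):
    pass


class SingularContactError(RuntimeError):
    """Raised when the stacked contact Jacobian cannot determine v_B."""


@dataclass(frozen=True)
class IKResult:
    s: float
    residual: float

    def __float__(self) -> float:
        return self.s


def _euler_error(R_err: np.ndarray) -> float:
    """Squared norm of the intrinsic ZYX Euler angles of a rotation error."""
    ang = ScipyRotation.from_matrix(R_err).as_euler("ZYX")
    return float(ang @ ang)


def pairwise_ik(R_meas: np.ndarray, joint: Joint,
                init: float | None = None,
                grid: int = 121, xatol: float = 1e-12) -> IKResult:
    """Recover a one-DoF joint angle from a measured relative rotation.

    Minimises the squared intrinsic-ZYX Euler-angle error between the
    measured parent-to-child rotation and the model rotation
    ``lambda_R_L(s)``, subject to the joint limits.  A coarse grid scan
    (robust to the multiple minima of angles up to pi) feeds a bounded
    scalar refinement; near-ties are broken toward ``init`` (in the
    pipeline, the previous sample's angle).
    """
    if joint.kind != "revolute":
        raise IKError(f"pairwise IK is defined for revolute joints, "
                      f"joint {joint.name!r} is {joint.kind}")
    lo, hi = joint.limits
    lo = max(lo, -2.0 * np.pi)
    hi = min(hi, 2.0 * np.pi)

    def objective(s: float) -> float:
        R_model = joint.child_pose(s).rotation
        return _euler_error(R_model.T @ R_meas)

    xs = np.linspace(lo, hi, grid)
    vals = np.array([objective(x) for x in xs])
    order = np.argsort(vals)
    best_s, best_f = None, np.inf
    for k in order[:3]:
        a = xs[max(k - 1, 0)]
        b = xs[min(k + 1, grid - 1)]
        if a == b:
            s_k, f_k = xs[k], vals[k]
        else:
            res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                                  options={"xatol": xatol})
            s_k, f_k = float(res.x), float(res.fun)
        if f_k < best_f - 1e-12:
            best_s, best_f = s_k, f_k
        elif abs(f_k - best_f) <= 1e-12 and init is not None:
            if abs(s_k - init) < abs(best_s - init):
                best_s = s_k
    if best_s is None or not np.isfinite(best_f):
        raise IKError(f"IK failed to converge for joint {joint.name!r}")
    return IKResult(float(np.clip(best_s, lo, hi)), float(np.sqrt(best_f)))


def ik_trajectory(model: MultiBodyModel,
                  relative_rotations: np.ndarray) -> np.ndarray:
    """Per-sample link-pairwise IK over a stream.

    ``relative_rotations`` has shape ``(T, n, 3, 3)``: the measured
    parent-to-child rotation of each joint at each sample.  Each sample
    initialises from the previous one; the first from mid-limits.
    """
    T, n = relative_rotations.shape[:2]
    if n != model.n_joints:
        raise ModelError("rotation stream width does not match model")
    s = np.zeros((T, n))
    for j, joint in enumerate(model.joints):
        lo, hi = joint.limits
        init = 0.5 * (max(lo, -np.pi) + min(hi, np.pi))
        for t in range(T):
            init = pairwise_ik(relative_rotations[t, j], joint, init=init).s
            s[t, j] = init
    return s


def sg_differentiate(series: np.ndarray, dt: float,
                     window: int = 9, poly_order: int = 3
                     ) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives by Savitzky–Golay filtering.

    Fits a local polynomial of degree ``poly_order`` over ``window``
    samples (odd) and evaluates its derivatives, exact for polynomial
    signals up to the fit degree.  Edges use the one-sided polynomial
    fit.  ``series`` may be 1-D or (T, n); differentiation runs along
    axis 0.
    """
    series = np.asarray(series, float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= poly_order:
        raise ValueError("window must exceed poly_order")
    if series.shape[0] < window:
        raise ValueError(f"series of length {series.shape[0]} is shorter "
                         f"than the window ({window})")
    d1 = savgol_filter(series, window, poly_order, deriv=1, delta=dt,
                       axis=0, mode="interp")
    d2 = savgol_filter(series, window, poly_order, deriv=2, delta=dt,
                       axis=0, mode="interp")
    return d1, d2


def contact_jacobian(model: MultiBodyModel, state: SystemState,
                     frame: str) -> np.ndarray:
    """6x(6+n) Jacobian of a frame in the mixed representation.

    Maps ``nu = (I_v_B, s_dot)`` — mixed base velocity — to the frame's
    mixed velocity ``(I_odot_F, I_w_F)``.  Partition: columns 0..5 are
    ``J_b``, the rest ``J_s``.
    """
    link, T_LF = model.resolve_frame(frame)
    J_body = body_jacobian(model, state, frame)
    poses = link_poses(model, state)
    R_F = poses[link].compose(T_LF).rotation
    J = rotation_adjoint(R_F) @ J_body
    J[:, :6] = J[:, :6] @ rotation_adjoint(state.base_rotation.T)
    return J


def base_velocity_from_contacts(model: MultiBodyModel, state: SystemState,
                                contact_frames: list[str],
                                cond_limit: float = 1e8
                                ) -> np.ndarray:
    """Floating-base mixed velocity from stance zero-velocity constraints.

    Solves ``min_v |J_b v + J_s s_dot|^2`` over the stacked Jacobians of
    the active contact frames.  With a single contact ``J_b`` is square
    and the solve is direct; with several the 6-column least-squares
    problem is solved by orthogonal decomposition.
    """
    if not contact_frames:
        raise ValueError("at least one contact frame is required")
    Js = [contact_jacobian(model, state, f) for f in contact_frames]
    J = np.vstack(Js)
    Jb, Jss = J[:, :6], J[:, 6:]
    rhs = -Jss @ state.s_dot
    if Jb.shape[0] == 6:
        cond = np.linalg.cond(Jb)
        if cond > cond_limit:
            raise SingularContactError(
                f"contact Jacobian is ill-conditioned (cond={cond:.3g})")
        return np.linalg.solve(Jb, rhs)
    sol, _, rank, sv = np.linalg.lstsq(Jb, rhs, rcond=1e-8)
    if rank < 6:
        raise SingularContactError(
            f"stacked contact Jacobian is rank deficient (rank={rank}, "
            f"singular values {sv.tolist()})")
    return sol


def base_velocity_for_label(model: MultiBodyModel, state: SystemState,
                            contacts: ContactSet, j: int) -> np.ndarray:
    """Convenience: pick the constraint set from a contact label stream."""
    return base_velocity_from_contacts(model, state, contacts.frames_at(j))


# ---------------------------------------------------------------------------
# orientation-stream I/O
# ---------------------------------------------------------------------------


def read_orientation_csv(path, link_names: list[str]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Read per-link orientation streams.

    Columns: ``time`` plus ``<link>_q{w,x,y,z}`` per link (w,x,y,z
    quaternion convention).  Returns (times, R) with R of shape
    (T, n_links, 3, 3).
    """
    df = pd.read_csv(path)
    times = df["time"].to_numpy(float)
    R = np.zeros((len(df), len(link_names), 3, 3))
    for i, name in enumerate(link_names):
        cols = [f"{name}_q{c}" for c in "wxyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"orientation CSV missing columns {missing}")
        q = df[cols].to_numpy(float)
        R[:, i] = ScipyRotation.from_quat(np.roll(q, -1, axis=1)).as_matrix()
    return times, R


def write_orientation_csv(path, times, link_names: list[str],
                          R: np.ndarray) -> None:
    data = {"time": times}
    for i, name in enumerate(link_names):
        q = np.roll(ScipyRotation.from_matrix(R[:, i]).as_quat(), 1, axis=1)
        for k, c in enumerate("wxyz"):
            data[f"{name}_q{c}"] = q[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def write_joint_trajectory_csv(path, times, joint_names: list[str],
                               s: np.ndarray, s_dot: np.ndarray,
                               s_ddot: np.ndarray) -> None:
    data = {"time": times}
    for k, name in enumerate(joint_names):
        data[f"{name}_s"] = s[:, k]
        data[f"{name}_s_dot"] = s_dot[:, k]
        data[f"{name}_s_ddot"] = s_ddot[:, k]
    pd.DataFrame(data).to_csv(path, index=False)
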