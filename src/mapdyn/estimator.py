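"""Maximum-a-posteriori estimation of whole-body dynamics.

The unknowns of one time sample are stacked in the estimation vector

    d = [ per-link (alpha_g, f_ext) ... | per-joint wrench ... | s_ddot ]

of length ``12 N_B + 7 n``: per link the proper sensor acceleration and
the external wrench, per joint the internal wrench and the joint
acceleration.  Joint torques are not part of ``d``; they are recovered
afterwards as the projection ``tau_J = S_J^T f_J``.

Two linear systems constrain ``d`` at each sample:

* the **dynamics system** ``D d + b_D = e_D`` stacks, per link, six
  acceleration-propagation rows and six Newton–Euler balance rows, with
  the velocity-product bias terms in ``b_D`` computed from propagated
  link twists;
* the **measurement system** ``Y d + b_Y = y`` with one row block per
  sensor channel (accelerometer triads, foot force/torque sensors,
  differentiated joint accelerations, and zero-wrench pseudo-measurements
  on links known to be contact free).

With Gaussian noise on both systems and a Gaussian prior
``d ~ N(mu_d, Sigma_d)``, the posterior is Gaussian with

    Sigma_d|y = (D' Sigma_D^-1 D + Sigma_d^-1 + Y' Sigma_y^-1 Y)^-1
    mu_d|y    = Sigma_d|y (Y' Sigma_y^-1 (y - b_Y)
                           - D' Sigma_D^-1 b_D + Sigma_d^-1 mu_d)

i.e. the dynamics-plus-prior fusion ``(Sigma_bar_D, mu_bar_D)`` combined
with the measurements by standard Gaussian conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_factor, cho_solve

from .contact import ContactSet
from .dynamics import (body_from_sensor_accel, link_poses,
                       mixed_accel_to_body, mixed_to_body,
                       sensor_from_body_accel)
from .kinematics import base_velocity_from_contacts, sg_differentiate
from .model import ModelError, MultiBodyModel, SystemState
from .spatial import (GRAVITY, SpatialTransform, crf, crm, force_adjoint,
                      motion_adjoint, skew)

DENSE_LIMIT = 500


# ---------------------------------------------------------------------------
# estimation-vector layout
# ---------------------------------------------------------------------------


class DLayout:
    """Index map between (link/joint, quantity) and slices of ``d``.

    Link blocks come first, 12 entries per link in link order
    (proper sensor acceleration then external wrench); then the joint
    wrenches (6 per joint, joints 1..n) and finally the joint
    accelerations (1 per joint).
    """

    def __init__(self, model: MultiBodyModel):
        self.n_links = model.n_links
        self.n_joints = model.n_joints
        self.size = 12 * self.n_links + 7 * self.n_joints

    def alpha(self, link: int) -> slice:
        return slice(12 * link, 12 * link + 6)

    def ext_wrench(self, link: int) -> slice:
        return slice(12 * link + 6, 12 * link + 12)

    def joint_wrench(self, joint: int) -> slice:
        """Joint index is 1-based (joint i couples link i to its parent)."""
        base = 12 * self.n_links + 6 * (joint - 1)
        return slice(base, base + 6)

    def s_ddot(self, joint: int) -> int:
        return 12 * self.n_links + 6 * self.n_joints + (joint - 1)

    def pack(self, alpha_g: np.ndarray, ext: np.ndarray,
             joint_wrenches: np.ndarray, s_ddot: np.ndarray) -> np.ndarray:
        d = np.zeros(self.size)
        for i in range(self.n_links):
            d[self.alpha(i)] = alpha_g[i]
            d[self.ext_wrench(i)] = ext[i]
        for j in range(1, self.n_joints + 1):
            d[self.joint_wrench(j)] = joint_wrenches[j - 1]
            d[self.s_ddot(j)] = s_ddot[j - 1]
        return d

    def unpack(self, d: np.ndarray) -> dict[str, np.ndarray]:
        NB, n = self.n_links, self.n_joints
        return {
            "alpha_g": np.array([d[self.alpha(i)] for i in range(NB)]),
            "ext_wrench": np.array([d[self.ext_wrench(i)] for i in range(NB)]),
            "joint_wrench": np.array([d[self.joint_wrench(j)]
                                      for j in range(1, n + 1)]),
            "s_ddot": np.array([d[self.s_ddot(j)] for j in range(1, n + 1)]),
        }


def proper_body_from_sensor(alpha_g: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper sensor acceleration -> proper body acceleration.

    ``v`` is the link body twist; the two representations differ by the
    velocity product ``(omega x v_lin, 0)``.
    """
    return body_from_sensor_accel(alpha_g, v)


def proper_sensor_from_body(a_g: np.ndarray, v: np.ndarray) -> np.ndarray:
    return sensor_from_body_accel(a_g, v)


# ---------------------------------------------------------------------------
# link twists from available kinematics
# ---------------------------------------------------------------------------


def propagate_twists(model: MultiBodyModel, state: SystemState) -> np.ndarray:
    """Body twist of every link from the base velocity and joint rates."""
    state.check_dims(model)
    v = np.zeros((model.n_links, 6))
    v[0] = mixed_to_body(state.base_rotation, state.base_velocity)
    for i in range(1, model.n_links):
        joint = model.joint_of(i)
        X = motion_adjoint(joint.child_pose(state.s[i - 1]).inverse())
        v[i] = X @ v[model.parent(i)] + joint.motion_subspace \
            * state.s_dot[i - 1]
    return v


# ---------------------------------------------------------------------------
# dynamics system D d + b_D = 0
# ---------------------------------------------------------------------------


def build_dynamics_system(model: MultiBodyModel, state: SystemState,
                          gravity: np.ndarray = GRAVITY
                          ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the stacked acceleration-propagation and Newton–Euler
    constraints for one sample.

    Row layout: 12 rows per link in link order — rows 0-5 the
    acceleration propagation (for the base: the known-base-acceleration
    anchor, see below), rows 6-11 the Newton–Euler balance.  The matrix
    has the tree's sparsity pattern.

    The base acceleration rows read ``-alpha_B + b = 0``.  When the state
    carries a base acceleration, ``b`` is the full known proper sensor
    acceleration of the base; otherwise the velocity-product term alone
    is used (a quasi-static approximation appropriate for near-static
    trials — inflate the corresponding ``Sigma_D`` rows in that case).
    """
    layout = DLayout(model)
    NB = model.n_links
    v = propagate_twists(model, state)
    w = np.zeros((NB, 6))
    w[:, :3] = np.cross(v[:, 3:], v[:, :3])

    rows, cols, vals = [], [], []
    b = np.zeros(12 * NB)

    def put(r0: int, csl: slice, block: np.ndarray) -> None:
        block = np.atleast_2d(block)
        rr, cc = np.nonzero(block)
        rows.extend(r0 + rr)
        cols.extend(csl.start + cc)
        vals.extend(block[rr, cc])

    eye6 = np.eye(6)
    for i in range(NB):
        r_acc = 12 * i
        r_ne = 12 * i + 6
        # acceleration rows
        put(r_acc, layout.alpha(i), -eye6)
        if i == 0:
            if state.base_acceleration is not None:
                a_body = mixed_accel_to_body(state.base_rotation,
                                             state.base_velocity,
                                             state.base_acceleration)
                a_g = a_body - np.concatenate(
                    [state.base_rotation.T @ gravity, np.zeros(3)])
                b[r_acc:r_acc + 6] = proper_sensor_from_body(a_g, v[0])
            else:
                b[r_acc:r_acc + 6] = w[0]
        else:
            joint = model.joint_of(i)
            p = model.parent(i)
            X = motion_adjoint(joint.child_pose(state.s[i - 1]).inverse())
            S = joint.motion_subspace
            put(r_acc, layout.alpha(p), X)
            put(r_acc, slice(layout.s_ddot(i), layout.s_ddot(i) + 1),
                S.reshape(6, 1))
            b[r_acc:r_acc + 6] = (crm(v[i]) @ (S * state.s_dot[i - 1])
                                  + w[i] - X @ w[p])
        # Newton–Euler rows
        M = model.links[i].inertia.matrix()
        put(r_ne, layout.alpha(i), M)
        put(r_ne, layout.ext_wrench(i), -eye6)
        if i != 0:
            put(r_ne, layout.joint_wrench(i), -eye6)
        for c in model.children(i):
            T = model.joint_of(c).child_pose(state.s[c - 1])
            put(r_ne, layout.joint_wrench(c), force_adjoint(T))
        wv = np.concatenate([np.zeros(3), v[i, 3:]])
        b[r_ne:r_ne + 6] = crf(wv) @ (M @ wv)

    D = sp.csr_matrix((vals, (rows, cols)), shape=(12 * NB, layout.size))
    return D, b


# ---------------------------------------------------------------------------
# measurement system Y d + b_Y = y
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementChannel:
    """One sensor channel block.

    kind:
      ``imu``          3 rows — accelerometer triad on link ``target``,
                       mounted at ``mount`` (link-to-sensor transform);
      ``ft``           6 rows — force/torque sensor at model frame
                       ``target`` measuring the external wrench of its
                       host link in the sensor frame;
      ``joint_acc``    1 row  — differentiated acceleration of joint
                       ``target`` (child-link name);
      ``null_wrench``  6 rows — pseudo-measurement pinning the external
                       wrench of link ``target`` to zero (used for links
                       known to be contact free).
    """

    kind: str
    target: str
    variance: float = 1e-4
    mount: SpatialTransform = field(default_factory=SpatialTransform.identity)
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("imu", "ft", "joint_acc", "null_wrench"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.variance <= 0:
            raise ValueError("channel variance must be positive")
        if not self.name:
            object.__setattr__(self, "name", f"{self.kind}:{self.target}")

    @property
    def n_rows(self) -> int:
        return {"imu": 3, "ft": 6, "joint_acc": 1, "null_wrench": 6}[self.kind]


def channel_variances(channels: list[MeasurementChannel]) -> np.ndarray:
    return np.concatenate([np.full(c.n_rows, c.variance) for c in channels])


def channel_slices(channels: list[MeasurementChannel]) -> dict[str, slice]:
    out, r = {}, 0
    for c in channels:
        out[c.name] = slice(r, r + c.n_rows)
        r += c.n_rows
    return out


def build_measurement_system(model: MultiBodyModel,
                             channels: list[MeasurementChannel],
                             state: SystemState
                             ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble ``(Y, b_Y)`` for a channel list at one sample.

    The accelerometer row derives from rigid-body transport of the proper
    sensor acceleration: a triad at ``(L_R_S, L_o_S)`` on link L reads ::

        y = S_R_L [ (1 | -S(L_o_S)) alpha_L_g + S(w_L)^2 L_o_S ]

    which reduces to selecting the linear slice of ``alpha_L_g`` for an
    origin-mounted, axis-aligned sensor at rest.
    """
    layout = DLayout(model)
    v = propagate_twists(model, state)
    rows, cols, vals = [], [], []
    b = []
    r0 = 0

    def put(r: int, csl: slice, block: np.ndarray) -> None:
        block = np.atleast_2d(block)
        rr, cc = np.nonzero(block)
        rows.extend(r + rr)
        cols.extend(csl.start + cc)
        vals.extend(block[rr, cc])

    for ch in channels:
        if ch.kind == "imu":
            link = model.link_index(ch.target)
            R_SL = ch.mount.rotation.T
            o = ch.mount.origin
            block = np.hstack([R_SL, -R_SL @ skew(o)])
            put(r0, layout.alpha(link), block)
            omega = v[link, 3:]
            b.append(R_SL @ (skew(omega) @ skew(omega) @ o))
        elif ch.kind == "ft":
            link, T_LF = model.resolve_frame(ch.target)
            put(r0, layout.ext_wrench(link), force_adjoint(T_LF.inverse()))
            b.append(np.zeros(6))
        elif ch.kind == "joint_acc":
            link = model.link_index(ch.target)
            if link == 0:
                raise ModelError("joint_acc channel cannot target the base")
            put(r0, slice(layout.s_ddot(link), layout.s_ddot(link) + 1),
                np.array([[1.0]]))
            b.append(np.zeros(1))
        else:  # null_wrench
            link = model.link_index(ch.target)
            put(r0, layout.ext_wrench(link), np.eye(6))
            b.append(np.zeros(6))
        r0 += ch.n_rows

    Y = sp.csr_matrix((vals, (rows, cols)), shape=(r0, layout.size))
    return Y, np.concatenate(b) if b else np.zeros(0)


# ---------------------------------------------------------------------------
# Gaussian MAP solve
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Covariance configuration of the estimator.

    ``sigma_D``: variance of the dynamics constraint rows (scalar or
    length-12N_B vector) — low values trust the model.  ``sigma_d`` /
    ``mu_d``: prior on ``d`` — a large ``sigma_d`` encodes no prior
    knowledge.  Defaults follow the usual procedural guidance (model
    variance in the 1e-6..1e-4 range, uninformative prior).
    """

    sigma_D: float | np.ndarray = 1e-6
    sigma_d: float | np.ndarray = 1e4
    mu_d: float | np.ndarray = 0.0


class PosteriorNotPDError(np.linalg.LinAlgError):
    pass


@dataclass
class GaussianEstimate:
    """Gaussian posterior over the estimation vector."""

    mean: np.ndarray
    _solve: object          # callable: (k,) or (k, m) rhs -> solution
    _dense_cov: np.ndarray | None = None

    @property
    def covariance(self) -> np.ndarray:
        if self._dense_cov is None:
            self._dense_cov = self._solve(np.eye(self.mean.size))
        return self._dense_cov

    def marginal_covariance(self, indices: np.ndarray) -> np.ndarray:
        """Covariance sub-block for the given entries of ``d``."""
        indices = np.asarray(indices, int)
        if self._dense_cov is not None:
            return self._dense_cov[np.ix_(indices, indices)]
        E = np.zeros((self.mean.size, indices.size))
        E[indices, np.arange(indices.size)] = 1.0
        cols = self._solve(E)
        return cols[indices]

    def variances(self, indices: np.ndarray) -> np.ndarray:
        return np.diag(self.marginal_covariance(indices))


def _as_variance_vector(value, size: int) -> np.ndarray:
    arr = np.asarray(value, float)
    if arr.ndim == 0:
        arr = np.full(size, float(arr))
    if arr.shape != (size,):
        raise ValueError(f"variance vector has shape {arr.shape}, "
                         f"expected ({size},)")
    if np.any(arr <= 0):
        raise ValueError("variances must be positive")
    return arr


def map_solve(Y, b_Y: np.ndarray, y: np.ndarray, sigma_y,
              D, b_D: np.ndarray, prior: PriorConfig) -> GaussianEstimate:
    """Posterior mean and covariance of ``d`` for one sample.

    ``sigma_y``, ``prior.sigma_D`` and ``prior.sigma_d`` are variances
    (diagonal covariances), scalars or per-row vectors.  The posterior
    information matrix is assembled sparsely and factorised by Cholesky
    (dense below :data:`DENSE_LIMIT` unknowns, sparse LU above); a
    factorisation failure raises :class:`PosteriorNotPDError`.
    """
    D = sp.csr_matrix(D)
    Y = sp.csr_matrix(Y)
    nd = D.shape[1]
    if Y.shape[1] != nd:
        raise ValueError("D and Y disagree on the size of d")
    w_D = 1.0 / _as_variance_vector(prior.sigma_D, D.shape[0])
    w_y = 1.0 / _as_variance_vector(sigma_y, Y.shape[0])
    w_d = 1.0 / _as_variance_vector(prior.sigma_d, nd)
    mu_d = np.broadcast_to(np.asarray(prior.mu_d, float), (nd,))

    Dw = D.multiply(w_D[:, None])
    Yw = Y.multiply(w_y[:, None])
    Lambda = (D.T @ Dw + Y.T @ Yw + sp.diags(w_d)).tocsc()
    rhs = (Yw.T @ (y - b_Y)) - (Dw.T @ b_D) + w_d * mu_d

    if nd < DENSE_LIMIT:
        dense = Lambda.toarray()
        try:
            factor = cho_factor(dense, lower=True)
        except np.linalg.LinAlgError as exc:
            raise PosteriorNotPDError(
                "posterior information matrix is not positive definite"
            ) from exc
        mean = cho_solve(factor, rhs)
        return GaussianEstimate(mean, lambda B: cho_solve(factor, B))

    lu = spla.splu(Lambda)
    diag_u = lu.U.diagonal()
    if np.any(diag_u.real <= 0) and np.any(np.abs(diag_u) < 1e-300):
        raise PosteriorNotPDError("sparse factorisation found a zero pivot")
    mean = lu.solve(rhs)
    if np.any(~np.isfinite(mean)):
        raise PosteriorNotPDError("posterior solve produced non-finite "
                                  "values")
    return GaussianEstimate(mean, lambda B: lu.solve(np.asarray(B)))


def extract_torques(estimate: GaussianEstimate, model: MultiBodyModel
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Joint torques and their posterior variances.

    ``tau_J = S_J^T f_J`` with variance ``S_J^T Sigma(f_J) S_J``.
    """
    layout = DLayout(model)
    n = model.n_joints
    tau = np.zeros(n)
    var = np.zeros(n)
    for j in range(1, n + 1):
        S = model.joint_of(j).motion_subspace
        sl = layout.joint_wrench(j)
        tau[j - 1] = S @ estimate.mean[sl]
        Sigma = estimate.marginal_covariance(np.arange(sl.start, sl.stop))
        var[j - 1] = S @ Sigma @ S
    return tau, var


# ---------------------------------------------------------------------------
# per-sample orchestration
# ---------------------------------------------------------------------------


@dataclass
class KinematicStreams:
    """Aligned kinematic inputs to the estimator, one row per sample.

    ``base_velocity``/``base_acceleration`` may be omitted: the runner
    then recovers the base velocity from the active contact constraints
    and differentiates it (Savitzky–Golay) for the base acceleration.
    """

    times: np.ndarray
    s: np.ndarray
    s_dot: np.ndarray
    base_position: np.ndarray
    base_rotation: np.ndarray          # (T, 3, 3)
    base_velocity: np.ndarray | None = None
    base_acceleration: np.ndarray | None = None

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times)))


@dataclass
class EstimationRun:
    """Per-sample MAP results over a trial."""

    times: np.ndarray
    d_mean: np.ndarray                  # (T, |d|)
    tau: np.ndarray                     # (T, n)
    tau_variance: np.ndarray            # (T, n)
    base_velocity: np.ndarray           # (T, 6) as used
    contact_log: list[list[str]]        # frames constrained at each sample
    estimates: list[GaussianEstimate] | None = None


def run_estimation(model: MultiBodyModel, streams: KinematicStreams,
                   measurements: np.ndarray,
                   channels: list[MeasurementChannel],
                   contacts: ContactSet,
                   prior: PriorConfig | None = None,
                   gravity: np.ndarray = GRAVITY,
                   sg_window: int = 9,
                   keep_estimates: bool = False) -> EstimationRun:
    """Run the MAP estimator over an aligned trial.

    Per sample: (1) the base velocity is taken from the streams or
    recovered from the stance constraint selected by the contact label;
    (2) the dynamics and measurement systems are assembled; (3) the
    Gaussian posterior is solved and torques extracted.  Samples are
    treated independently (no temporal smoothing) — the only cross-sample
    operation is the optional differentiation of the base velocity.
    """
    prior = prior or PriorConfig()
    T = len(streams)
    measurements = np.asarray(measurements, float)
    if measurements.shape[0] != T:
        raise ValueError("measurement stream length does not match times")
    if len(contacts) != T:
        raise ValueError("contact label length does not match times")
    sigma_y = channel_variances(channels)

    # pass 1: base velocity for every sample
    vB = np.zeros((T, 6))
    contact_log: list[list[str]] = []
    for t in range(T):
        frames = contacts.frames_at(t)
        contact_log.append(frames)
        if streams.base_velocity is not None:
            vB[t] = streams.base_velocity[t]
        else:
            st = SystemState(streams.base_position[t],
                             streams.base_rotation[t],
                             streams.s[t], s_dot=streams.s_dot[t])
            vB[t] = base_velocity_from_contacts(model, st, frames)

    if streams.base_acceleration is not None:
        aB = streams.base_acceleration
    else:
        dt = 1.0 / streams.rate
        aB, _ = sg_differentiate(vB, dt, window=min(sg_window, T | 1))

    layout = DLayout(model)
    d_mean = np.zeros((T, layout.size))
    n = model.n_joints
    tau = np.zeros((T, n))
    tau_var = np.zeros((T, n))
    kept = [] if keep_estimates else None
    for t in range(T):
        state = SystemState(streams.base_position[t],
                            streams.base_rotation[t],
                            streams.s[t], s_dot=streams.s_dot[t],
                            base_velocity=vB[t], base_acceleration=aB[t],
                            s_ddot=np.zeros(n))
        try:
            D, b_D = build_dynamics_system(model, state, gravity)
            Y, b_Y = build_measurement_system(model, channels, state)
            est = map_solve(Y, b_Y, measurements[t], sigma_y, D, b_D, prior)
        except Exception as exc:
            raise RuntimeError(f"estimation failed at sample {t} "
                               f"(t={streams.times[t]:.4f}s): {exc}") from exc
        d_mean[t] = est.mean
        tau[t], tau_var[t] = extract_torques(est, model)
        if kept is not None:
            kept.append(est)
    return EstimationRun(streams.times, d_mean, tau, tau_var, vB,
                         contact_log, kept)
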