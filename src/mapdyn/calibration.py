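"""Offline least-squares estimation of a sensor's position on its host link.

A wearable IMU suite exposes each sensor's linear proper acceleration and
orientation, and its host link's angular velocity/acceleration and
orientation — but not where the sensor sits on the link.  For a sensor
rigidly attached at ``L_o_S`` the accelerometer reading obeys

    a_S = S_R_I (I_oddot_L - I_g)
        + S_R_I (S(I_wdot_L) + S(I_w_L)^2) I_R_L  L_o_S

so every sample with angular motion yields three linear equations in the
unknown offset.  Stacking samples and solving the least-squares problem
recovers ``L_o_S``; purely static samples carry no position information
(the regressor vanishes) and are dropped by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import GRAVITY, check_rotation, skew


class UnobservabilityError(ValueError):
    """The stacked regressor is rank deficient: some direction of the
    sensor offset is unexcited by the calibration motion."""

    def __init__(self, message: str, null_directions: np.ndarray):
        super().__init__(message)
        self.null_directions = null_directions


@dataclass(frozen=True)
class CalibrationSample:
    """One time sample of the calibration streams.

    All angular quantities refer to the host link and are expressed in the
    inertial frame; ``a_S`` is the accelerometer reading in the sensor
    frame [m/s^2].
    """

    a_S: np.ndarray
    omega: np.ndarray
    omega_dot: np.ndarray
    R_L: np.ndarray
    R_S: np.ndarray
    o_ddot_L: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        for name in ("a_S", "omega", "omega_dot", "o_ddot_L"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name),
                                          float).reshape(3))
        object.__setattr__(self, "R_L", check_rotation(np.asarray(self.R_L,
                                                                  float)))
        object.__setattr__(self, "R_S", check_rotation(np.asarray(self.R_S,
                                                                  float)))


def build_regressor(sample: CalibrationSample,
                    gravity: np.ndarray = GRAVITY
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample regressor ``(A, b)`` with ``A @ L_o_S = b``.

    ``A = (S(wdot) + S(w)^2) I_R_L`` and
    ``b = I_R_S a_S - (I_oddot_L - I_g)``.
    """
    A = (skew(sample.omega_dot) + skew(sample.omega) @ skew(sample.omega)) \
        @ sample.R_L
    b = sample.R_S @ sample.a_S - (sample.o_ddot_L - gravity)
    return A, b


@dataclass
class CalibrationResult:
    position: np.ndarray
    residual_norm: float
    condition_number: float
    singular_values: np.ndarray
    n_used: int
    n_total: int

    def to_json(self) -> str:
        return json.dumps({
            "position": self.position.tolist(),
            "residual_norm": self.residual_norm,
            "condition_number": self.condition_number,
            "singular_values": self.singular_values.tolist(),
            "n_used": self.n_used,
            "n_total": self.n_total,
        }, indent=1)


def estimate_sensor_position(samples: list[CalibrationSample],
                             gravity: np.ndarray = GRAVITY,
                             rank_tol: float = 1e-8,
                             motion_threshold: float = 1e-3
                             ) -> CalibrationResult:
    """Least-squares sensor offset from a list of calibration samples.

    Samples whose angular velocity *and* acceleration norms are both below
    ``motion_threshold`` are discarded (they contribute only noise); set
    ``motion_threshold=0`` to keep everything.  Singular values of the
    stacked regressor below ``rank_tol * sigma_max`` are treated as zero;
    if fewer than three survive, an :class:`UnobservabilityError` names
    the unobservable direction(s).
    """
    if not samples:
        raise ValueError("at least one calibration sample is required")
    rows_A, rows_b = [], []
    for smp in samples:
        if (np.linalg.norm(smp.omega) < motion_threshold
                and np.linalg.norm(smp.omega_dot) < motion_threshold):
            continue
        A, b = build_regressor(smp, gravity)
        rows_A.append(A)
        rows_b.append(b)
    n_used = len(rows_A)
    if n_used == 0:
        raise UnobservabilityError(
            "all samples are static: the sensor position is unobservable "
            "in every direction", np.eye(3))
    A_bar = np.vstack(rows_A)
    b_bar = np.concatenate(rows_b)
    U, sv, Vt = np.linalg.svd(A_bar, full_matrices=False)
    keep = sv > rank_tol * sv[0]
    if keep.sum() < 3:
        null_dirs = Vt[keep.sum():]
        raise UnobservabilityError(
            "calibration motion does not excite the sensor offset along "
            f"direction(s) {np.round(null_dirs, 6).tolist()} "
            f"(singular values {sv.tolist()})", null_dirs)
    pos = Vt.T @ ((U.T @ b_bar) / sv)
    residual = float(np.linalg.norm(A_bar @ pos - b_bar))
    return CalibrationResult(pos, residual, float(sv[0] / sv[-1]), sv,
                             n_used, len(samples))


# CSV column order for calibration logs (one row per sample):
_CSV_COLUMNS = (
    ["time"]
    + [f"a_S_{c}" for c in "xyz"]
    + [f"omega_{c}" for c in "xyz"]
    + [f"omega_dot_{c}" for c in "xyz"]
    + [f"q_L_{c}" for c in "wxyz"]
    + [f"q_S_{c}" for c in "wxyz"]
    + [f"o_ddot_L_{c}" for c in "xyz"]
)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    # stored w,x,y,z; scipy wants x,y,z,w
    return Rotation.from_quat(np.roll(q, -1)).as_matrix()


def _matrix_to_quat(R: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return np.roll(Rotation.from_matrix(R).as_quat(), 1)


def read_calibration_csv(path) -> list[CalibrationSample]:
    """Read a calibration log.

    Expected columns (quaternions in w,x,y,z order): ``time``,
    ``a_S_{x,y,z}``, ``omega_{x,y,z}``, ``omega_dot_{x,y,z}``,
    ``q_L_{w,x,y,z}``, ``q_S_{w,x,y,z}``, ``o_ddot_L_{x,y,z}``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calibration CSV is missing columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        samples.append(CalibrationSample(
            a_S=row[[f"a_S_{c}" for c in "xyz"]].to_numpy(float),
            omega=row[[f"omega_{c}" for c in "xyz"]].to_numpy(float),
            omega_dot=row[[f"omega_dot_{c}" for c in "xyz"]].to_numpy(float),
            R_L=_quat_to_matrix(row[[f"q_L_{c}" for c in "wxyz"]
                                    ].to_numpy(float)),
            R_S=_quat_to_matrix(row[[f"q_S_{c}" for c in "wxyz"]
                                    ].to_numpy(float)),
            o_ddot_L=row[[f"o_ddot_L_{c}" for c in "xyz"]].to_numpy(float),
        ))
    return samples


def write_calibration_csv(path, times, samples: list[CalibrationSample]):
    rows = []
    for t, s in zip(times, samples):
        rows.append(np.concatenate([
            [t], s.a_S, s.omega, s.omega_dot,
            _matrix_to_quat(s.R_L), _matrix_to_quat(s.R_S), s.o_ddot_L]))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
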