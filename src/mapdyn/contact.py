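"""Offline gait contact classification from vertical shoe forces.

Each sample is labelled double / right / left support by comparing the
two vertical force channels against a self-tuned threshold: the mean of
the summed channels (roughly body weight), optionally scaled.  With the
literal threshold almost every gait sample classifies as double support
— the ``scale`` parameter shrinks the double-support band; ``scale=1``
keeps the literal rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DOUBLE, RIGHT, LEFT = "double", "right", "left"


@dataclass(frozen=True)
class VerticalForcePair:
    """Vertical (z) force time series for the right and left shoe [N]."""

    rf_fz: np.ndarray
    lf_fz: np.ndarray

    def __post_init__(self):
        rf = np.atleast_1d(np.asarray(self.rf_fz, float))
        lf = np.atleast_1d(np.asarray(self.lf_fz, float))
        if rf.shape != lf.shape or rf.ndim != 1:
            raise ValueError("rf_fz and lf_fz must be 1-D series of equal "
                             "length")
        if rf.size == 0:
            raise ValueError("force series must contain at least one sample")
        if not (np.isfinite(rf).all() and np.isfinite(lf).all()):
            raise ValueError("force series contain non-finite values")
        object.__setattr__(self, "rf_fz", rf)
        object.__setattr__(self, "lf_fz", lf)

    def __len__(self) -> int:
        return self.rf_fz.size


@dataclass(frozen=True)
class ContactSet:
    """Per-sample support labels plus the names of the contact frames."""

    labels: np.ndarray
    right_frame: str = "RF"
    left_frame: str = "LF"

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        bad = set(labels) - {DOUBLE, RIGHT, LEFT}
        if bad:
            raise ValueError(f"unknown contact labels: {bad}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.labels.size

    def frames_at(self, j: int) -> list[str]:
        """Contact frame names active at sample ``j``."""
        label = self.labels[j]
        if label == DOUBLE:
            return [self.right_frame, self.left_frame]
        return [self.right_frame if label == RIGHT else self.left_frame]


def compute_threshold(forces: VerticalForcePair, scale: float = 1.0) -> float:
    """Self-tuned threshold: ``scale * mean(RF_fz + LF_fz)``."""
    if len(forces) == 0:
        raise ValueError("empty force series")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    return float(scale * np.mean(forces.rf_fz + forces.lf_fz))


def classify_contacts(forces: VerticalForcePair, threshold: float,
                      right_frame: str = "RF",
                      left_frame: str = "LF") -> ContactSet:
    """Label every sample as double, right or left support.

    ``|RF_fz - LF_fz| <= threshold`` is double support; otherwise the foot
    with the larger vertical force is the single stance foot.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    diff = forces.rf_fz - forces.lf_fz
    labels = np.where(np.abs(diff) <= threshold, DOUBLE,
                      np.where(diff > 0, RIGHT, LEFT)).astype(object)
    return ContactSet(labels, right_frame, left_frame)


def min_duration_filter(contacts: ContactSet, min_samples: int) -> ContactSet:
    """Optional debouncing: absorb label runs shorter than ``min_samples``
    into the preceding run.  Off by default in the pipeline."""
    labels = np.array(contacts.labels, dtype=object)
    n = labels.size
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if 0 < i and (j - i) < min_samples:
            labels[i:j] = labels[i - 1]
        i = j
    return ContactSet(labels, contacts.right_frame, contacts.left_frame)


def read_forces_csv(path) -> tuple[np.ndarray, VerticalForcePair]:
    """CSV with columns ``time, rf_fz, lf_fz``."""
    df = pd.read_csv(path)
    for col in ("time", "rf_fz", "lf_fz"):
        if col not in df.columns:
            raise ValueError(f"force CSV is missing column {col!r}")
    return (df["time"].to_numpy(float),
            VerticalForcePair(df["rf_fz"].to_numpy(float),
                              df["lf_fz"].to_numpy(float)))


def write_labels_csv(path, times, contacts: ContactSet) -> None:
    pd.DataFrame({"time": times, "label": contacts.labels}
                 ).to_csv(path, index=False)
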