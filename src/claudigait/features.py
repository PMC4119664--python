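"""The nine gait features used to differentiate normal, PAD, L5 and L4
walking, computed from one mean gait cycle.

Feature definitions (fixed order, names used everywhere downstream):

1. ``mean_ankle_angle``          -- mean of q4 over the cycle [rad]
2. ``knee_angle_at_stance_start`` -- mean of q3 over the window ending at
   the stance start (the 4 raw frames before it plus the stance frame,
   rescaled when the cycle has been resampled) [rad]
3. ``femur_amplitude``           -- peak-to-peak range of q2 [rad]
4-6. ``gastroc_max_relaxed``, ``gastroc_max_contracted``, ``gastroc_rom``
   -- per-cycle max, min and range of the normalized gastrocnemius
   length [reference mm]
7-9. ``quad_max_relaxed``, ``quad_max_contracted``, ``quad_rom`` -- the
   same for the normalized quadriceps length.

"Maximally relaxed" is the longest length reached over the cycle and
"maximally contracted" the shortest, so ``rom = relaxed - contracted``
holds exactly and is never negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import GaitCycle, compute_angles, detect_stance_starts, mean_cycle
from .reference_model import (
    ReferenceSkeleton,
    default_skeleton,
    gastrocnemius_length,
    quadriceps_length,
)

FEATURE_NAMES = (
    "mean_ankle_angle",
    "knee_angle_at_stance_start",
    "femur_amplitude",
    "gastroc_max_relaxed",
    "gastroc_max_contracted",
    "gastroc_rom",
    "quad_max_relaxed",
    "quad_max_contracted",
    "quad_rom",
)

#: Raw-frame width of the pre-stance knee window (frames before the
#: stance-start frame, at the native frame rate).
STANCE_WINDOW_RAW = 4


@dataclass(frozen=True)
class FeatureVector:
    """The nine differentiation features for one subject."""

    mean_ankle_angle: float
    knee_angle_at_stance_start: float
    femur_amplitude: float
    gastroc_max_relaxed: float
    gastroc_max_contracted: float
    gastroc_rom: float
    quad_max_relaxed: float
    quad_max_contracted: float
    quad_rom: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("features must be finite")
        if self.gastroc_rom < 0 or self.quad_rom < 0:
            raise ValueError("muscle range of motion cannot be negative")
        for muscle in ("gastroc", "quad"):
            if getattr(self, f"{muscle}_max_relaxed") <= 0 or getattr(self, f"{muscle}_max_contracted") <= 0:
                raise ValueError("muscle lengths must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def mean_ankle_angle(cycle: GaitCycle) -> float:
    """Arithmetic mean of the ankle angle q4 over the cycle [rad]."""
    return float(np.mean(cycle.q4))


def stance_window_length(cycle: GaitCycle) -> int:
    """Pre-stance knee-window width in (possibly resampled) cycle frames.

    The window is defined as 4 raw frames; on a resampled mean cycle it is
    rescaled by cycle_length / source_cycle_length and rounded to the
    nearest frame (minimum 1).
    """
    if cycle.source_cycle_length is None:
        return STANCE_WINDOW_RAW
    scaled = STANCE_WINDOW_RAW * cycle.length / cycle.source_cycle_length
    return max(1, int(round(scaled)))


def knee_angle_at_stance_start(cycle: GaitCycle, window: int | None = None) -> float:
    """Mean knee angle q3 over the ``window + 1`` frames ending at the
    stance start, indexed cyclically (the mean cycle is periodic) [rad]."""
    w = stance_window_length(cycle) if window is None else int(window)
    if w < 1:
        raise ValueError("window must be >= 1")
    if cycle.length < w + 1:
        raise ValueError("cycle shorter than the stance window")
    idx = (cycle.stance_start_index + np.arange(-w, 1)) % cycle.length
    return float(np.mean(cycle.q3[idx]))


def femur_amplitude(cycle: GaitCycle) -> float:
    """Peak-to-peak range (max - min) of the femur angle q2 [rad]."""
    return float(np.max(cycle.q2) - np.min(cycle.q2))


def muscle_features(cycle: GaitCycle, skel: ReferenceSkeleton | None = None) -> dict[str, float]:
    """Per-cycle max ("maximally relaxed"), min ("maximally contracted")
    and range of motion of both normalized muscle lengths."""
    if skel is None:
        skel = default_skeleton()
    gastroc = gastrocnemius_length(cycle.q3, cycle.q4, skel)
    quad = quadriceps_length(cycle.q1, cycle.q2, cycle.q3, skel)
    out = {}
    for name, series in (("gastroc", np.asarray(gastroc)), ("quad", np.asarray(quad))):
        hi, lo = float(np.max(series)), float(np.min(series))
        out[f"{name}_max_relaxed"] = hi
        out[f"{name}_max_contracted"] = lo
        out[f"{name}_rom"] = hi - lo
    return out


def extract_features(cycle: GaitCycle, skel: ReferenceSkeleton | None = None) -> FeatureVector:
    """Assemble the nine differentiation features from one mean cycle."""
    return FeatureVector(
        mean_ankle_angle=mean_ankle_angle(cycle),
        knee_angle_at_stance_start=knee_angle_at_stance_start(cycle),
        femur_amplitude=femur_amplitude(cycle),
        **muscle_features(cycle, skel),
    )


def subject_features(
    traj,
    skel: ReferenceSkeleton | None = None,
    cycle_length: int = 100,
) -> FeatureVector:
    """Full per-subject pipeline: markers -> angles -> stance starts ->
    mean cycle -> features."""
    angles = compute_angles(traj)
    starts = detect_stance_starts(traj)
    cycle = mean_cycle(angles, starts, length=cycle_length)
    return extract_features(cycle, skel)


def cohort_feature_matrix(
    subjects,
    skel: ReferenceSkeleton | None = None,
    cycle_length: int = 100,
) -> pd.DataFrame:
    """Feature matrix for an iterable of (subject_id, class_label,
    trajectory) records (e.g. ``Cohort.subjects``): one row per subject,
    columns ``subject_id``, ``class`` and the nine features."""
    rows = []
    for rec in subjects:
        subject_id, label, traj = rec.subject_id, rec.class_label, rec.trajectory
        fv = subject_features(traj, skel, cycle_length)
        row = {"subject_id": subject_id, "class": label}
        row.update(dict(zip(FEATURE_NAMES, fv.as_array())))
        rows.append(row)
    return pd.DataFrame(rows)
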