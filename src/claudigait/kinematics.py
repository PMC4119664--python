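"""Sagittal-plane gait kinematics: marker trajectories -> joint-angle series
-> stance-phase segmentation -> mean gait cycle.

Angle conventions (THE convention of this package; radians everywhere):

* ``q1`` -- upper-body angle: orientation of the acromion->ASIS segment
  relative to the downward vertical, offset so a vertical trunk gives
  ``q1 = pi`` and forward lean gives ``q1 > pi``.
* ``q2`` -- femur angle: same construction for the ASIS->fibular-head
  segment (``pi`` = thigh vertical, ``> pi`` = thigh advanced).
* ``q3`` -- knee angle: interior angle at the fibular head between the
  thigh and shank segments; a fully extended knee gives ``q3 = pi``
  (180 degrees) and flexion reduces it.
* ``q4`` -- ankle angle: interior angle at the lateral malleolus between
  the shank (pointing up toward the knee) and the foot segment; shank
  vertical with a horizontal foot gives ``q4 = pi/2``, plantarflexion
  (toes down) increases it, dorsiflexion decreases it.

All angles are reported wrapped into ``[0, 2*pi)`` and depend only on
marker geometry, so they are invariant to translation and uniform scaling
of the coordinates.  Mirroring the x axis reflects every angle about its
neutral value (``q -> 2*pi - q``, modulo ``2*pi``); the tests pin this
equivariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

#: Marker names in proximal-to-distal chain order (shoulder to toe).
MARKER_NAMES = (
    "acromion",
    "anterior_superior_iliac",
    "fibular_head",
    "lateral_malleolus",
    "fifth_metatarsal_head",
)

#: Body segments as (name, proximal marker index, distal marker index).
SEGMENTS = (
    ("trunk", 0, 1),
    ("thigh", 1, 2),
    ("shank", 2, 3),
    ("foot", 3, 4),
)

_COINCIDENT_TOL = 1e-9


@dataclass
class MarkerTrajectory:
    """Per-frame 2-D positions of the five sagittal markers.

    ``positions`` has shape ``(n_frames, 5, 2)`` with markers ordered as
    :data:`MARKER_NAMES` and coordinates ``(x forward, y up)``.
    """

    positions: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (5, 2):
            raise ValueError(
                f"positions must have shape (n_frames, 5, 2), got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("marker coordinates must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def marker(self, name: str) -> np.ndarray:
        """(n_frames, 2) trace of one named marker."""
        return self.positions[:, MARKER_NAMES.index(name), :]

    def to_frame(self) -> pd.DataFrame:
        cols = {"frame": np.arange(self.n_frames)}
        for i, name in enumerate(MARKER_NAMES):
            cols[f"{name}_x"] = self.positions[:, i, 0]
            cols[f"{name}_y"] = self.positions[:, i, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float = 30.0) -> "MarkerTrajectory":
        pos = np.empty((len(df), 5, 2))
        for i, name in enumerate(MARKER_NAMES):
            pos[:, i, 0] = df[f"{name}_x"].to_numpy(float)
            pos[:, i, 1] = df[f"{name}_y"].to_numpy(float)
        return cls(pos, frame_rate=frame_rate)

    @classmethod
    def from_csv(cls, path, frame_rate: float = 30.0) -> "MarkerTrajectory":
        return cls.from_frame(pd.read_csv(path), frame_rate=frame_rate)


@dataclass
class AngleSeries:
    """Per-frame values of the four sagittal angles, shape ``(n_frames, 4)``
    ordered ``(q1 upper body, q2 femur, q3 knee, q4 ankle)``."""

    values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"values must have shape (n_frames, 4), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angles must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def q1(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def q2(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def q3(self) -> np.ndarray:
        return self.values[:, 2]

    @property
    def q4(self) -> np.ndarray:
        return self.values[:, 3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "q1": self.q1,
                "q2": self.q2,
                "q3": self.q3,
                "q4": self.q4,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float = 30.0) -> "AngleSeries":
        df = pd.read_csv(path)
        return cls(df[["q1", "q2", "q3", "q4"]].to_numpy(float), frame_rate=frame_rate)


@dataclass
class GaitCycle:
    """One mean gait cycle: angle series resampled to a fixed length.

    ``stance_start_index`` is 0 by construction (cycles run stance start to
    stance start).  ``source_cycle_length`` records the mean length, in
    original frames, of the cycles that were averaged; feature windows
    defined on raw frames are rescaled with it.
    """

    values: np.ndarray
    stance_start_index: int = 0
    source_cycle_length: float | None = None
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("cycle values must have shape (length, 4)")
        if self.length < 10:
            raise ValueError("cycle length must be >= 10")
        if not 0 <= self.stance_start_index < self.length:
            raise ValueError("stance_start_index out of range")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def q1(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def q2(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def q3(self) -> np.ndarray:
        return self.values[:, 2]

    @property
    def q4(self) -> np.ndarray:
        return self.values[:, 3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.length), "q1": self.q1, "q2": self.q2,
             "q3": self.q3, "q4": self.q4}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles into [0, 2*pi)."""
    return np.mod(angle, TWO_PI)


def _vertical_angle(d: np.ndarray) -> np.ndarray:
    """Signed angle of segment vectors ``d`` from the downward vertical,
    positive when the distal end is forward (+x)."""
    return np.arctan2(d[..., 0], -d[..., 1])


def compute_angles(traj: MarkerTrajectory) -> AngleSeries:
    """Derive the four sagittal angle series from marker positions.

    Raises ``ValueError`` naming the frame and segment if two adjacent
    markers coincide in any frame (the segment direction is undefined).
    """
    p = traj.positions
    for name, i, j in SEGMENTS:
        norms = np.linalg.norm(p[:, j] - p[:, i], axis=1)
        bad = np.nonzero(norms < _COINCIDENT_TOL)[0]
        if bad.size:
            raise ValueError(
                f"coincident markers on segment '{name}' at frame {int(bad[0])}"
            )

    d_trunk = p[:, 1] - p[:, 0]
    d_thigh = p[:, 2] - p[:, 1]
    d_shank = p[:, 3] - p[:, 2]
    d_foot = p[:, 4] - p[:, 3]

    a_trunk = _vertical_angle(d_trunk)
    a_thigh = _vertical_angle(d_thigh)
    a_shank = _vertical_angle(d_shank)
    theta_foot = np.arctan2(d_foot[:, 1], d_foot[:, 0])

    q1 = _wrap(np.pi + a_trunk)
    q2 = _wrap(np.pi + a_thigh)
    q3 = _wrap(np.pi + a_shank - a_thigh)
    q4 = _wrap(np.pi / 2.0 + a_shank - theta_foot)
    return AngleSeries(np.column_stack([q1, q2, q3, q4]), frame_rate=traj.frame_rate)


def _local_maxima(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and heights of strict-or-plateau local maxima of ``x``.

    A maximal run of equal values is one candidate, reported at its first
    frame (ties broken toward the earlier frame).  Runs touching either end
    of the series are not counted (no confirming neighbour).
    """
    n = x.size
    starts: list[int] = []
    heights: list[float] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        interior = i > 0 and j < n - 1
        if interior and x[i - 1] < x[i] and x[j + 1] < x[i]:
            starts.append(i)
            heights.append(x[i])
        i = j + 1
    return np.asarray(starts, dtype=int), np.asarray(heights, dtype=float)


def detect_stance_starts(traj, min_prominence_fraction: float = 0.15) -> np.ndarray:
    """Detect stance-phase starts: frames where the fifth-metatarsal
    forward (x) coordinate is locally maximal.

    Accepts a :class:`MarkerTrajectory` or a bare 1-D x series.  A frame is
    a stance start if its value is >= both neighbours and exceeds the
    series mean (this suppresses small maxima far from the forward
    extreme); plateau ties resolve to the earlier frame.  As a guard
    against measurement noise splitting the rounded forward extreme into
    several nearby maxima, candidates whose topographic prominence is
    below ``min_prominence_fraction`` of the series range are dropped --
    noise bumps riding on the forward plateau have prominence of the
    noise scale, while each true per-cycle extreme carries most of the
    stride's excursion.

    Raises ``ValueError('no gait cycle detected')`` when no qualifying
    maximum exists (e.g. monotone or constant series).
    """
    if isinstance(traj, MarkerTrajectory):
        x = traj.marker("fifth_metatarsal_head")[:, 0]
    else:
        x = np.asarray(traj, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("no gait cycle detected")

    idx, height = _local_maxima(x)
    above = height > x.mean()
    idx, height = idx[above], height[above]
    if idx.size == 0:
        raise ValueError("no gait cycle detected")

    if idx.size > 1 and min_prominence_fraction > 0:
        from scipy.signal import peak_prominences

        prom = peak_prominences(x, idx)[0]
        keep = prom >= min_prominence_fraction * (x.max() - x.min())
        if keep.any():
            idx, height = idx[keep], height[keep]
    return idx


def mean_cycle(
    angles: AngleSeries,
    stance_starts,
    length: int = 100,
) -> GaitCycle:
    """Average all complete stance-to-stance cycles into one mean cycle.

    Each inter-stance segment is resampled to ``length`` frames by linear
    interpolation and the segments are averaged pointwise.  Requires at
    least two stance starts (one complete cycle).
    """
    starts = np.asarray(stance_starts, dtype=int)
    if starts.size < 2:
        raise ValueError("need >= 2 stance starts (one complete cycle)")
    if length < 10:
        raise ValueError("cycle length must be >= 10")
    if np.any(np.diff(starts) <= 0):
        raise ValueError("stance starts must be strictly increasing")
    if starts[-1] >= angles.n_frames:
        raise ValueError("stance start beyond end of series")

    seg_lengths = np.diff(starts)
    med = np.median(seg_lengths)
    resampled = []
    used_lengths = []
    for s, e in zip(starts[:-1], starts[1:]):
        if (e - s) < 0.5 * med:
            continue  # spurious short segment (split peak); skip
        t = s + np.arange(length) * (e - s) / length
        frames = np.arange(s, e + 1)
        seg = np.column_stack(
            [np.interp(t, frames, angles.values[s : e + 1, k]) for k in range(4)]
        )
        resampled.append(seg)
        used_lengths.append(e - s)
    mean_vals = np.mean(resampled, axis=0)
    return GaitCycle(
        mean_vals,
        stance_start_index=0,
        source_cycle_length=float(np.mean(used_lengths)),
        frame_rate=angles.frame_rate,
    )
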