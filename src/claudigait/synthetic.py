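"""Synthetic gait-cohort generator.

No clinical recordings ship with this package, so every downstream stage
is exercised on synthetic cohorts that reproduce the *feature-level*
structure of the four groups (normal, PAD, L5, L4):

* PAD walks plantarflexed (large mean ankle angle, short gastrocnemius);
* L5 walks dorsiflexed and shuffling (small ankle angle, small leg lift,
  long gastrocnemius, small muscle ranges of motion);
* L4 lands with the knee extended close to 180 degrees and keeps the
  quadriceps contracted;
* normal shows the largest femur amplitude, leg lift and muscle ranges
  of motion.

Waveforms are sums of at most three sinusoidal harmonics per angle -- the
simplest smooth periodic family whose parameters steer each feature
independently.  The generator targets these class contrasts only; it does
not emulate ground-reaction dynamics or realistic inter-joint timing.

Angles follow the package convention (see :mod:`claudigait.kinematics`);
all angles are radians, treadmill walking is assumed so markers oscillate
about fixed mean positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import AngleSeries, MarkerTrajectory

CLASS_LABELS = ("normal", "PAD", "L5", "L4")


@dataclass(frozen=True)
class ClassSignature:
    """Per-class deviations from a neutral gait that drive the nine
    differentiation features.

    ``ankle_offset`` shifts the mean ankle angle [rad];
    ``knee_stance_target`` is the knee angle held over the pre-stance
    window [rad]; ``femur_amplitude_scale`` scales the thigh excursion;
    ``leg_lift_scale`` scales swing-phase knee flexion and ankle
    excursion (foot clearance, hence muscle ranges of motion);
    ``quad_contraction_bias`` biases the knee toward extension [rad],
    shortening the quadriceps' most-contracted length.
    """

    class_label: str
    ankle_offset: float = 0.0
    knee_stance_target: float = 2.85
    femur_amplitude_scale: float = 1.0
    leg_lift_scale: float = 1.0
    quad_contraction_bias: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.ankle_offset,
            self.knee_stance_target,
            self.femur_amplitude_scale,
            self.leg_lift_scale,
            self.quad_contraction_bias,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("signature parameters must be finite")
        if self.femur_amplitude_scale <= 0 or self.leg_lift_scale <= 0:
            raise ValueError("scale parameters must be > 0")


#: Neutral gait about which class effects are expressed; effect_scale
#: interpolates every signature toward this point, so effect_scale = 0
#: makes all classes identical.
NEUTRAL_SIGNATURE = ClassSignature("neutral")

#: Default class signatures.  Chosen to realise the reported group
#: orderings: PAD > normal = L4 > L5 on the ankle offset; L4 maximal on
#: the knee-at-stance target (close to 180 degrees); normal maximal on
#: femur amplitude; normal maximal and L5 minimal on leg lift.
DEFAULT_SIGNATURES = {
    "normal": ClassSignature(
        "normal", ankle_offset=0.0, knee_stance_target=2.85,
        femur_amplitude_scale=1.15, leg_lift_scale=1.15, quad_contraction_bias=0.0,
    ),
    "PAD": ClassSignature(
        "PAD", ankle_offset=0.12, knee_stance_target=2.85,
        femur_amplitude_scale=0.85, leg_lift_scale=0.90, quad_contraction_bias=0.0,
    ),
    "L5": ClassSignature(
        "L5", ankle_offset=-0.12, knee_stance_target=2.80,
        femur_amplitude_scale=0.80, leg_lift_scale=0.70, quad_contraction_bias=0.0,
    ),
    "L4": ClassSignature(
        "L4", ankle_offset=0.0, knee_stance_target=3.10,
        femur_amplitude_scale=0.90, leg_lift_scale=1.00, quad_contraction_bias=0.08,
    ),
}


@dataclass(frozen=True)
class SegmentLengths:
    """Marker-chain segment lengths [mm] for forward kinematics."""

    trunk: float = 500.0
    thigh: float = 440.0
    shank: float = 400.0
    foot: float = 150.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"segment length '{f.name}' must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort geometry, variability and reproducibility settings.

    Defaults mirror the study conditions this generator stands in for:
    group sizes 13/10/13/10, 30 frames/s video, and frame-level angular
    noise within the quoted 0.007-0.04 rad measurement accuracy band.
    ``subject_sd`` [rad] jitters each subject's waveform parameters
    (between-subject variability); ``effect_scale`` in [0, 1] scales all
    class effects (0 = identical classes).  The same seed and config give
    a bit-identical cohort.
    """

    n_per_class: dict = field(
        default_factory=lambda: {"normal": 13, "PAD": 10, "L5": 13, "L4": 10}
    )
    cycle_length: int = 30
    n_cycles: int = 10
    frame_rate: float = 30.0
    subject_sd: float = 0.03
    noise_sd: float = 0.02
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("counts must be >= 1")
        if self.cycle_length < 10:
            raise ValueError("cycle_length must be >= 10")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be >= 0")
        if not 0.0 <= self.effect_scale <= 1.0:
            raise ValueError("effect_scale must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _effective_signature(sig: ClassSignature, effect_scale: float) -> ClassSignature:
    """Interpolate a signature toward the neutral gait by effect_scale."""
    n = NEUTRAL_SIGNATURE
    lerp = lambda a, b: b + effect_scale * (a - b)
    return ClassSignature(
        sig.class_label,
        ankle_offset=lerp(sig.ankle_offset, n.ankle_offset),
        knee_stance_target=lerp(sig.knee_stance_target, n.knee_stance_target),
        femur_amplitude_scale=lerp(sig.femur_amplitude_scale, n.femur_amplitude_scale),
        leg_lift_scale=lerp(sig.leg_lift_scale, n.leg_lift_scale),
        quad_contraction_bias=lerp(sig.quad_contraction_bias, n.quad_contraction_bias),
    )


# base-waveform constants (radians unless noted); see docs/methods.md
_TRUNK_LEAN = 0.06
_TRUNK_SWAY = 0.02
_FEMUR_HALF_AMPLITUDE = 0.30
_KNEE_TONIC_FLEXION = 0.08
_KNEE_SWING_FLEXION = 0.85
_KNEE_SWING_PHASE = 0.72      # cycle fraction of peak swing flexion
_KNEE_FLEXION_FLOOR = 0.02
_ANKLE_NEUTRAL = np.pi / 2 + 0.10
_ANKLE_AMP_1 = 0.12
_ANKLE_AMP_2 = 0.06
# smooth blend weights for the knee pull toward the stance target, at
# frame offsets -6..+2 relative to each stance start (full pull on the
# 5-frame feature window -4..0)
_PULL_OFFSETS = np.arange(-6, 3)
_PULL_WEIGHTS = np.array([0.35, 0.7, 1.0, 1.0, 1.0, 1.0, 1.0, 0.7, 0.35])


def generate_angle_waveforms(
    sig: ClassSignature,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> AngleSeries:
    """One subject's four angle series over ``n_cycles`` gait cycles.

    Smooth periodic base waveforms (at most three harmonics per angle)
    with the signature's offsets and scales applied, per-subject
    parameter jitter ~ Normal(0, subject_sd) and additive frame noise
    ~ Normal(0, noise_sd).  The knee angle over the 5 frames ending at
    each stance start is pulled toward ``knee_stance_target``.  Stance
    starts (forward extreme of the foot) fall at a per-subject random
    frame offset, once per cycle.
    """
    eff = _effective_signature(sig, cfg.effect_scale)
    P = cfg.cycle_length
    n_frames = cfg.n_cycles * P + 1

    ssd = cfg.subject_sd
    d_ankle = rng.normal(0.0, ssd)
    d_lean = rng.normal(0.0, ssd)
    m_femur = max(0.1, 1.0 + rng.normal(0.0, ssd))
    m_lift = max(0.1, 1.0 + rng.normal(0.0, ssd))
    d_target = rng.normal(0.0, ssd)
    phase0 = int(rng.integers(0, P))

    k = np.arange(n_frames)
    phi = ((k - phase0) % P) / P

    femur_amp = _FEMUR_HALF_AMPLITUDE * eff.femur_amplitude_scale * m_femur
    lift = eff.leg_lift_scale * m_lift

    q1 = np.pi + _TRUNK_LEAN + d_lean + _TRUNK_SWAY * np.cos(4 * np.pi * phi)
    q2 = np.pi + femur_amp * np.cos(2 * np.pi * phi)

    bump = ((1.0 + np.cos(2 * np.pi * (phi - _KNEE_SWING_PHASE))) / 2.0) ** 2
    flexion = _KNEE_TONIC_FLEXION + _KNEE_SWING_FLEXION * lift * bump
    flexion = np.maximum(flexion - eff.quad_contraction_bias, _KNEE_FLEXION_FLOOR)
    q3 = np.pi - flexion

    target = eff.knee_stance_target + d_target
    offset_in_cycle = (k - phase0) % P
    for off, w in zip(_PULL_OFFSETS, _PULL_WEIGHTS):
        sel = offset_in_cycle == (off % P)
        q3[sel] += w * (target - q3[sel])

    q4 = (
        _ANKLE_NEUTRAL
        + eff.ankle_offset
        + d_ankle
        + lift * (_ANKLE_AMP_1 * np.sin(2 * np.pi * phi) + _ANKLE_AMP_2 * np.sin(4 * np.pi * phi + 0.8))
    )

    values = np.column_stack([q1, q2, q3, q4])
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    return AngleSeries(values, frame_rate=cfg.frame_rate)


def angles_to_markers(
    angles: AngleSeries | np.ndarray,
    segment_lengths: SegmentLengths | None = None,
    frame_rate: float | None = None,
) -> MarkerTrajectory:
    """Forward kinematics: place the five markers so that
    :func:`claudigait.kinematics.compute_angles` recovers the input
    angles exactly (round-trip identity, noise-free).

    The ASIS marker is held at a fixed point (treadmill walking: markers
    oscillate about fixed mean positions); x is forward, y is up.
    """
    if segment_lengths is None:
        segment_lengths = SegmentLengths()
    if isinstance(angles, AngleSeries):
        vals = angles.values
        fr = angles.frame_rate if frame_rate is None else frame_rate
    else:
        vals = np.asarray(angles, dtype=float)
        fr = 30.0 if frame_rate is None else frame_rate
    q1, q2, q3, q4 = vals[:, 0], vals[:, 1], vals[:, 2], vals[:, 3]

    a1 = q1 - np.pi
    a2 = q2 - np.pi
    a3 = a2 + q3 - np.pi          # shank angle from the downward vertical
    theta_f = np.pi / 2 + a3 - q4  # foot direction from +x

    n = vals.shape[0]
    asis = np.broadcast_to(np.array([0.0, 1000.0]), (n, 2))
    down = lambda a, L: L * np.column_stack([np.sin(a), -np.cos(a)])
    acromion = asis - down(a1, segment_lengths.trunk)
    fibular = asis + down(a2, segment_lengths.thigh)
    malleolus = fibular + down(a3, segment_lengths.shank)
    metatarsal = malleolus + segment_lengths.foot * np.column_stack(
        [np.cos(theta_f), np.sin(theta_f)]
    )
    positions = np.stack([acromion, asis, fibular, malleolus, metatarsal], axis=1)
    return MarkerTrajectory(positions, frame_rate=fr)


@dataclass
class SubjectRecord:
    subject_id: str
    class_label: str
    trajectory: MarkerTrajectory
    angles: AngleSeries
    params: dict


@dataclass
class Cohort:
    """A labeled synthetic cohort: one marker trajectory per subject plus
    the ground-truth class manifest."""

    subjects: list
    config: CohortConfig
    signatures: dict

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "class": [s.class_label for s in self.subjects],
            }
        )

    def write(self, directory) -> None:
        """Write one trajectory CSV per subject plus manifest and config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            s.trajectory.to_csv(directory / f"{s.subject_id}.csv")
        self.manifest.to_csv(directory / "manifest.csv", index=False)
        self.config.to_yaml(directory / "config.yaml")


def read_cohort(directory) -> Cohort:
    """Load a cohort previously written with :meth:`Cohort.write`.

    Angle series and generator parameters are not stored on disk, so the
    loaded records carry trajectories only.
    """
    directory = Path(directory)
    cfg = CohortConfig.from_yaml(directory / "config.yaml")
    manifest = pd.read_csv(directory / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        traj = MarkerTrajectory.from_csv(
            directory / f"{row.subject_id}.csv", frame_rate=cfg.frame_rate
        )
        subjects.append(SubjectRecord(row.subject_id, row["class"], traj, None, {}))
    return Cohort(subjects, cfg, {})


def generate_cohort(
    signatures: dict | None = None,
    cfg: CohortConfig | None = None,
    segment_lengths: SegmentLengths | None = None,
) -> Cohort:
    """Generate a labeled cohort (default 13/10/13/10 = 46 subjects).

    Reproducible: the same (signatures, cfg) give a bit-identical cohort.
    Rejects duplicate or mismatched class labels.
    """
    if signatures is None:
        signatures = DEFAULT_SIGNATURES
    if cfg is None:
        cfg = CohortConfig()
    labels = [s.class_label for s in signatures.values()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in signatures")
    for key, sig in signatures.items():
        if key != sig.class_label:
            raise ValueError(f"signature key {key!r} != label {sig.class_label!r}")
    missing = set(cfg.n_per_class) - set(signatures)
    if missing:
        raise ValueError(f"no signature for classes {sorted(missing)}")

    root = np.random.SeedSequence(cfg.seed)
    total = sum(cfg.n_per_class.values())
    children = root.spawn(total)

    ordered = [l for l in CLASS_LABELS if l in cfg.n_per_class]
    ordered += [l for l in cfg.n_per_class if l not in ordered]
    subjects = []
    child_iter = iter(children)
    for label in ordered:
        sig = signatures[label]
        for i in range(cfg.n_per_class[label]):
            rng = np.random.default_rng(next(child_iter))
            angles = generate_angle_waveforms(sig, cfg, rng)
            traj = angles_to_markers(angles, segment_lengths)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{label}_{i:02d}",
                    class_label=label,
                    trajectory=traj,
                    angles=angles,
                    params={"signature": dataclasses.asdict(_effective_signature(sig, cfg.effect_scale))},
                )
            )
    return Cohort(subjects, cfg, dict(signatures))
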