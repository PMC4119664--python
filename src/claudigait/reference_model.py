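"""Reference-skeleton muscle geometry: joint angles -> normalized
biarticular muscle lengths.

Muscle lengths cannot be compared across people directly because they
scale with body size.  Instead, every subject's joint angles are applied
to one fixed reference skeleton and the origin-to-insertion distances of
the two biarticular muscles of interest are measured on that skeleton:

* gastrocnemius -- spans knee and ankle; origin on the posterior distal
  femur, insertion on the calcaneus.  Plantarflexion (large ankle angle)
  brings the heel toward the calf and shortens it.
* quadriceps (rectus femoris path) -- spans hip and knee; origin on the
  anterior pelvis near the hip, insertion on the tibial tuberosity.  Knee
  flexion stretches it; the path wraps a circular patellar surface at the
  knee when the straight line would penetrate it.

The outputs ("normalized muscle lengths", reference millimetres) contain
no subject parameter, so they are comparable across subjects by
construction.

Segment frames for attachment coordinates, each written ``(axial,
anterior)``:

* femur frame: origin at the knee centre, axial toward the hip;
* pelvis frame: origin at the hip centre, axial toward the shoulder
  (moves with the upper-body angle, so the hip angle stretches the
  quadriceps origin away from the knee);
* shank frame: origin at the knee centre, axial toward the ankle;
* foot frame: origin at the ankle centre, axial toward the toes.

The reference geometry is an explicit package choice of anatomical
order-of-magnitude values; only the ordinal (monotone) angle-to-length
behaviour matters downstream, and that is what the tests pin.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .kinematics import TWO_PI


@dataclass(frozen=True)
class ReferenceSkeleton:
    """Bone lengths (mm) and 2-D muscle attachment points of the fixed
    reference skeleton.  Attachment points are ``(axial, anterior)``
    coordinates in the segment frames documented in the module docstring.
    """

    trunk_length: float = 500.0
    femur_length: float = 430.0
    shank_length: float = 410.0
    foot_length: float = 200.0
    # gastrocnemius: posterior distal femur -> calcaneus
    gastroc_origin: tuple[float, float] = (30.0, -25.0)      # femur frame
    gastroc_insertion: tuple[float, float] = (-50.0, 0.0)    # foot frame
    # quadriceps (rectus femoris): anterior pelvis -> tibial tuberosity
    quad_origin: tuple[float, float] = (-20.0, 30.0)         # pelvis frame
    quad_insertion: tuple[float, float] = (40.0, 25.0)       # shank frame
    patella_radius: float = 25.0

    def __post_init__(self) -> None:
        lengths = {
            "trunk_length": self.trunk_length,
            "femur_length": self.femur_length,
            "shank_length": self.shank_length,
            "foot_length": self.foot_length,
        }
        for name, val in lengths.items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be a positive finite length")
        if self.patella_radius < 0 or not np.isfinite(self.patella_radius):
            raise ValueError("patella_radius must be >= 0")
        extents = {
            "gastroc_origin": self.femur_length,
            "gastroc_insertion": self.foot_length,
            "quad_origin": self.trunk_length,
            "quad_insertion": self.shank_length,
        }
        for name, extent in extents.items():
            ax, ant = getattr(self, name)
            if not (np.isfinite(ax) and np.isfinite(ant)):
                raise ValueError(f"{name} must be finite")
            if abs(ax) > extent or abs(ant) > extent:
                raise ValueError(f"{name} lies outside its segment extent")
        # the quadriceps insertion must sit outside the patellar circle
        if np.hypot(*self.quad_insertion) <= self.patella_radius:
            raise ValueError("quad_insertion lies inside the patellar wrap circle")
        # normalise tuples so serialization round-trips exactly
        object.__setattr__(self, "gastroc_origin", tuple(map(float, self.gastroc_origin)))
        object.__setattr__(self, "gastroc_insertion", tuple(map(float, self.gastroc_insertion)))
        object.__setattr__(self, "quad_origin", tuple(map(float, self.quad_origin)))
        object.__setattr__(self, "quad_insertion", tuple(map(float, self.quad_insertion)))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("gastroc_origin", "gastroc_insertion", "quad_origin", "quad_insertion"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceSkeleton":
        d = dict(d)
        for key in ("gastroc_origin", "gastroc_insertion", "quad_origin", "quad_insertion"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceSkeleton":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_skeleton() -> ReferenceSkeleton:
    """The package's fixed default reference skeleton (deterministic)."""
    return ReferenceSkeleton()


def _check_angles(*angles) -> list[np.ndarray]:
    out = []
    for a in angles:
        arr = np.asarray(a, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("angles must be finite")
        if np.any(arr <= 0) or np.any(arr >= TWO_PI):
            raise ValueError("angles must lie in the open interval (0, 2*pi)")
        out.append(arr)
    return out


def _femur_axis(knee):
    """Unit vector from the knee toward the hip, in the knee-centred frame
    where the shank points straight down.  ``knee`` is the interior knee
    angle q3; extension (q3 = pi) puts the femur straight up and flexion
    swings the hip posteriorly (-x)."""
    return np.stack([-np.sin(knee), -np.cos(knee)], axis=-1)


def _anterior(u):
    """Anterior (clockwise) perpendicular of axial unit vectors ``u``."""
    return np.stack([u[..., 1], -u[..., 0]], axis=-1)


def gastrocnemius_length(knee_angle, ankle_angle, skel: ReferenceSkeleton | None = None):
    """Normalized gastrocnemius length (reference mm) at the given knee
    and ankle angles.  Straight-line origin-to-insertion distance on the
    posed femur-shank-foot chain; independent of the upper-body and femur
    angles.  Vectorized over broadcastable angle arrays.
    """
    if skel is None:
        skel = default_skeleton()
    knee, ankle = _check_angles(knee_angle, ankle_angle)
    knee, ankle = np.broadcast_arrays(knee, ankle)

    u_f = _femur_axis(knee)
    origin = skel.gastroc_origin[0] * u_f + skel.gastroc_origin[1] * _anterior(u_f)

    ankle_pt = np.zeros(knee.shape + (2,))
    ankle_pt[..., 1] = -skel.shank_length
    # foot axial direction: shank-proximal (0, 1) rotated clockwise by q4
    u_foot = np.stack([np.sin(ankle), np.cos(ankle)], axis=-1)
    insertion = ankle_pt + skel.gastroc_insertion[0] * u_foot
    insertion = insertion + skel.gastroc_insertion[1] * _anterior(u_foot) * -1.0  # +perp is dorsal (up)

    length = np.linalg.norm(origin - insertion, axis=-1)
    return length if length.shape else float(length)


def _wrapped_distance(p1: np.ndarray, p2: np.ndarray, r: float) -> np.ndarray:
    """Length of the shortest path from ``p1`` (origin, proximal) to
    ``p2`` (insertion, distal) constrained to pass on the anterior side
    of the circle of radius ``r`` centred at the origin of the frame
    (one-sided circular wrap: the muscle may not cut through the joint).

    The wrap angle is the counter-clockwise angle swept from ``p2`` to
    ``p1``; when it exceeds the two tangent half-angles the path is
    tangent-arc-tangent, otherwise the straight segment.  ``r = 0``
    degenerates to the plain point-to-point distance.  Both endpoints
    must lie outside the circle.
    """
    d1 = np.linalg.norm(p1, axis=-1)
    d2 = np.linalg.norm(p2, axis=-1)
    straight = np.linalg.norm(p1 - p2, axis=-1)
    if r == 0.0:
        return straight
    if np.any(d1 <= r) or np.any(d2 <= r):
        raise ValueError("attachment point inside the wrap circle")
    cross = p2[..., 0] * p1[..., 1] - p2[..., 1] * p1[..., 0]
    dot = np.sum(p1 * p2, axis=-1)
    beta = np.mod(np.arctan2(cross, dot), 2.0 * np.pi)  # CCW sweep p2 -> p1
    arc = beta - np.arccos(np.clip(r / d1, -1.0, 1.0)) - np.arccos(np.clip(r / d2, -1.0, 1.0))
    tangents = np.sqrt(d1 * d1 - r * r) + np.sqrt(d2 * d2 - r * r)
    return np.where(arc > 0, tangents + r * np.maximum(arc, 0.0), straight)


def quadriceps_length(
    upper_body_angle, femur_angle, knee_angle, skel: ReferenceSkeleton | None = None
):
    """Normalized quadriceps length (reference mm) at the given upper-body,
    femur and knee angles.

    Origin fixed in the pelvis (so the trunk-femur relative angle enters),
    insertion on the tibial tuberosity; the path wraps the patellar circle
    at the knee when the straight line would penetrate it.  Knee flexion
    (q3 decreasing from pi) lengthens the muscle.  Vectorized over
    broadcastable angle arrays.
    """
    if skel is None:
        skel = default_skeleton()
    q1, q2, q3 = _check_angles(upper_body_angle, femur_angle, knee_angle)
    q1, q2, q3 = np.broadcast_arrays(q1, q2, q3)

    u_f = _femur_axis(q3)
    hip = skel.femur_length * u_f
    # pelvis axial direction: femur axis rotated CCW by the hip angle q1 - q2
    hip_rel = q1 - q2
    c, s = np.cos(hip_rel), np.sin(hip_rel)
    u_p = np.stack(
        [c * u_f[..., 0] - s * u_f[..., 1], s * u_f[..., 0] + c * u_f[..., 1]],
        axis=-1,
    )
    origin = hip + skel.quad_origin[0] * u_p + skel.quad_origin[1] * _anterior(u_p)

    insertion = np.zeros(q3.shape + (2,))
    insertion[..., 0] = skel.quad_insertion[1]       # anterior of the downward shank
    insertion[..., 1] = -skel.quad_insertion[0]      # distal along the shank

    length = _wrapped_distance(origin, insertion, skel.patella_radius)
    return length if np.ndim(length) else float(length)
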