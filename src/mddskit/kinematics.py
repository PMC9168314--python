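"""Head coordinate frame, rotation vectors and cross-product machinery.

The head frame is right-handed with

* ``+X`` along the naso-occipital axis, pointing forward (roll axis),
* ``+Y`` along the interaural axis, pointing out of the *left* ear
  (pitch axis),
* ``+Z`` through the vertex, pointing up (yaw axis).

All rotation senses follow the right-hand rule: a rotation vector ``w``
moves a point ``r`` with velocity ``w x r``.  Angles are degrees at the
API surface and radians internally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Vec3",
    "PullDirection",
    "OKSDirection",
    "X_AXIS",
    "Y_AXIS",
    "Z_AXIS",
    "cross",
    "dot",
    "angle_between_deg",
    "oks_rotation_vector",
    "rotate_about",
]


@dataclass(frozen=True)
class Vec3:
    """A 3-component rotation/orientation vector in the head frame.

    ``x`` lies on the naso-occipital (roll) axis, ``y`` on the interaural
    (pitch) axis and ``z`` on the vertical (yaw) axis.  Units depend on
    use: unit orientation vectors are dimensionless, angular-velocity
    vectors carry deg/s.
    """

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: np.ndarray) -> "Vec3":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected shape (3,), got {a.shape}")
        return Vec3(float(a[0]), float(a[1]), float(a[2]))

    @property
    def norm(self) -> float:
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)

    def unit(self) -> "Vec3":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalize the zero vector")
        return Vec3(self.x / n, self.y / n, self.z / n)

    def __add__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x - other.x, self.y - other.y, self.z - other.z)

    def __mul__(self, s: float) -> "Vec3":
        return Vec3(self.x * s, self.y * s, self.z * s)

    __rmul__ = __mul__

    def __neg__(self) -> "Vec3":
        return Vec3(-self.x, -self.y, -self.z)


X_AXIS = Vec3(1.0, 0.0, 0.0)
Y_AXIS = Vec3(0.0, 1.0, 0.0)
Z_AXIS = Vec3(0.0, 0.0, 1.0)


class PullDirection(str, enum.Enum):
    """Direction of a perceived gravitational pull.

    ``left``/``right`` are the subject's own left/right-ear-down pull;
    ``up`` is the floating sensation, ``down`` heaviness.
    """

    BACK = "back"
    FORWARD = "forward"
    LEFT = "left"
    RIGHT = "right"
    UP = "up"
    DOWN = "down"


class OKSDirection(str, enum.Enum):
    """Full-field optokinetic stripe stimulus direction.

    The label names the stripe motion seen by the subject on a frontal
    screen; the associated rotation vector (see
    :func:`oks_rotation_vector`) is the right-hand-rule axis of the
    implied surround rotation.
    """

    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"
    ROLL_CW = "roll_cw"
    ROLL_CCW = "roll_ccw"


#: Stripe-motion description for each OKS label (frontal screen).
STRIPE_MOTION = {
    OKSDirection.UP: "stripes move upward across the frontal field",
    OKSDirection.DOWN: "stripes move downward across the frontal field",
    OKSDirection.LEFT: "stripes move toward the subject's left",
    OKSDirection.RIGHT: "stripes move toward the subject's right",
    OKSDirection.ROLL_CW: "stripes rotate clockwise as seen by the subject",
    OKSDirection.ROLL_CCW: "stripes rotate counterclockwise as seen by the subject",
}

# Rotation vectors of the implied surround rotation, right-hand rule.
# Upward stripe motion is a surround rotation about the interaural axis
# whose vector points INTO the left ear (-Y); downward points out of the
# left ear (+Y).  Rightward stripes rotate the surround about the
# downward vertical (-Z); leftward about +Z (check with w x r on a
# frontal point r = +X).  A clockwise roll, as seen by the subject
# looking along +X, carries the top of the visual field toward the
# subject's right, i.e. a rotation about +X; counterclockwise is -X.
_OKS_VECTORS = {
    OKSDirection.UP: Vec3(0.0, -1.0, 0.0),
    OKSDirection.DOWN: Vec3(0.0, 1.0, 0.0),
    OKSDirection.LEFT: Vec3(0.0, 0.0, 1.0),
    OKSDirection.RIGHT: Vec3(0.0, 0.0, -1.0),
    OKSDirection.ROLL_CW: Vec3(1.0, 0.0, 0.0),
    OKSDirection.ROLL_CCW: Vec3(-1.0, 0.0, 0.0),
}

OPPOSITE_OKS = {
    OKSDirection.UP: OKSDirection.DOWN,
    OKSDirection.DOWN: OKSDirection.UP,
    OKSDirection.LEFT: OKSDirection.RIGHT,
    OKSDirection.RIGHT: OKSDirection.LEFT,
    OKSDirection.ROLL_CW: OKSDirection.ROLL_CCW,
    OKSDirection.ROLL_CCW: OKSDirection.ROLL_CW,
}


def cross(a: Vec3, b: Vec3) -> Vec3:
    """Right-handed cross product ``a x b``."""
    return Vec3(
        a.y * b.z - a.z * b.y,
        a.z * b.x - a.x * b.z,
        a.x * b.y - a.y * b.x,
    )


def dot(a: Vec3, b: Vec3) -> float:
    return a.x * b.x + a.y * b.y + a.z * b.z


def angle_between_deg(a: Vec3, b: Vec3) -> float:
    """Unsigned angle between two non-zero vectors, in [0, 180] degrees."""
    na, nb = a.norm, b.norm
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle undefined for the zero vector")
    c = dot(a, b) / (na * nb)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def oks_rotation_vector(
    d: OKSDirection | str, roll_sign_convention: str = "subject_view"
) -> Vec3:
    """Unit rotation vector of the surround rotation implied by an OKS label.

    Parameters
    ----------
    d
        OKS label or its string value.
    roll_sign_convention
        ``"subject_view"`` (default): clockwise roll as seen by the
        subject looking forward maps to ``+X``, counterclockwise to
        ``-X``.  ``"observer_view"`` flips the two roll labels (the
        convention of an examiner facing the subject).
    """
    d = OKSDirection(d)
    v = _OKS_VECTORS[d]
    if roll_sign_convention not in ("subject_view", "observer_view"):
        raise ValueError(f"unknown roll sign convention {roll_sign_convention!r}")
    if roll_sign_convention == "observer_view" and d in (
        OKSDirection.ROLL_CW,
        OKSDirection.ROLL_CCW,
    ):
        v = -v
    return v


def rotate_about(v: Vec3, axis: Vec3, angle_deg: float) -> Vec3:
    """Rotate ``v`` about ``axis`` by ``angle_deg`` (Rodrigues, right-hand rule)."""
    k = axis.unit()
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    kxv = cross(k, v)
    kdv = dot(k, v)
    return Vec3(
        v.x * c + kxv.x * s + k.x * kdv * (1.0 - c),
        v.y * c + kxv.y * s + k.y * kdv * (1.0 - c),
        v.z * c + kxv.z * s + k.z * kdv * (1.0 - c),
    )
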