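"""From eigenvector maladaptation to perceived pull and OKS prescription.

A tilt of the yaw velocity-storage eigenvector away from the head
vertical is felt as a gravitational pull *opposite* the tilt (the head
yaw axis is displaced relative to the eigenvector): eigenvector forward
-> pull back, back -> pull forward, right -> pull left ear down, left ->
pull right ear down.  A change of the yaw-channel magnitude is felt
vertically: reduced gain -> floating (pull up), increased gain ->
heaviness (pull down).

The treatment table maps each pull to the OKS whose rotation vector
re-adapts the eigenvector by the right-hand rule — sometimes
counter-intuitively (pull back is treated with *upward* OKS).  For
lateral pulls the horizontal OKS is the clinically used primary
stimulus; the model predicts the opposing roll OKS would be more potent
and it is surfaced as the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinematics import OKSDirection, OPPOSITE_OKS, PullDirection, Vec3
from .velocity_storage import (
    DEFAULT_KAPPA,
    EigenStructure,
    build_system_matrix,
    eigenstructure,
    misalignment,
    orientation_drive,
)

__all__ = [
    "PullSensation",
    "OKSPrescription",
    "predict_pull",
    "recommend_oks",
    "wrong_direction_effect",
    "eigenstructure_for_pull",
]

#: Sensitivity floors below which no pull is reported.
DEFAULT_TILT_THRESHOLD_DEG = 1.0
DEFAULT_GAIN_THRESHOLD = 0.05

#: Nominal maladaptations used to reconstruct an eigenstructure from a
#: categorical pull (tilt in degrees; gain deviation from 1).
NOMINAL_TILT_DEG = 10.0
NOMINAL_GAIN_DELTA = 0.2


@dataclass(frozen=True)
class PullSensation:
    """A perceived gravitational pull.

    ``strength`` is sin(tilt) for horizontal (orientation-driven) pulls
    and ``|yaw_gain - 1|`` clipped to [0, 1] for vertical
    (magnitude-driven) ones.  ``azimuth_deg`` is the raw horizontal
    azimuth of the pull (0 = back, measured toward the subject's left),
    kept alongside the cardinal bin; ``detail`` notes a secondary
    maladaptation when both channels exceed threshold.
    """

    direction: PullDirection
    strength: float
    source: str  # "orientation" | "magnitude"
    azimuth_deg: float | None = None
    detail: str | None = None

    def __post_init__(self):
        if self.source not in ("orientation", "magnitude"):
            raise ValueError(f"unknown source {self.source!r}")
        vertical = self.direction in (PullDirection.UP, PullDirection.DOWN)
        if vertical != (self.source == "magnitude"):
            raise ValueError(
                "up/down pulls must have source='magnitude', horizontal "
                "pulls source='orientation'"
            )
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")


@dataclass(frozen=True)
class OKSPrescription:
    """An optokinetic stripe prescription (default clinical protocol)."""

    primary: OKSDirection
    alternative: OKSDirection | None = None
    speed_deg_s: float = 5.0
    duration_min: float = 1.0
    brightness_lux: float = 2.0

    def __post_init__(self):
        if self.duration_min < 1.0:
            raise ValueError("duration must be at least 1 min")
        if self.speed_deg_s <= 0:
            raise ValueError("speed must be positive")


# Eigenvector tilt direction -> perceived pull (pull opposes the tilt).
_TILT_TO_PULL = {
    "forward": PullDirection.BACK,
    "back": PullDirection.FORWARD,
    "right": PullDirection.LEFT,
    "left": PullDirection.RIGHT,
}
_PULL_TO_TILT = {v: k for k, v in _TILT_TO_PULL.items()}

# The model-based treatment table (primary, alternative).
_PRESCRIPTION = {
    PullDirection.BACK: (OKSDirection.UP, None),
    PullDirection.FORWARD: (OKSDirection.DOWN, None),
    PullDirection.LEFT: (OKSDirection.RIGHT, OKSDirection.ROLL_CCW),
    PullDirection.RIGHT: (OKSDirection.LEFT, OKSDirection.ROLL_CW),
    PullDirection.UP: (OKSDirection.UP, None),
    PullDirection.DOWN: (OKSDirection.DOWN, None),
}


def _azimuth_to_cardinal(az_deg: float) -> PullDirection:
    """Bin a pull azimuth (0 = back, toward +Y = 90 = left) to a cardinal."""
    az = az_deg % 360.0
    if az < 45.0 or az >= 315.0:
        return PullDirection.BACK
    if az < 135.0:
        return PullDirection.LEFT
    if az < 225.0:
        return PullDirection.FORWARD
    return PullDirection.RIGHT


def predict_pull(
    es: EigenStructure,
    tilt_threshold_deg: float = DEFAULT_TILT_THRESHOLD_DEG,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
) -> PullSensation | None:
    """Perceived gravitational pull implied by an eigenstructure.

    Returns ``None`` when both the tilt and the gain deviation sit below
    their thresholds.  When both channels are maladapted the
    orientation pull is reported (the clinical account treats the two
    cases separately) and the magnitude deviation is noted in ``detail``.
    """
    _, tilt = misalignment(es)
    gain_dev = es.yaw_gain - 1.0

    orientation = tilt >= tilt_threshold_deg
    magnitude = abs(gain_dev) >= gain_threshold

    if orientation:
        # Pull azimuth: opposite the horizontal projection of ev_yaw;
        # 0 deg = pull back (-X), measured toward the subject's left (+Y).
        ev = es.ev_yaw
        az_pull = math.degrees(math.atan2(-ev.y, ev.x)) % 360.0
        direction = _azimuth_to_cardinal(az_pull)
        detail = None
        if magnitude:
            kind = "floating" if gain_dev < 0 else "heaviness"
            detail = (
                f"combined maladaptation: yaw_gain={es.yaw_gain:.3f} "
                f"({kind}) also exceeds threshold"
            )
        return PullSensation(
            direction=direction,
            strength=min(1.0, math.sin(math.radians(tilt))),
            source="orientation",
            azimuth_deg=az_pull,
            detail=detail,
        )
    if magnitude:
        direction = PullDirection.UP if gain_dev < 0 else PullDirection.DOWN
        return PullSensation(
            direction=direction,
            strength=min(1.0, abs(gain_dev)),
            source="magnitude",
        )
    return None


def recommend_oks(p: PullSensation | PullDirection | str) -> OKSPrescription:
    """Model-based OKS prescription for a pull sensation.

    back -> up; forward -> down; left -> right (alternative: CCW roll);
    right -> left (alternative: CW roll); up (floating) -> up; down
    (heaviness) -> down.  Default protocol: 5 deg/s, 1 min, 2 lux.
    """
    direction = p.direction if isinstance(p, PullSensation) else PullDirection(p)
    primary, alternative = _PRESCRIPTION[direction]
    return OKSPrescription(primary=primary, alternative=alternative)


def eigenstructure_for_pull(
    direction: PullDirection | str,
    tilt_deg: float = NOMINAL_TILT_DEG,
    gain_delta: float = NOMINAL_GAIN_DELTA,
    time_constants: tuple[float, float, float] = (10.0, 8.0, 15.0),
) -> EigenStructure:
    """Nominal eigenstructure that would produce a given pull (inverse map)."""
    direction = PullDirection(direction)
    if direction in _PULL_TO_TILT:
        sm = build_system_matrix(time_constants, _PULL_TO_TILT[direction], tilt_deg)
    else:
        gain = 1.0 - gain_delta if direction is PullDirection.UP else 1.0 + gain_delta
        sm = build_system_matrix(time_constants, "forward", 0.0, yaw_gain=gain)
    return eigenstructure(sm)


def wrong_direction_effect(
    p: PullSensation | PullDirection | str,
    oks: OKSDirection | str,
    kappa: float = DEFAULT_KAPPA,
    roll_sign_convention: str = "subject_view",
) -> str:
    """Predicted qualitative effect of an arbitrary OKS on a pull.

    Reconstructs the nominal eigenstructure behind the pull and signs
    the effective adaptation drive: ``"improve"`` (drive > 0),
    ``"worsen"`` (< 0) or ``"no_effect"``.  Captures the clinical
    finding that the OKS antipodal to the model's prescription typically
    worsens the pulling sensation.
    """
    direction = p.direction if isinstance(p, PullSensation) else PullDirection(p)
    oks = OKSDirection(oks)
    if direction in _PULL_TO_TILT:
        es = eigenstructure_for_pull(direction)
        E = orientation_drive(es.ev_yaw, oks, kappa, roll_sign_convention)
    else:
        # Magnitude channel: only vertical OKS moves the yaw gain.
        if oks is OKSDirection.UP:
            E = 1.0 if direction is PullDirection.UP else -1.0
        elif oks is OKSDirection.DOWN:
            E = 1.0 if direction is PullDirection.DOWN else -1.0
        else:
            E = 0.0
    if E > 1e-9:
        return "improve"
    if E < -1e-9:
        return "worsen"
    return "no_effect"
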