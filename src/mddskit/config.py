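"""Configuration file support (JSON or YAML).

A config file collects the free parameters of the model in one place:
the head-frame axis labels (metadata; the canonical right-handed frame
of :mod:`mddskit.kinematics` is fixed), the roll-OKS sign convention,
storage time constants, the maladaptation (tilt direction/angle, yaw
gain), adaptation rates, sensitivity thresholds and stimulus schedules.

Example (YAML)::

    frame:
      forward_axis: "+x"
      left_axis: "+y"
      up_axis: "+z"
    oks:
      roll_sign_convention: subject_view
    time_constants: [15.0, 8.0, 20.0]
    tilt: {direction: forward, angle_deg: 10.0}
    yaw_gain: 1.0
    adaptation: {eta_orient: 0.1, eta_mag: 0.1, kappa: 0.5}
    thresholds: {tilt_deg: 1.0, gain: 0.05}
    classifier: {axis_ratio: 2.0, skew_threshold: 0.5}
    oks_schedule:
      - {t_on: 0.0, t_off: 60.0, omega: [0.0, 0.0, 5.0]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinematics import Vec3
from .velocity_storage import SystemMatrix, build_system_matrix

__all__ = ["FrameConfig", "ModelConfig", "load_config"]

_AXIS_VECTORS = {
    "+x": (1, 0, 0), "-x": (-1, 0, 0),
    "+y": (0, 1, 0), "-y": (0, -1, 0),
    "+z": (0, 0, 1), "-z": (0, 0, -1),
}


@dataclass(frozen=True)
class FrameConfig:
    """Head-frame axis labels; must form a right-handed triple."""

    forward_axis: str = "+x"
    left_axis: str = "+y"
    up_axis: str = "+z"

    def __post_init__(self):
        try:
            f = Vec3(*_AXIS_VECTORS[self.forward_axis])
            l = Vec3(*_AXIS_VECTORS[self.left_axis])
            u = Vec3(*_AXIS_VECTORS[self.up_axis])
        except KeyError as e:
            raise ValueError(f"unknown axis label {e}") from None
        from .kinematics import cross, dot

        if dot(cross(f, l), u) != 1:
            raise ValueError(
                "frame axes must form a right-handed orthogonal triple"
            )


@dataclass(frozen=True)
class ModelConfig:
    """All tunable parameters of the model and analysis."""

    frame: FrameConfig = field(default_factory=FrameConfig)
    roll_sign_convention: str = "subject_view"
    time_constants: tuple[float, float, float] = (15.0, 8.0, 20.0)
    tilt_direction: str | None = None
    tilt_angle_deg: float = 0.0
    yaw_gain: float = 1.0
    eta_orient: float = 0.1   # 1/min
    eta_mag: float = 0.1      # 1/min
    kappa: float = 0.5
    tilt_threshold_deg: float = 1.0
    gain_threshold: float = 0.05
    axis_ratio: float = 2.0
    skew_threshold: float = 0.5
    oks_schedule: tuple = ()  # ((t_on, t_off, Vec3), ...)

    def system_matrix(self) -> SystemMatrix:
        return build_system_matrix(
            self.time_constants,
            self.tilt_direction or "forward",
            self.tilt_angle_deg,
            self.yaw_gain,
        )


def _parse_schedule(raw) -> tuple:
    steps = []
    for step in raw:
        if isinstance(step, dict):
            t_on, t_off = float(step["t_on"]), float(step["t_off"])
            omega = step["omega"]
        else:
            t_on, t_off, omega = step
        steps.append((float(t_on), float(t_off), Vec3(*map(float, omega))))
    return tuple(steps)


def load_config(path: str | Path) -> ModelConfig:
    """Read a JSON (.json) or YAML (.yml/.yaml) model configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    elif path.suffix in (".yml", ".yaml"):
        raw = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    raw = raw or {}

    frame = FrameConfig(**raw.get("frame", {}))
    tilt = raw.get("tilt", {})
    adaptation = raw.get("adaptation", {})
    thresholds = raw.get("thresholds", {})
    classifier = raw.get("classifier", {})
    tc = raw.get("time_constants", (15.0, 8.0, 20.0))
    return ModelConfig(
        frame=frame,
        roll_sign_convention=raw.get("oks", {}).get(
            "roll_sign_convention", "subject_view"
        ),
        time_constants=tuple(float(t) for t in tc),
        tilt_direction=tilt.get("direction"),
        tilt_angle_deg=float(tilt.get("angle_deg", 0.0)),
        yaw_gain=float(raw.get("yaw_gain", 1.0)),
        eta_orient=float(adaptation.get("eta_orient", 0.1)),
        eta_mag=float(adaptation.get("eta_mag", 0.1)),
        kappa=float(adaptation.get("kappa", 0.5)),
        tilt_threshold_deg=float(thresholds.get("tilt_deg", 1.0)),
        gain_threshold=float(thresholds.get("gain", 0.05)),
        axis_ratio=float(classifier.get("axis_ratio", 2.0)),
        skew_threshold=float(classifier.get("skew_threshold", 0.5)),
        oks_schedule=_parse_schedule(raw.get("oks_schedule", ())),
    )
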