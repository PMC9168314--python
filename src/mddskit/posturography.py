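"""Static-posturography metrics and motion-pattern classification.

Works on center-of-pressure (COP) recordings from a balance board: the
mediolateral channel (``x_ml``, + = subject's left, the *roll/sway*
axis) and the anteroposterior channel (``y_ap``, + = forward, the
*pitch/rock* axis), both in millimetres.

The stability measures are the cumulative COP path length over a 20-s
window ("trace 20s", the primary measure for the asymmetric,
non-sinusoidal motion of gravitational-pull patients), the mean-removed
RMS per axis, and the dominant sway frequency from the Welch power
spectrum.  ``classify_motion`` separates symmetric oscillation (rocking
fore-aft, swaying side-to-side) from directional pull, which shows a
slow drift toward the pull with fast corrective returns and is detected
through the skewness of the COP velocity distribution.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .kinematics import PullDirection

__all__ = [
    "COPTrace",
    "PosturographyMetrics",
    "MotionClass",
    "MotionClassification",
    "FlatSignalError",
    "trace_length",
    "axis_rms",
    "dominant_frequency",
    "percent_improvement",
    "classify_motion",
    "compute_metrics",
]

DEFAULT_WINDOW_S = 20.0
DEFAULT_BAND_HZ = (0.05, 2.0)
#: RMS ratio above which one axis dominates the motion.
DEFAULT_AXIS_RATIO = 2.0
#: |skewness| of the COP velocity above which motion is a pull.
DEFAULT_SKEW_THRESHOLD = 0.5
#: Block-averaging window for the velocity series: COP increments are
#: taken at this timescale so broadband sensor noise does not bury the
#: slow drift-and-return asymmetry.
DEFAULT_VELOCITY_WINDOW_S = 0.2

_AXIS_TO_CHANNEL = {"roll": "x_ml", "pitch": "y_ap"}


class FlatSignalError(ValueError):
    """Signal has no power: spectral/shape measures are undefined."""


class MotionClass(str, enum.Enum):
    ROCKING = "rocking"
    SWAYING = "swaying"
    PULL_BACK = "pull_back"
    PULL_FORWARD = "pull_forward"
    PULL_LEFT = "pull_left"
    PULL_RIGHT = "pull_right"
    MIXED = "mixed"


# sign of the slow-drift direction on each channel -> pull label
_PULL_LABELS = {
    ("roll", 1): MotionClass.PULL_LEFT,
    ("roll", -1): MotionClass.PULL_RIGHT,
    ("pitch", 1): MotionClass.PULL_FORWARD,
    ("pitch", -1): MotionClass.PULL_BACK,
}

PULL_CLASS_TO_DIRECTION = {
    MotionClass.PULL_BACK: PullDirection.BACK,
    MotionClass.PULL_FORWARD: PullDirection.FORWARD,
    MotionClass.PULL_LEFT: PullDirection.LEFT,
    MotionClass.PULL_RIGHT: PullDirection.RIGHT,
}


@dataclass
class COPTrace:
    """A sampled COP recording with condition metadata."""

    t: np.ndarray
    x_ml: np.ndarray
    y_ap: np.ndarray
    fs: float
    condition: str = "eyes_closed"  # eyes_open | eyes_closed
    stance: str = "feet_apart"      # feet_apart | feet_together
    exaggerated: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x_ml = np.asarray(self.x_ml, dtype=float)
        self.y_ap = np.asarray(self.y_ap, dtype=float)
        n = self.t.size
        if n < 2 or self.x_ml.size != n or self.y_ap.size != n:
            raise ValueError("channels must share length >= 2")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name, ch in (("t", self.t), ("x_ml", self.x_ml), ("y_ap", self.y_ap)):
            if np.any(~np.isfinite(ch)):
                raise ValueError(f"NaN/inf in channel {name}")
        if self.condition not in ("eyes_open", "eyes_closed"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.stance not in ("feet_apart", "feet_together"):
            raise ValueError(f"unknown stance {self.stance!r}")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, window_s: float, start_s: float = 0.0) -> "COPTrace":
        """Sub-trace covering [start, start + window] seconds."""
        if self.duration + 1.0 / self.fs < window_s:
            raise ValueError(
                f"recording spans {self.duration:.1f} s < window {window_s} s"
            )
        t0 = self.t[0] + start_s
        m = (self.t >= t0 - 1e-12) & (self.t <= t0 + window_s + 1e-12)
        return COPTrace(
            self.t[m], self.x_ml[m], self.y_ap[m], self.fs,
            self.condition, self.stance, self.exaggerated,
        )

    def channel(self, axis: str) -> np.ndarray:
        try:
            return getattr(self, _AXIS_TO_CHANNEL[axis])
        except KeyError:
            raise ValueError(f"axis must be 'roll' or 'pitch', got {axis!r}") from None

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write t,x_ml,y_ap as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"t": self.t, "x_ml": self.x_ml, "y_ap": self.y_ap}).to_csv(
            path, index=False
        )
        if sidecar:
            meta = {
                "fs": self.fs,
                "condition": self.condition,
                "stance": self.stance,
                "exaggerated": self.exaggerated,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "COPTrace":
        """Read a delimited t,x_ml,y_ap file (sniffing , ; or tab).

        Metadata comes from a JSON sidecar (same stem, .json), from
        condition/stance/exaggerated columns, or from keyword overrides;
        ``fs`` defaults to the median sampling interval.
        """
        path = Path(path)
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"t", "x_ml", "y_ap"}
        if not required <= set(df.columns):
            raise ValueError(f"missing columns {required - set(df.columns)}")
        df = df.dropna(subset=["t", "x_ml", "y_ap"])
        info: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            info.update(json.loads(sidecar.read_text()))
        for col in ("condition", "stance", "exaggerated"):
            if col in df.columns:
                info[col] = df[col].iloc[0]
        info.update(meta)
        t = df["t"].to_numpy(float)
        fs = float(info.pop("fs", 1.0 / np.median(np.diff(t))))
        return cls(
            t=t,
            x_ml=df["x_ml"].to_numpy(float),
            y_ap=df["y_ap"].to_numpy(float),
            fs=fs,
            condition=str(info.get("condition", "eyes_closed")),
            stance=str(info.get("stance", "feet_apart")),
            exaggerated=bool(info.get("exaggerated", False)),
        )


@dataclass(frozen=True)
class PosturographyMetrics:
    """Per-trace stability report (all lengths in mm, frequencies in Hz)."""

    trace_20s: float
    roll_rms: float
    pitch_rms: float
    dominant_freq_roll: float | None
    dominant_freq_pitch: float | None
    window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "trace_20s_mm": self.trace_20s,
            "roll_rms_mm": self.roll_rms,
            "pitch_rms_mm": self.pitch_rms,
            "dominant_freq_roll_hz": self.dominant_freq_roll,
            "dominant_freq_pitch_hz": self.dominant_freq_pitch,
            "window_s": list(self.window),
        }


@dataclass(frozen=True)
class MotionClassification:
    label: MotionClass
    confidence: float
    dominant_axis: str | None
    rms_ratio: float
    velocity_skewness: float | None


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def trace_length(
    c: COPTrace, window_s: float = DEFAULT_WINDOW_S, start_s: float = 0.0
) -> float:
    """Cumulative COP path length (mm) over the window — "trace 20s".

    Raw sample-to-sample Euclidean increments, no smoothing.
    """
    w = c.window(window_s, start_s)
    return float(np.sum(np.hypot(np.diff(w.x_ml), np.diff(w.y_ap))))


def axis_rms(
    c: COPTrace,
    axis: str,
    window_s: float = DEFAULT_WINDOW_S,
    start_s: float = 0.0,
) -> float:
    """Mean-removed RMS displacement (mm) of one axis over the window.

    ``roll`` is the mediolateral (sway) channel, ``pitch`` the
    anteroposterior (rock) channel.  The mean is removed so a constant
    lean does not register as oscillation power.
    """
    x = c.window(window_s, start_s).channel(axis)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def dominant_frequency(
    c: COPTrace,
    axis: str,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> float:
    """Dominant oscillation frequency (Hz) of one axis from the Welch PSD.

    Linear detrend, Hann window, segments of min(duration, 40 s) with
    50% overlap; the maximal PSD bin within ``band_hz`` wins.  At least
    20 s of data are required (>= 40 s recommended for a 0.05 Hz band
    edge).

    Raises :class:`FlatSignalError` for an all-constant signal.
    """
    if c.duration + 1.0 / c.fs < DEFAULT_WINDOW_S:
        raise ValueError("at least 20 s of data required")
    x = c.channel(axis)
    if np.allclose(x, x[0]):
        raise FlatSignalError(f"{axis} channel is constant; no dominant frequency")
    nperseg = int(min(x.size, round(40.0 * c.fs)))
    f, p = signal.welch(
        x,
        fs=c.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
    )
    m = (f >= band_hz[0]) & (f <= band_hz[1])
    if not np.any(m) or np.all(p[m] == 0):
        raise FlatSignalError(f"no power in band {band_hz}")
    return float(f[m][np.argmax(p[m])])


def percent_improvement(before_mm: float, after_mm: float) -> int:
    """Stability improvement 100*(1 - after/before), nearest integer.

    Negative values indicate worsening.
    """
    if before_mm <= 0:
        raise ValueError("'before' trace length must be positive")
    if after_mm < 0:
        raise ValueError("'after' trace length must be non-negative")
    return int(round(100.0 * (1.0 - after_mm / before_mm)))


def compute_metrics(
    c: COPTrace,
    window_s: float = DEFAULT_WINDOW_S,
    start_s: float = 0.0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> PosturographyMetrics:
    """Full stability report for one trace."""
    freqs = {}
    for axis in ("roll", "pitch"):
        try:
            freqs[axis] = dominant_frequency(c, axis, band_hz)
        except FlatSignalError:
            freqs[axis] = None
    return PosturographyMetrics(
        trace_20s=trace_length(c, window_s, start_s),
        roll_rms=axis_rms(c, "roll", window_s, start_s),
        pitch_rms=axis_rms(c, "pitch", window_s, start_s),
        dominant_freq_roll=freqs["roll"],
        dominant_freq_pitch=freqs["pitch"],
        window=(start_s, start_s + window_s),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_motion(
    c: COPTrace,
    axis_ratio: float = DEFAULT_AXIS_RATIO,
    skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
    velocity_window_s: float = DEFAULT_VELOCITY_WINDOW_S,
) -> MotionClassification:
    """Classify a COP trace as symmetric oscillation, directional pull or mixed.

    1. The dominant axis is the one whose mean-removed RMS exceeds the
       other's by ``axis_ratio``; no dominant axis -> ``mixed``.
    2. On the dominant axis the skewness S of the velocity series (COP
       increments over ``velocity_window_s`` block means, so broadband
       noise does not mask the slow drift) separates symmetric
       oscillation (|S| <= ``skew_threshold``: rocking on pitch, swaying
       on roll) from pull.  A pull drifts slowly toward the pull and
       snaps back fast, so the drift direction is *opposite* the sign
       of S.
    3. The sign of the mean COP offset must agree with the inferred
       pull direction; disagreement halves the confidence.
    """
    if c.duration + 1.0 / c.fs < DEFAULT_WINDOW_S:
        raise ValueError("at least 20 s of data required")
    chans = {
        "roll": c.x_ml - c.x_ml.mean(),
        "pitch": c.y_ap - c.y_ap.mean(),
    }
    rms = {a: float(np.sqrt(np.mean(v**2))) for a, v in chans.items()}
    if rms["roll"] == 0 and rms["pitch"] == 0:
        raise FlatSignalError("flat trace on both axes")
    hi, lo = ("roll", "pitch") if rms["roll"] >= rms["pitch"] else ("pitch", "roll")
    ratio = rms[hi] / rms[lo] if rms[lo] > 0 else np.inf
    if ratio < axis_ratio:
        return MotionClassification(
            label=MotionClass.MIXED,
            confidence=1.0,
            dominant_axis=None,
            rms_ratio=ratio,
            velocity_skewness=None,
        )
    x = c.channel(hi)
    block = max(1, int(round(velocity_window_s * c.fs)))
    if block > 1:
        nb = x.size // block
        xs = x[: nb * block].reshape(nb, block).mean(axis=1)
    else:
        xs = x
    skew = float(stats.skew(np.diff(xs)))
    if abs(skew) <= skew_threshold:
        label = MotionClass.ROCKING if hi == "pitch" else MotionClass.SWAYING
        return MotionClassification(
            label=label,
            confidence=1.0,
            dominant_axis=hi,
            rms_ratio=ratio,
            velocity_skewness=skew,
        )
    drift_sign = -1 if skew > 0 else 1
    label = _PULL_LABELS[(hi, drift_sign)]
    confidence = 1.0
    if np.sign(x.mean() - np.median(x)) not in (0.0, float(drift_sign)):
        # mean pulled toward the excursions should match the drift side
        confidence = 0.5
    return MotionClassification(
        label=label,
        confidence=confidence,
        dominant_axis=hi,
        rms_ratio=ratio,
        velocity_skewness=skew,
    )
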