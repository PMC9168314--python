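"""Synthetic COP traces and patient cohorts.

No public posturography recordings exist for this condition (the
clinical recordings live in a proprietary balance-board format), so the
generators here emulate the statistical structure the analysis relies
on:

* symmetric sinusoidal rocking/swaying near 0.1-0.35 Hz,
* asymmetric pull patterns — slow drift toward the pull with a fast
  corrective return (a jittered sawtooth),
* eyes-open vs eyes-closed amplitude differences,
* cohort-level pull-direction frequencies and per-direction treatment
  response rates.

Every generator is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import OKSDirection, OPPOSITE_OKS, PullDirection
from .posturography import COPTrace
from .pull_prediction import recommend_oks

__all__ = [
    "OscillationSpec",
    "PullSpec",
    "CohortSpec",
    "gen_oscillation",
    "gen_pull",
    "gen_before_after",
    "gen_cohort",
]

#: Amplitude scale of eyes-open relative to eyes-closed recordings
#: (vision damps sway; body motions were larger with eyes closed).
EYES_OPEN_AMPLITUDE_FACTOR = 0.6

#: Non-exclusive per-direction marginal probabilities of experiencing a
#: pull; the printed frequencies (multi-directional pulls overlap), with
#: the lateral fraction split evenly left/right by default.
DEFAULT_DIRECTION_MARGINALS = {
    PullDirection.BACK: 0.52,
    PullDirection.LEFT: 0.16,
    PullDirection.RIGHT: 0.16,
    PullDirection.FORWARD: 0.11,
    PullDirection.DOWN: 0.05,
    PullDirection.UP: 0.03,
}

#: Observed lateral split (89 left vs 101 right of 190 lateral patients).
OBSERVED_LATERAL_SPLIT = (0.47, 0.53)

#: Fraction of patients improving under the model-prescribed OKS, per
#: dominant pull direction.
DEFAULT_RESPONSE_RATES = {
    PullDirection.BACK: 0.96,
    PullDirection.LEFT: 0.95,
    PullDirection.RIGHT: 0.95,
    PullDirection.FORWARD: 0.94,
    PullDirection.UP: 0.94,
    PullDirection.DOWN: 0.85,
}

#: Fraction worsening when treated with the OKS antipodal to the
#: prescription (20 of 26 backward-pull patients given downward OKS).
DEFAULT_WRONG_DIRECTION_WORSEN_RATE = 0.77


@dataclass(frozen=True)
class OscillationSpec:
    """Symmetric sinusoidal rocking (pitch axis) or swaying (roll axis)."""

    axis: str = "pitch"          # pitch -> rocking, roll -> swaying
    freq: float = 0.27           # Hz; rocking mean 0.27, swaying 0.33
    amplitude: float = 15.0      # mm, near the +/-15 mm figure annotations
    noise_sigma: float = 1.0     # mm white noise on both axes
    duration: float = 60.0       # s
    fs: float = 50.0             # Hz
    condition: str = "eyes_closed"
    seed: int = 0

    def __post_init__(self):
        if self.axis not in ("roll", "pitch"):
            raise ValueError("axis must be 'roll' or 'pitch'")
        if not 0.05 < self.freq < 1.0:
            raise ValueError("frequency must lie in (0.05, 1) Hz")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sigma < 0 or self.duration <= 0 or self.fs <= 0:
            raise ValueError("invalid spec")


@dataclass(frozen=True)
class PullSpec:
    """Directional pull: slow drift toward the pull, fast corrective return."""

    direction: PullDirection = PullDirection.BACK
    drift_speed: float = 5.0          # mm/s toward the pull
    excursion_threshold: float = 15.0  # mm before the corrective return
    return_speed_ratio: float = 4.0   # return/drift speed; 1 = triangle wave
    noise_sigma: float = 1.0          # mm
    duration: float = 60.0            # s
    fs: float = 50.0                  # Hz
    condition: str = "eyes_closed"
    seed: int = 0

    def __post_init__(self):
        d = PullDirection(self.direction)
        object.__setattr__(self, "direction", d)
        if d in (PullDirection.UP, PullDirection.DOWN):
            raise ValueError("COP pull traces are horizontal (back/forward/left/right)")
        if self.return_speed_ratio < 1.0:
            raise ValueError("return must not be slower than the drift")
        if self.drift_speed <= 0 or self.excursion_threshold <= 0:
            raise ValueError("invalid spec")
        if self.noise_sigma < 0 or self.duration <= 0 or self.fs <= 0:
            raise ValueError("invalid spec")


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a simulated patient cohort."""

    n_patients: int = 426
    direction_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_DIRECTION_MARGINALS)
    )
    response_rates: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSE_RATES))
    wrong_direction_fraction: float = 0.0
    wrong_direction_worsen_rate: float = DEFAULT_WRONG_DIRECTION_WORSEN_RATE
    mt_fraction: float = 0.66         # motion-triggered onset (33 of 50)
    female_fraction: float = 0.82
    treatment_minutes_mean: float = 17.0
    treatment_minutes_sd: float = 19.0
    likert_before_mean: float = 5.5
    likert_before_sd: float = 2.3
    followup_sustain_rate: float = 0.59
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        for m in (self.direction_marginals, self.response_rates):
            for d, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of range for {d}: {p}")
        for p in (
            self.wrong_direction_fraction,
            self.wrong_direction_worsen_rate,
            self.mt_fraction,
            self.female_fraction,
            self.followup_sustain_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trace generators
# ---------------------------------------------------------------------------


def _amplitude_factor(condition: str) -> float:
    return EYES_OPEN_AMPLITUDE_FACTOR if condition == "eyes_open" else 1.0


def gen_oscillation(spec: OscillationSpec) -> COPTrace:
    """Symmetric sinusoid on one axis plus white noise on both.

    The phase is drawn from the seed; eyes-open traces are damped by
    :data:`EYES_OPEN_AMPLITUDE_FACTOR`.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    a = spec.amplitude * _amplitude_factor(spec.condition)
    wave = a * np.sin(2.0 * np.pi * spec.freq * t + phase)
    noise = rng.normal(0.0, spec.noise_sigma, size=(2, n))
    x_ml = noise[0] + (wave if spec.axis == "roll" else 0.0)
    y_ap = noise[1] + (wave if spec.axis == "pitch" else 0.0)
    return COPTrace(t, x_ml, y_ap, spec.fs, condition=spec.condition)


_PULL_CHANNEL_SIGN = {
    PullDirection.LEFT: ("x_ml", 1.0),
    PullDirection.RIGHT: ("x_ml", -1.0),
    PullDirection.FORWARD: ("y_ap", 1.0),
    PullDirection.BACK: ("y_ap", -1.0),
}


def gen_pull(spec: PullSpec) -> COPTrace:
    """Sawtooth drift-and-return trace for a directional pull.

    The COP drifts at ``drift_speed`` toward the pull until the
    excursion reaches the threshold (jittered +/-20% per cycle), then
    returns at ``drift_speed * return_speed_ratio`` to a baseline
    jittered around zero.  The mean displacement carries the sign of the
    pull.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs)) + 1
    dt = 1.0 / spec.fs
    scale = _amplitude_factor(spec.condition)
    drift = spec.drift_speed * scale
    ret = drift * spec.return_speed_ratio

    pos = np.empty(n)
    p = 0.0
    target = spec.excursion_threshold * scale * rng.uniform(0.8, 1.2)
    baseline = 0.0
    going_out = True
    for i in range(n):
        pos[i] = p
        if going_out:
            p += drift * dt
            if p >= target:
                going_out = False
                baseline = spec.excursion_threshold * scale * 0.1 * rng.normal()
        else:
            p -= ret * dt
            if p <= baseline:
                going_out = True
                target = spec.excursion_threshold * scale * rng.uniform(0.8, 1.2)

    channel, sign = _PULL_CHANNEL_SIGN[spec.direction]
    noise = rng.normal(0.0, spec.noise_sigma, size=(2, n))
    x_ml, y_ap = noise[0], noise[1]
    if channel == "x_ml":
        x_ml = x_ml + sign * pos
    else:
        y_ap = y_ap + sign * pos
    t = np.arange(n) / spec.fs
    return COPTrace(t, x_ml, y_ap, spec.fs, condition=spec.condition)


def gen_before_after(
    spec: OscillationSpec | PullSpec, improvement_fraction: float
) -> tuple[COPTrace, COPTrace]:
    """Before/after pair with the after-trace scaled toward a target
    trace-length improvement.

    COP path length is proportional to the motion scale, so the
    after-trace regenerates the same seed with amplitude (or drift
    speed) and noise multiplied by ``1 - improvement_fraction``;
    expected percent improvement of trace length is then about
    ``100 * improvement_fraction``.
    """
    if not -1.0 < improvement_fraction < 1.0:
        raise ValueError("improvement fraction must lie in (-1, 1)")
    s = 1.0 - improvement_fraction
    before = _generate(spec)
    if isinstance(spec, OscillationSpec):
        after_spec = replace(
            spec, amplitude=spec.amplitude * s, noise_sigma=spec.noise_sigma * s
        )
    else:
        after_spec = replace(
            spec,
            drift_speed=spec.drift_speed * s,
            excursion_threshold=spec.excursion_threshold * s,
            noise_sigma=spec.noise_sigma * s,
        )
    return before, _generate(after_spec)


def _generate(spec) -> COPTrace:
    if isinstance(spec, OscillationSpec):
        return gen_oscillation(spec)
    if isinstance(spec, PullSpec):
        return gen_pull(spec)
    raise TypeError(f"unknown spec type {type(spec)!r}")


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a patient cohort as a table of cohort records.

    Per patient: the set of experienced pull directions is drawn so
    that every per-direction marginal is hit exactly while guaranteeing
    at least one direction per patient (the printed marginals sum to
    103%, so the 3% excess is realized as multi-direction patients):
    each direction owns an interval of length ``p_d`` on the unit
    circle, laid end to end and wrapping past 1, and a single uniform
    draw per patient selects every interval containing it.  A dominant
    direction is picked among the experienced set (weighted by the
    marginals), the OKS follows the model prescription for the dominant
    direction, and the immediate response is Bernoulli with the
    per-direction response rate.  An optional wrong-direction arm
    receives the antipodal OKS instead and worsens with
    ``wrong_direction_worsen_rate``.

    Returns a DataFrame with one row per patient and the cohort-record
    columns (pull_directions is a frozenset of labels).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    dirs = list(spec.direction_marginals)
    probs = np.array([spec.direction_marginals[d] for d in dirs])

    # systematic-overlap coupling: exact marginals, >= 1 direction when
    # the marginals sum to >= 1
    starts = np.concatenate([[0.0], np.cumsum(probs)[:-1]])
    u1 = rng.random((n, 1))
    draws = ((u1 - starts) % 1.0) < probs
    empty = ~draws.any(axis=1)
    if empty.any():  # marginals sum to < 1: fill the gap with one direction
        fill = rng.choice(len(dirs), size=int(empty.sum()), p=probs / probs.sum())
        draws[np.flatnonzero(empty), fill] = True

    # dominant direction: among experienced, weighted by marginal prevalence
    weights = np.where(draws, probs, 0.0)
    weights = weights / weights.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights, axis=1)
    u = rng.random((n, 1))
    dom_idx = (u > cum).sum(axis=1)
    dominant = np.array([str(PullDirection(dirs[i]).value) for i in dom_idx])

    rates = np.array(
        [spec.response_rates[PullDirection(d)] for d in dominant]
    )
    wrong_arm = rng.random(n) < spec.wrong_direction_fraction
    oks = np.array(
        [str(recommend_oks(PullDirection(d)).primary.value) for d in dominant]
    )
    oks[wrong_arm] = [str(OPPOSITE_OKS[OKSDirection(o)].value) for o in oks[wrong_arm]]

    r = rng.random(n)
    response = np.where(r < rates, "improved", "no_change")
    worsened = rng.random(n) < spec.wrong_direction_worsen_rate
    response[wrong_arm] = np.where(worsened[wrong_arm], "worsened", "no_change")

    minutes = rng.gamma(
        shape=(spec.treatment_minutes_mean / spec.treatment_minutes_sd) ** 2,
        scale=spec.treatment_minutes_sd**2 / spec.treatment_minutes_mean,
        size=n,
    )
    minutes = np.maximum(1.0, np.round(minutes))

    likert_before = np.clip(
        np.round(rng.normal(spec.likert_before_mean, spec.likert_before_sd, n)), 0, 10
    )
    improved = response == "improved"
    # >= 50% subjective improvement for responders, jitter otherwise
    likert_after = np.where(
        improved,
        np.round(likert_before * rng.uniform(0.0, 0.5, n)),
        likert_before + rng.integers(-1, 2, n),
    )
    likert_after = np.clip(likert_after, 0, 10)
    followup = np.where(
        improved, rng.random(n) < spec.followup_sustain_rate, False
    )

    records = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "trigger": np.where(rng.random(n) < spec.mt_fraction, "MT", "non_MT"),
            "sex": np.where(rng.random(n) < spec.female_fraction, "F", "M"),
            "pull_directions": [
                frozenset(dirs[j].value for j in np.flatnonzero(row))
                for row in draws
            ],
            "dominant_direction": dominant,
            "oks_given": oks,
            "treatment_minutes": minutes,
            "response": response,
            "likert_before": likert_before.astype(int),
            "likert_after": likert_after.astype(int),
            "followup_improved": followup,
        }
    )
    return records
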