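# mddskit

Velocity-storage eigenvector modelling, optokinetic treatment
prescription and posturography analysis for the gravitational-pull
sensation of **Mal de Debarquement Syndrome (MdDS)**.

MdDS patients report persistent non-spinning vertigo — rocking, swaying
and, in many, a steady *gravitational pull* backward, forward, sideways,
up (floating) or down (heaviness). `mddskit` implements a mechanistic
account of that pull and its treatment, aimed at vestibular researchers
and clinician-scientists who want to reproduce the model's direction
predictions, analyse balance-board recordings, or stress-test the whole
pipeline on synthetic data.

## The model

Central velocity storage is a three-dimensional leaky integrator on the
head axes (roll, pitch, yaw):

```
dx/dt = H x + G0·w_scc + G2·w_oks + G4·w_prop
y     = G1·w_scc + G3·w_oks + x
```

with `x` the stored angular velocity, `H` (1/s) the system matrix and
`G0..G4` the canal, optokinetic and proprioceptive gain couplings.
Normally `H` is diagonal with entries `-1/τᵢ` and its eigenvectors sit
on the head axes. The model's claim: the pull sensation arises when the
**yaw eigenvector** of `H` tilts away from the head vertical, or when
the yaw channel's magnitude (gain `g`) deviates from 1.

The perceived pull is encoded by the right-hand-rule cross product of
the head yaw axis `ẑ` with the yaw eigenvector `êᵥ`:

```
M = ẑ × êᵥ ,   |M| = sin(tilt)
```

An eigenvector tilted *forward* gives `M` out of the left ear (+Y) and a
pull *backward*; tilted back → pull forward; tilted right → pull to the
left ear; tilted left → pull right. Reduced gain is felt as floating,
increased gain as heaviness. The prescribed optokinetic stimulation
(OKS) is the full-field stripe stimulus whose surround rotation vector
re-adapts `êᵥ` toward `ẑ` — sometimes counter-intuitively:

| pull | OKS (primary) | more potent alternative |
| --- | --- | --- |
| back | up | – |
| forward | down | – |
| left | right | counterclockwise roll |
| right | left | clockwise roll |
| up (floating) | up | – |
| down (heaviness) | down | – |

Stimulation *antipodal* to the prescription drives the eigenvector away
from vertical and worsens the pull — the model's most distinctive,
clinically confirmed prediction.

On the posturography side, the package computes the standard stability
measures of a center-of-pressure (COP) recording — 20-s path length
("trace 20s"), per-axis mean-removed RMS, dominant sway frequency from
the Welch spectrum — and classifies the motion pattern: symmetric
oscillation (rocking / swaying) versus directional pull, the latter
recognized by the skewed velocity distribution of its slow-drift /
fast-return cycle.

## Worked example

```python
import mddskit as mk

# a patient whose yaw eigenvector is pitched 10° forward
sm = mk.build_system_matrix((15, 8, 20), "forward", 10.0)
es = mk.eigenstructure(sm)
p  = mk.predict_pull(es)
rx = mk.recommend_oks(p)
print(p.direction.value, round(p.strength, 4))   # back 0.1736
print(rx.primary.value, rx.speed_deg_s, rx.duration_min)  # up 5.0 1.0

# five minutes of the prescribed (upward) vs the antipodal OKS
print(round(mk.eigenstructure(mk.adapt(sm, rx.primary, 5)).yaw_tilt_deg, 2))  # 6.13
print(round(mk.eigenstructure(mk.adapt(sm, "down",     5)).yaw_tilt_deg, 2))  # 16.03

# synthetic posturography: backward pull, then a treated follow-up
b, a = mk.gen_before_after(mk.PullSpec(direction=mk.PullDirection.BACK, seed=3), 0.8)
print(mk.classify_motion(b).label.value)                      # pull_back
print(round(mk.trace_length(b), 1), round(mk.trace_length(a), 1))  # 1753.6 350.7
print(mk.percent_improvement(mk.trace_length(b), mk.trace_length(a)))  # 80
```

The tilt strength `0.1736 = sin 10°`; upward OKS shrinks the tilt
(10° → 6.13° after 5 min at the default adaptation rate) while downward
OKS grows it (→ 16.03°). The synthetic backward-pull trace is classified
from its COP statistics alone, and the treated trace's path length
yields the percent-improvement statistic used to quantify postural
stability.

A thin CLI wraps the same functions:

```bash
mddskit recommend --pull back
mddskit predict --tilt-direction right --tilt-angle 10
mddskit synth cohort --seed 1 --n 426 --out scratch/
mddskit analyze-cop scratch/trace.csv --report report.json
```

## Layout

- `mddskit.kinematics` — head frame, rotation vectors, cross products
- `mddskit.velocity_storage` — `H` matrix construction, eigenstructure,
  RK4 simulation, OKS adaptation law
- `mddskit.pull_prediction` — maladaptation → pull → OKS prescription
- `mddskit.posturography` — COP metrics and motion classification
- `mddskit.synthetic_data` — trace and cohort generators
- `mddskit.outcomes` — cohort aggregation and proportion utilities
- `mddskit.config` — JSON/YAML parameter files

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
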