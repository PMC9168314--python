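# Methods

This note documents the model implemented by `mddskit`, the choices made
where the underlying clinical account is qualitative, and what the
synthetic-data generators do and do not emulate.

## Coordinate conventions

The head frame is right-handed: +X naso-occipital pointing forward
(roll axis), +Y interaural pointing out of the left ear (pitch axis),
+Z through the vertex pointing up (yaw axis). All rotation senses
follow the right-hand rule; degrees at the API surface, radians
internally.

OKS stripe labels map to surround-rotation vectors as: up → (0,−1,0)
(into the left ear), down → (0,+1,0), left → (0,0,+1), right → (0,0,−1),
clockwise roll (as seen by the subject looking forward) → (+1,0,0),
counterclockwise → (−1,0,0). The roll-label assignment is geometric —
"counterclockwise for the subject" carries the top of the visual field
toward the subject's left, a rotation about −X — and it is exactly the
assignment under which the opposing roll OKS is the potent alternative
treatment for lateral pulls. Because the observer-facing convention is
also in circulation, `oks_rotation_vector` accepts
`roll_sign_convention="observer_view"`, which flips the two roll labels.

## Velocity storage

State equation: `ẋ = Hx + G0·ω_scc + G2·ω_oks + G4·ω_prop`, output
`y = G1·ω_scc + G3·ω_oks + x`. The rapid proprioceptive path is omitted
(it plays no role in the maladaptation modelled here). Gain matrices
default to identity.

`H` is built as `V Λ V⁻¹`: the roll and pitch eigenvectors default to
their head axes, the yaw eigenvector is the unit vector at the given
tilt from +Z toward the stated direction, and
`Λ = diag(−1/τ_roll, −1/τ_pitch, −g/τ_yaw)`. The yaw-channel magnitude
`g` is encoded as a scaling of the yaw eigenvalue, with the reference
time constants carried alongside `H` so the decomposition can separate
`g` from `τ_yaw`. A fore-aft tilt of the yaw eigenvector necessarily
places the coupling in the yaw *column* (roll row, `h_yr`); a lateral
tilt in the pitch row (`h_yp`) — a yaw-row element would tilt the roll
or pitch eigenvector instead.

`eigenstructure` requires real, distinct, strictly negative eigenvalues;
complex or repeated spectra are rejected loudly as unsupported
maladaptations (note that equal `τ_roll = τ_yaw` with unit gain makes
the tilt unobservable: `H` collapses to a scalar matrix). Eigenvectors
are labelled by the axis permutation maximizing the total absolute axis
component, with an ambiguity error when the best two permutations tie;
each eigenvector is normalized and signed so its dot product with the
matching head axis is non-negative.

### Integration

`simulate` uses classical fixed-step RK4, default dt = 1 ms. Because
the state equation is linear, one RK4 step collapses to constant
matrices (`x' = Φx + A·u_start + B·u_mid + C·u_end`), so the integration
is a single 3×3 matrix recursion — bit-identical to a naive RK4 loop but
an order of magnitude faster. The end-stage input of each step is
sampled as a left limit so that a stimulus switching off exactly on a
step boundary is still integrated over that step. Against the exact
matrix-exponential solution of piecewise-constant inputs the trajectory
error is ~1e-12 relative at dt = 1 ms (the acceptance script recomputes
this).

### Adaptation under OKS

The clinical account specifies only the *directions* of re-adaptation;
the dynamics here are the minimal law reproducing every reported
qualitative outcome (improve / worsen / no effect).

Signed effectiveness of an OKS with rotation vector `T` on a yaw
eigenvector with misalignment `M = ẑ × êᵥ`:

```
E = −T·M̂  −  κ (T·ẑ)(M̂·x̂)
```

The first term covers vertical and roll OKS, whose rotation vector can
directly oppose the misalignment rotation. Horizontal OKS is orthogonal
to every possible `M` and acts only through the yaw→roll cross-coupling
of velocity storage, with weight κ (default 0.5): rightward OKS corrects
a rightward eigenvector tilt and vice versa. Under this drive the roll
alternative enters at full weight 1 > κ, which is precisely the "more
potent" prediction for lateral pulls. (A literal triple-product form of
the coupling term, `κ(T×êᵥ)·(−M̂)`, is parity-odd: it gives opposite
signs for the two mirror-image lateral cases and cannot reproduce both
prescriptions; the form above is its sign-corrected, mirror-symmetric
counterpart.)

The tilt then relaxes along its unchanged azimuth through a saturating
exponential in atanh space,

```
tilt' = T_sat · tanh( atanh(tilt/T_sat) · exp(−η_orient E d) ) ,  T_sat = 45°
```

which reduces to the plain exponential decay `tilt·exp(−ηEd)` for small
tilt, drives corrective exposure (E > 0) to zero, and grows maladaptive
exposure strictly but asymptotically — the eigenbasis never degenerates
and the 45° labelling horizon is never crossed. The magnitude channel
uses the identical law on `|ln g|` with saturation `ln 4` (gain confined
to [1/4, 4]); only vertical OKS moves the gain (up increases it, down
decreases it). Defaults η_orient = η_mag = 0.1/min; all rates and κ are
free parameters, as nothing quantitative about adaptation speed is
established. Eigenvalues (time constants) are held fixed under
adaptation.

## Pull prediction

`predict_pull` reports an orientation pull when the tilt exceeds 1°
(strength `sin(tilt)`, azimuth binned to the nearest cardinal with the
raw azimuth kept), a magnitude pull when `|g−1|` exceeds 0.05 (floating
below 1, heaviness above). Both thresholds are arbitrary sensitivity
floors, config-overridable. When both channels are maladapted, the
orientation pull is reported and the magnitude deviation is noted in a
detail field — the clinical account treats the two cases separately and
gives no combination rule. `wrong_direction_effect` reconstructs the
nominal maladaptation behind a categorical pull (tilt 10°, gain 1±0.2,
time constants (10, 8, 15) s — chosen so no two eigenvalues collide) and
signs the drive E.

## Posturography

- **Trace length**: sum of raw sample-to-sample Euclidean increments
  over a 20-s window (first 20 s by default; placement configurable).
  No smoothing or resampling — the quantity is deliberately the raw
  path length.
- **Axis RMS**: mean-removed RMS per channel. Mean removal matters: a
  constant lean would otherwise dominate the RMS and contradict the
  near-zero roll RMS observed in laterally-pulled patients.
- **Dominant frequency**: Welch PSD (linear detrend, Hann window,
  segments of min(duration, 40 s), 50% overlap), maximal bin in
  0.05–2 Hz. Constant signals raise a distinct `FlatSignalError`.
- **Percent improvement**: `round(100·(1 − after/before))` to the
  nearest integer — the only rounding rule consistent with all printed
  before/after percentages (flooring fails on the 310→184 case).
- **Classification**: dominant axis by mean-removed RMS ratio ≥ 2
  (otherwise `mixed`); on the dominant axis, the skewness of the COP
  velocity separates symmetric oscillation (|S| ≤ 0.5 → rocking on
  pitch, swaying on roll) from directional pull, whose slow drift toward
  the pull and fast return give |S| > 0.5 with drift direction opposite
  the skewness sign. Velocity is measured on 0.2-s block means so
  broadband sensor noise does not bury the drift asymmetry. A mean
  offset inconsistent with the inferred drift halves the confidence.
  The skewness operationalization of "drift away and snap back" is this
  package's own; thresholds are validated only on the synthetic
  generator and exposed in config.

## Synthetic data

No public COP recordings exist for this condition, so the generators
emulate the statistical structure the analysis relies on. Defaults:
fs = 50 Hz, 60 s duration, 1 mm Gaussian noise — unstated in the source
material, chosen so a 20-s window and 0.05-Hz spectral resolution are
attainable with margin.

- **Oscillation**: `A·sin(2πft+φ)` on one axis (rocking 0.27 Hz on
  pitch, swaying 0.33 Hz on roll — the reported group means), amplitude
  15 mm (near the annotated ±15 mm excursions), phase drawn from the
  seed, noise on both axes.
- **Pull**: sawtooth — drift at 5 mm/s toward the pull until a 15 mm
  excursion threshold (jittered ±20% per cycle), return at 4× drift
  speed to a baseline jittered around zero. `return_speed_ratio = 1`
  degenerates to a symmetric triangle wave, which the classifier
  correctly reads as oscillation.
- **Eyes-open traces** are scaled by 0.6 relative to eyes-closed — a
  single amplitude factor standing in for visual stabilization, the
  only eyes-open/closed feature the analysis consumes.
- **Before/after pairs** rescale motion and noise by
  `1 − improvement_fraction`; path length is proportional to scale, so
  the expected percent improvement equals the target.
- **Cohort**: the printed per-direction pull frequencies (back 52%,
  lateral 32% split evenly left/right — the observed 47/53 split is
  available as an option — forward 11%, down 5%, up 3%) sum to 103%
  and are treated as non-exclusive marginals. Direction sets are drawn
  by a systematic-overlap coupling: each direction owns an interval of
  its marginal length laid end-to-end around the unit circle, and one
  uniform draw per patient selects every interval containing it. This
  hits every marginal exactly, guarantees at least one direction per
  patient, and realizes the 3% excess as multi-direction patients.
  (Independent Bernoulli draws with resampling of empty sets — the
  obvious alternative — would inflate the back marginal from 0.52 to
  ~0.72.) The model prescribes the OKS for the dominant direction;
  responses are Bernoulli with the printed per-direction rates (back
  0.96, lateral 0.95, forward 0.94, up 0.94, down 0.85); an optional
  wrong-direction arm receives the antipodal OKS and worsens with
  probability 0.77. Treatment minutes are gamma with mean 17 / SD 19;
  Likert scores normal 5.5(2.3) clipped to 0–10.

What the generators do **not** emulate: biomechanically realistic
inverted-pendulum sway, non-stationary or multi-frequency oscillation,
correlated direction sets beyond the single overlap pair, visit-level
treatment dynamics, or the reported multi-direction breakdowns (which
are not jointly consistent with marginals summing to 103%). Passing
closure tests therefore show that the analysis recovers the *structure
it assumes*, not that it is validated on real patient recordings — the
original recordings are in a proprietary format and not deposited, so
the printed derived numbers and pattern-level behaviour are the only
reproducible targets.

## Outcomes

Percentages are `round(100·k/n)` to the nearest integer, which
reproduces every printed (k, n, %) triple. Means and SDs render as
`a(b)` with integer rounding; a single observation renders `a(–)`.
Patients with unknown follow-up are excluded from follow-up
denominators. The two-proportion comparison is the Pearson chi-square
on the 2×2 table without continuity correction (Yates optional) via
scipy. Sub-group tables whose denominators cannot be reconstructed from
printed counts are out of scope.

## Numerical and degenerate-input policy

- Zero vectors: `angle_between_deg` and unit normalization raise.
- Unstable or non-diagonalizable `H`: rejected before simulation or
  decomposition.
- `adapt` on a perfectly aligned, unit-gain state returns the matrix
  unchanged (no direction is defined for the orientation drive).
- Flat COP signals raise `FlatSignalError` from spectral and
  classification routines.
- All generators are deterministic per seed (`numpy.random.default_rng`).

## Problem sizes

The test suite runs the simulation-fidelity check at 100 random systems
× 60 s at dt = 1 ms, the eigen round-trip at 1000 random maladaptations,
classifier closure at 500 traces per class, and cohort recovery at
100 000 patients. The acceptance script uses 25 systems × 40 s, 300
round-trips, 150 traces per class and the same 100 000-patient cohort —
sizes at which every stochastic quantity is stable to well under its
comparison tolerance.
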