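"""Velocity-storage system matrix, simulation and OKS adaptation.

Velocity storage is modelled as a three-dimensional leaky integrator on
the head (roll, pitch, yaw) axes,

    dx/dt = H x + G0 w_scc + G2 w_oks + G4 w_prop ,
    y     = G1 w_scc + G3 w_oks + x ,

where ``x`` is the stored angular velocity, ``H`` (1/s) the system
matrix, ``w_scc``/``w_oks``/``w_prop`` the semicircular-canal,
optokinetic and proprioceptive velocity inputs, and G0..G4 the gain
coupling matrices (the rapid proprioceptive path plays no role in the
maladaptation modelled here and is omitted).

In the normal state ``H`` is diagonal with entries ``-1/tau_i`` and its
eigenvectors sit on the head axes.  Maladaptation tilts the yaw
eigenvector away from the head vertical (off-diagonal terms ``h_yr``,
``h_yp``) or rescales the gain of the yaw channel; both are the
substrate of the gravitational-pull sensation and of its optokinetic
treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import (
    OKSDirection,
    Vec3,
    Z_AXIS,
    angle_between_deg,
    cross,
    dot,
    oks_rotation_vector,
    rotate_about,
)

__all__ = [
    "GainMatrices",
    "SystemMatrix",
    "EigenStructure",
    "build_system_matrix",
    "system_matrix_from_yaw_vector",
    "eigenstructure",
    "misalignment",
    "simulate",
    "adapt",
    "ComplexEigenvalueError",
    "AmbiguousEigenvectorError",
]

#: Default orientation adaptation rate (1/min).
DEFAULT_ETA_ORIENT = 0.1
#: Default magnitude adaptation rate (1/min).
DEFAULT_ETA_MAG = 0.1
#: Default yaw->roll cross-coupling weight of horizontal OKS.
DEFAULT_KAPPA = 0.5
#: Default integrator step (s).
DEFAULT_DT = 1e-3
#: Saturation of the eigenvector tilt under maladaptive OKS (deg).  Kept
#: below 45 deg so the yaw eigenvector always stays dominant on the
#: vertical axis and the labelling of the basis remains unique.
TILT_SATURATION_DEG = 45.0
#: Saturation of |ln yaw_gain| under maladaptive vertical OKS
#: (gain confined to [1/4, 4]).
LOG_GAIN_SATURATION = math.log(4.0)

_AXIS_NAMES = ("roll", "pitch", "yaw")


class ComplexEigenvalueError(ValueError):
    """H has complex eigenvalues: unsupported maladaptation."""


class AmbiguousEigenvectorError(ValueError):
    """Two eigenvectors are dominant on the same head axis."""


@dataclass(frozen=True)
class GainMatrices:
    """Gain coupling matrices of the velocity-storage pathways.

    G0: canal -> storage; G1: direct canal path; G2: OKS -> storage;
    G3: direct OKS path; G4: proprioception -> storage.  Dimensionless;
    defaults are identity.
    """

    G0: np.ndarray = field(default_factory=lambda: np.eye(3))
    G1: np.ndarray = field(default_factory=lambda: np.eye(3))
    G2: np.ndarray = field(default_factory=lambda: np.eye(3))
    G3: np.ndarray = field(default_factory=lambda: np.eye(3))
    G4: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        for name in ("G0", "G1", "G2", "G3", "G4"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.shape != (3, 3) or not np.all(np.isfinite(g)):
                raise ValueError(f"{name} must be a finite 3x3 matrix")
            object.__setattr__(self, name, g)


@dataclass(frozen=True)
class SystemMatrix:
    """The 3x3 velocity-storage matrix H (1/s) on (roll, pitch, yaw) axes.

    ``tau_ref`` carries the reference (normal-state) time constants so
    that a yaw-channel gain, encoded as a scaling of the yaw eigenvalue
    (lambda_yaw = -gain/tau_yaw), can be separated from the time
    constant on decomposition.
    """

    H: np.ndarray
    tau_ref: tuple[float, float, float] | None = None

    def __post_init__(self):
        h = np.asarray(self.H, dtype=float)
        if h.shape != (3, 3) or not np.all(np.isfinite(h)):
            raise ValueError("H must be a finite 3x3 real matrix")
        object.__setattr__(self, "H", h)
        if self.tau_ref is not None:
            tr = tuple(float(t) for t in self.tau_ref)
            if len(tr) != 3 or any(t <= 0 for t in tr):
                raise ValueError("tau_ref must be three positive time constants")
            object.__setattr__(self, "tau_ref", tr)

    @property
    def h_yr(self) -> float:
        """Yaw->roll coupling (roll row, yaw column).

        Nonzero when the yaw eigenvector is pitched forward or back: a
        yaw-row element cannot tilt the yaw eigenvector (it tilts the
        roll one), so the coupling that pitches the yaw eigenvector
        necessarily sits in the yaw column.
        """
        return float(self.H[0, 2])

    @property
    def h_yp(self) -> float:
        """Yaw->pitch coupling (pitch row, yaw column); nonzero when the
        yaw eigenvector is rolled to the side."""
        return float(self.H[1, 2])

    def is_stable(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.linalg.eigvals(self.H).real < -tol))


@dataclass(frozen=True)
class EigenStructure:
    """Eigen-decomposition of H labelled on the head axes.

    Eigenvectors are unit length and oriented so the dot product with
    the matching head axis is non-negative; time constants are
    ``-1/Re(lambda)`` in seconds.  ``yaw_gain`` is the magnitude scale
    of the yaw storage channel (1 = normal).
    """

    ev_roll: Vec3
    ev_pitch: Vec3
    ev_yaw: Vec3
    lambda_roll: float
    lambda_pitch: float
    lambda_yaw: float
    yaw_gain: float = 1.0

    @property
    def tau_roll(self) -> float:
        return -1.0 / self.lambda_roll

    @property
    def tau_pitch(self) -> float:
        return -1.0 / self.lambda_pitch

    @property
    def tau_yaw(self) -> float:
        return -1.0 / self.lambda_yaw

    @property
    def yaw_tilt_deg(self) -> float:
        """Angle of the yaw eigenvector from the head vertical."""
        return angle_between_deg(Z_AXIS, self.ev_yaw)


# ---------------------------------------------------------------------------
# Construction and decomposition
# ---------------------------------------------------------------------------

_TILT_AXES = {
    # unit direction in the horizontal plane toward which +Z is tilted
    "forward": Vec3(1.0, 0.0, 0.0),
    "back": Vec3(-1.0, 0.0, 0.0),
    "left": Vec3(0.0, 1.0, 0.0),
    "right": Vec3(0.0, -1.0, 0.0),
}


def _yaw_vector(direction: str, angle_deg: float) -> Vec3:
    d = _TILT_AXES[direction]
    s, c = math.sin(math.radians(angle_deg)), math.cos(math.radians(angle_deg))
    return Vec3(d.x * s, d.y * s, d.z * s + c)


def system_matrix_from_yaw_vector(
    time_constants: tuple[float, float, float],
    ev_yaw: Vec3,
    yaw_gain: float = 1.0,
    ev_roll: Vec3 | None = None,
    ev_pitch: Vec3 | None = None,
) -> SystemMatrix:
    """Build H = V Lambda V^-1 from an explicit yaw eigenvector.

    The roll and pitch eigenvectors default to their head axes; Lambda
    is diag(-1/tau_roll, -1/tau_pitch, -yaw_gain/tau_yaw).
    """
    taus = tuple(float(t) for t in time_constants)
    if any(t <= 0 for t in taus):
        raise ValueError("time constants must be positive")
    if yaw_gain <= 0:
        raise ValueError("yaw_gain must be positive")
    cols = [
        (ev_roll or Vec3(1, 0, 0)).unit().as_array(),
        (ev_pitch or Vec3(0, 1, 0)).unit().as_array(),
        ev_yaw.unit().as_array(),
    ]
    V = np.column_stack(cols)
    if abs(np.linalg.det(V)) < 1e-12:
        raise ValueError("eigenvector basis is singular")
    lam = np.diag([-1.0 / taus[0], -1.0 / taus[1], -yaw_gain / taus[2]])
    H = V @ lam @ np.linalg.inv(V)
    return SystemMatrix(H=H, tau_ref=taus)


def build_system_matrix(
    time_constants: tuple[float, float, float],
    yaw_tilt_direction: str = "forward",
    yaw_tilt_angle_deg: float = 0.0,
    yaw_gain: float = 1.0,
) -> SystemMatrix:
    """Velocity-storage matrix with the yaw eigenvector tilted off vertical.

    Parameters
    ----------
    time_constants
        (tau_roll, tau_pitch, tau_yaw) in seconds, all positive.
    yaw_tilt_direction
        Horizontal direction toward which the yaw eigenvector leans:
        one of ``forward``, ``back``, ``left``, ``right``.
    yaw_tilt_angle_deg
        Tilt of the yaw eigenvector from +Z, 0 <= angle < 90.  Zero
        gives the normal diagonal matrix.
    yaw_gain
        Magnitude scale of the yaw channel (1 = normal); scales the yaw
        eigenvalue.

    A fore-aft tilt produces a nonzero ``h_yr`` element, a lateral tilt
    a nonzero ``h_yp`` element.
    """
    if not 0.0 <= yaw_tilt_angle_deg < 90.0:
        raise ValueError("tilt angle must be in [0, 90) degrees")
    if yaw_tilt_direction not in _TILT_AXES:
        raise ValueError(f"unknown tilt direction {yaw_tilt_direction!r}")
    return system_matrix_from_yaw_vector(
        time_constants, _yaw_vector(yaw_tilt_direction, yaw_tilt_angle_deg), yaw_gain
    )


def eigenstructure(
    sm: SystemMatrix,
    imag_tol: float = 1e-9,
    ambiguity_tol: float = 1e-6,
) -> EigenStructure:
    """Eigen-decomposition of H, labelled by head axis.

    Eigenvectors are assigned to roll/pitch/yaw by their maximal
    absolute component, normalized and sign-fixed so the dot product
    with the matching head axis is >= 0.

    Raises
    ------
    ComplexEigenvalueError
        If any eigenvalue has an imaginary part above ``imag_tol``
        (such maladaptations are outside the model).
    AmbiguousEigenvectorError
        If two eigenvectors claim the same head axis, or the dominant
        components tie within ``ambiguity_tol``.
    """
    w, V = np.linalg.eig(sm.H)
    if np.any(np.abs(w.imag) > imag_tol):
        raise ComplexEigenvalueError(
            f"complex eigenvalues {w}: unsupported maladaptation"
        )
    w = w.real
    V = V.real
    if np.any(w >= 0):
        raise ValueError("H is not stable: eigenvalue with non-negative real part")
    scale = np.max(np.abs(w))
    d = np.sort(w)
    if np.any(np.diff(d) < 1e-9 * scale):
        raise AmbiguousEigenvectorError(
            f"repeated eigenvalues {w}: eigenbasis is not unique"
        )

    # Label by the axis each eigenvector is dominant on, resolved as a
    # global assignment: of the six axis permutations pick the one
    # maximizing the total absolute axis component.  A near-tie between
    # the best two permutations means dominance is genuinely ambiguous.
    Vn = np.abs(V) / np.linalg.norm(V, axis=0)
    perms = (
        (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
    )
    scores = sorted(
        ((sum(Vn[axis, j] for axis, j in enumerate(p)), p) for p in perms),
        reverse=True,
    )
    if scores[0][0] - scores[1][0] < ambiguity_tol:
        raise AmbiguousEigenvectorError(
            f"no unique axis labelling for eigenvectors (columns) {V}"
        )
    assigned = {axis: j for axis, j in enumerate(scores[0][1])}

    evs: list[Vec3] = []
    lams: list[float] = []
    for axis in range(3):
        j = assigned[axis]
        v = V[:, j]
        v = v / np.linalg.norm(v)
        if v[axis] < 0:
            v = -v
        evs.append(Vec3.from_array(v))
        lams.append(float(w[j]))

    if sm.tau_ref is not None:
        yaw_gain = -lams[2] * sm.tau_ref[2]
    else:
        yaw_gain = 1.0
    return EigenStructure(
        ev_roll=evs[0],
        ev_pitch=evs[1],
        ev_yaw=evs[2],
        lambda_roll=lams[0],
        lambda_pitch=lams[1],
        lambda_yaw=lams[2],
        yaw_gain=yaw_gain,
    )


def misalignment(es: EigenStructure) -> tuple[Vec3, float]:
    """Misalignment rotation vector and tilt angle of the yaw eigenvector.

    ``M = zhat x ev_yaw`` encodes, by the right-hand rule, the rotation
    carrying the head yaw axis onto the yaw eigenvector; ``|M| =
    sin(tilt)``.  A forward-tilted eigenvector gives M out of the left
    ear (+Y), the internal signature of a backward pull.
    """
    M = cross(Z_AXIS, es.ev_yaw)
    tilt = angle_between_deg(Z_AXIS, es.ev_yaw)
    return M, tilt


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _schedule_to_fn(schedule):
    """Accept a callable t -> Vec3/array, a constant, or [(t_on, t_off, v)]."""
    if schedule is None:
        return lambda t: np.zeros((np.size(t), 3))
    if callable(schedule):
        def fn(t):
            t = np.atleast_1d(t)
            out = np.empty((t.size, 3))
            for i, ti in enumerate(t):
                v = schedule(float(ti))
                out[i] = v.as_array() if isinstance(v, Vec3) else np.asarray(v, float)
            return out
        return fn
    if isinstance(schedule, Vec3):
        v = schedule.as_array()
        return lambda t: np.broadcast_to(v, (np.size(t), 3)).copy()
    if isinstance(schedule, (np.ndarray, list, tuple)) and not (
        len(schedule) and isinstance(schedule[0], (list, tuple))
    ):
        v = np.asarray(schedule, float)
        return lambda t: np.broadcast_to(v, (np.size(t), 3)).copy()
    steps = [
        (float(a), float(b), s.as_array() if isinstance(s, Vec3) else np.asarray(s, float))
        for a, b, s in schedule
    ]

    def fn(t):
        t = np.atleast_1d(t)
        out = np.zeros((t.size, 3))
        for a, b, v in steps:
            out[(t >= a) & (t < b)] += v
        return out

    return fn


def _rk4_step_maps(H: np.ndarray, dt: float):
    """Exact linear maps of one classical RK4 step for dx/dt = Hx + u.

    With u sampled at the step start (u1), midpoint (u2) and end (u3),
    one RK4 step is x' = Phi x + A u1 + B u2 + C u3 for constant 3x3
    matrices; obtained by propagating basis vectors through the stage
    algebra once.
    """
    I = np.eye(3)
    a = dt / 2.0

    def step(x, u1, u2, u3):
        k1 = H @ x + u1
        k2 = H @ (x + a * k1) + u2
        k3 = H @ (x + a * k2) + u2
        k4 = H @ (x + dt * k3) + u3
        return x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    z = np.zeros(3)
    Phi = np.column_stack([step(I[:, i], z, z, z) for i in range(3)])
    A = np.column_stack([step(z, I[:, i], z, z) for i in range(3)])
    B = np.column_stack([step(z, z, I[:, i], z) for i in range(3)])
    C = np.column_stack([step(z, z, z, I[:, i]) for i in range(3)])
    return Phi, A, B, C


def simulate(
    sm: SystemMatrix,
    gains: GainMatrices | None = None,
    omega_scc=None,
    omega_oks=None,
    omega_prop=None,
    dt: float = DEFAULT_DT,
    duration: float = 60.0,
) -> pd.DataFrame:
    """Integrate the velocity-storage state with fixed-step RK4.

    Input schedules may be ``None`` (zero), a constant ``Vec3``/array, a
    callable ``t -> Vec3``, or a step list ``[(t_on, t_off, Vec3), ...]``
    in deg/s.  Returns a tidy frame with time ``t`` (s), stored velocity
    ``x_roll, x_pitch, x_yaw`` and full output ``y_roll, y_pitch,
    y_yaw`` (deg/s), including both endpoints.

    Because the state equation is linear, the RK4 stage algebra for one
    step collapses to constant matrices, so the integration is a single
    matrix recursion; the result is bit-identical to a naive RK4 loop.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not sm.is_stable():
        raise ValueError("unstable system matrix rejected")
    gains = gains or GainMatrices()
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt

    f_scc = _schedule_to_fn(omega_scc)
    f_oks = _schedule_to_fn(omega_oks)
    f_prop = _schedule_to_fn(omega_prop)

    def drive(ts):
        return (
            f_scc(ts) @ gains.G0.T + f_oks(ts) @ gains.G2.T + f_prop(ts) @ gains.G4.T
        )

    u_start = drive(t[:-1])               # (n, 3) at step starts
    u_mid = drive(t[:-1] + dt / 2.0)      # (n, 3) at midpoints
    # End-stage input is the left limit so a step whose right edge sits on
    # an input offset still integrates the input that was active over it.
    u_end = drive(t[:-1] + dt * (1.0 - 1e-9))

    Phi, A, B, C = _rk4_step_maps(sm.H, dt)
    d = u_start @ A.T + u_mid @ B.T + u_end @ C.T
    x = np.zeros((n + 1, 3))
    xi = np.zeros(3)
    for i in range(n):
        xi = Phi @ xi + d[i]
        x[i + 1] = xi

    y = f_scc(t) @ gains.G1.T + f_oks(t) @ gains.G3.T + x
    return pd.DataFrame(
        {
            "t": t,
            "x_roll": x[:, 0],
            "x_pitch": x[:, 1],
            "x_yaw": x[:, 2],
            "y_roll": y[:, 0],
            "y_pitch": y[:, 1],
            "y_yaw": y[:, 2],
        }
    )


# ---------------------------------------------------------------------------
# Adaptation
# ---------------------------------------------------------------------------


def _saturating_relax(value: float, sat: float, exponent: float) -> float:
    """Relax ``value`` in (0, sat) by ``exp(-exponent)`` in atanh space.

    Reduces to ``value * exp(-exponent)`` for value << sat; decays to 0
    for exponent -> +inf and saturates strictly below ``sat`` for
    exponent -> -inf.
    """
    if value <= 0.0:
        return 0.0
    z = min(value / sat, 1.0 - 1e-12)
    return sat * math.tanh(math.atanh(z) * math.exp(-exponent))


def orientation_drive(
    ev_yaw: Vec3, oks: OKSDirection | str, kappa: float = DEFAULT_KAPPA,
    roll_sign_convention: str = "subject_view",
) -> float:
    """Signed effectiveness E of an OKS at re-aligning the yaw eigenvector.

    E > 0: the stimulus rotates the eigenvector toward the head vertical
    (treatment); E < 0: away from it (worsening); E = 0: no effect.

    The direct term ``-T . Mhat`` covers vertical and roll OKS, whose
    rotation vector T can directly oppose the misalignment rotation
    ``M = zhat x ev_yaw``.  Horizontal OKS (T on the vertical axis) is
    orthogonal to any M and acts only through the yaw->roll
    cross-coupling of velocity storage, with weight ``kappa``: rightward
    OKS corrects a rightward (ev_y < 0) eigenvector tilt and vice versa,
    giving ``-kappa (T.zhat)(Mhat.xhat)``.
    """
    M = cross(Z_AXIS, ev_yaw)
    if M.norm < 1e-15:
        return 0.0
    Mhat = M.unit()
    T = oks_rotation_vector(oks, roll_sign_convention)
    direct = -dot(T, Mhat)
    coupled = -kappa * T.z * Mhat.x
    return direct + coupled


def adapt(
    sm: SystemMatrix,
    oks: OKSDirection | str,
    duration_min: float,
    eta_orient: float = DEFAULT_ETA_ORIENT,
    eta_mag: float = DEFAULT_ETA_MAG,
    kappa: float = DEFAULT_KAPPA,
    roll_sign_convention: str = "subject_view",
) -> SystemMatrix:
    """Re-adapt the yaw eigenvector under a period of OKS exposure.

    The tilt relaxes (or grows) along its unchanged azimuth through a
    saturating exponential,

        tilt' = T_sat * tanh( atanh(tilt / T_sat) * exp(-eta_orient * E * d) )

    with E the signed drive of :func:`orientation_drive` and ``T_sat``
    :data:`TILT_SATURATION_DEG`.  For small tilt this is the plain
    exponential law ``tilt * exp(-eta * E * d)``; corrective OKS (E > 0)
    drives the tilt to zero, maladaptive OKS grows it strictly but
    asymptotically, so the eigenbasis never degenerates.  The magnitude
    channel relaxes identically in log-gain: the vertical OKS pushing
    the yaw gain toward 1 shrinks ``|ln gain|``, the opposite one grows
    it toward :data:`LOG_GAIN_SATURATION`; horizontal and roll OKS leave
    the gain unchanged.  Eigenvalues (time constants) are held fixed.

    Returns the rebuilt system matrix; a perfectly aligned eigenvector
    with unit gain is returned unchanged.
    """
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    if eta_orient < 0 or eta_mag < 0 or kappa < 0:
        raise ValueError("rates must be non-negative")
    oks = OKSDirection(oks)
    es = eigenstructure(sm)
    M, tilt = misalignment(es)

    new_ev = es.ev_yaw
    if tilt > 0 and M.norm > 1e-15:
        E = orientation_drive(es.ev_yaw, oks, kappa, roll_sign_convention)
        new_tilt = _saturating_relax(
            tilt, TILT_SATURATION_DEG, eta_orient * E * duration_min
        )
        new_ev = rotate_about(Z_AXIS, M.unit(), new_tilt)

    u = math.log(es.yaw_gain)
    if oks in (OKSDirection.UP, OKSDirection.DOWN) and u != 0.0:
        s = 1.0 if oks is OKSDirection.UP else -1.0  # up increases magnitude
        e_mag = 1.0 if s * u < 0 else -1.0           # corrective vs maladaptive
        u = math.copysign(
            _saturating_relax(abs(u), LOG_GAIN_SATURATION, eta_mag * e_mag * duration_min),
            u,
        )
    new_gain = math.exp(u)

    taus = sm.tau_ref
    if taus is None:
        taus = (es.tau_roll, es.tau_pitch, es.tau_yaw)
    return system_matrix_from_yaw_vector(
        taus, new_ev, new_gain, ev_roll=es.ev_roll, ev_pitch=es.ev_pitch
    )
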