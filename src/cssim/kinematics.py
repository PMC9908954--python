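"""Forward/inverse kinematics of the 3-DOF scaled middle leg and footpaths.

The leg is a serial chain of three revolute joints -- thorax-coxa (ThC),
coxa-trochanter (CTr) and femur-tibia (FTi) -- modeled with the product of
exponentials: g(theta) = exp(xi1^ th1) exp(xi2^ th2) exp(xi3^ th3) g_st,
where each twist is defined by a unit axis direction omega_i and a point q_i
on the axis (mm), and g_st is the foot frame at the zero configuration.

Frame convention (the one the zero-configuration table is written in):
x is anterior-posterior (+x anterior), y is lateral, pointing distally along
the leg at zero configuration, z is dorso-ventral (+z dorsal).  The ThC axis
is slanted 37 degrees in the y-z plane; CTr and FTi rotate about x, so the
distal leg moves in a plane that the ThC rotation swings anteriorly and
posteriorly.  The treadmill is a plane of constant z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import fsolve

__all__ = [
    "JointAngles",
    "LegModel",
    "Pose",
    "FootPath",
    "UnreachableTargetError",
    "forward_kinematics",
    "inverse_kinematics",
    "position_jacobian",
    "joint_frames",
    "generate_footpath",
    "path_to_angles",
    "default_leg",
]

_DEG37 = math.radians(37.0)


class UnreachableTargetError(RuntimeError):
    """Inverse kinematics failed to converge; carries the final residual (mm)."""

    def __init__(self, target, residual: float, index: Optional[int] = None):
        self.target = np.asarray(target, dtype=float)
        self.residual = float(residual)
        self.index = index
        where = f" at sample {index}" if index is not None else ""
        super().__init__(
            f"target {np.round(self.target, 3)} unreachable{where} "
            f"(residual {self.residual:.3g} mm)"
        )


@dataclass(frozen=True)
class JointAngles:
    """ThC, CTr, FTi joint angles in radians (zero = zero configuration)."""

    theta1: float
    theta2: float
    theta3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "JointAngles":
        a = np.asarray(arr, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class Pose:
    """Rigid pose of the foot: rotation ``R`` (3x3) and position ``p`` (mm)."""

    R: np.ndarray
    p: np.ndarray


def _default_omegas() -> np.ndarray:
    return np.array(
        [
            [0.0, -math.sin(_DEG37), -math.cos(_DEG37)],  # ThC, slanted in y-z
            [1.0, 0.0, 0.0],  # CTr
            [1.0, 0.0, 0.0],  # FTi
        ]
    )


def _default_qs() -> np.ndarray:
    return np.array(
        [
            [0.0, 61.34, 15.03],  # point on ThC axis
            [0.0, 93.46, 22.36],  # CTr joint
            [0.0, 230.45, -80.90],  # FTi joint
        ]
    )


@dataclass
class LegModel:
    """Twist-parameterized 15:1 scaled middle leg.

    ``omegas`` are unit joint-axis directions (rows), ``qs`` points on the
    axes (mm), ``q_end`` the foot position at zero angles, ``R_st`` the foot
    orientation at zero angles (identity by default).
    """

    omegas: np.ndarray = field(default_factory=_default_omegas)
    qs: np.ndarray = field(default_factory=_default_qs)
    q_end: np.ndarray = field(default_factory=lambda: np.array([0.0, 362.42, -180.99]))
    R_st: np.ndarray = field(default_factory=lambda: np.eye(3))
    scale: float = 15.0
    joint_limits: Optional[np.ndarray] = None  # (3, 2) lo/hi radians

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float).reshape(3, 3)
        self.qs = np.asarray(self.qs, dtype=float).reshape(3, 3)
        self.q_end = np.asarray(self.q_end, dtype=float).reshape(3)
        norms = np.linalg.norm(self.omegas, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("joint axis directions must be unit vectors")

    def max_reach(self) -> float:
        """Upper bound on the foot's distance from the ThC axis point (mm)."""
        pts = np.vstack([self.qs, self.q_end])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def default_leg() -> LegModel:
    """The published 15:1 scaled *C. morosus* middle-leg geometry."""
    return LegModel()


def _rodrigues(omega: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix exp([omega] theta) for a unit axis."""
    w1, w2, w3 = omega
    K = np.array([[0.0, -w3, w2], [w3, 0.0, -w1], [-w2, w1, 0.0]])
    return np.eye(3) + math.sin(theta) * K + (1.0 - math.cos(theta)) * (K @ K)


def _screw_transform(omega: np.ndarray, q: np.ndarray, theta: float) -> Tuple[np.ndarray, np.ndarray]:
    """Homogeneous transform (R, t) of the revolute screw about (omega, q).

    For a pure rotation about an axis through q, t = (I - R) q.
    """
    R = _rodrigues(omega, theta)
    return R, (np.eye(3) - R) @ q


def _chain(angles: np.ndarray, leg: LegModel):
    """Cumulative transforms G_i = T_1 ... T_i, i = 1..3, as (R, t) pairs."""
    R_acc, t_acc = np.eye(3), np.zeros(3)
    out = []
    for i in range(3):
        R_i, t_i = _screw_transform(leg.omegas[i], leg.qs[i], angles[i])
        R_acc, t_acc = R_acc @ R_i, R_acc @ t_i + t_acc
        out.append((R_acc.copy(), t_acc.copy()))
    return out


def forward_kinematics(angles: JointAngles | Sequence[float], leg: Optional[LegModel] = None) -> Pose:
    """Foot pose for the given joint angles via the product of exponentials."""
    leg = leg or default_leg()
    th = angles.as_array() if isinstance(angles, JointAngles) else np.asarray(angles, dtype=float)
    R3, t3 = _chain(th, leg)[-1]
    return Pose(R=R3 @ leg.R_st, p=R3 @ leg.q_end + t3)


def joint_frames(angles, leg: Optional[LegModel] = None):
    """Displaced joint positions, axes, segment rotations and foot position.

    Returns a dict with keys ``p`` (3x3 displaced axis points: ThC point, CTr,
    FTi), ``omega`` (3x3 displaced axis directions), ``R`` (list of cumulative
    rotations after joints 1..3) and ``foot`` (3,).  Used by the strain model
    to place gauge sites and resolve segment-local bending axes.
    """
    leg = leg or default_leg()
    th = angles.as_array() if isinstance(angles, JointAngles) else np.asarray(angles, dtype=float)
    chain = _chain(th, leg)
    p = np.empty((3, 3))
    om = np.empty((3, 3))
    p[0], om[0] = leg.qs[0], leg.omegas[0]
    for i in (1, 2):
        R_prev, t_prev = chain[i - 1]
        p[i] = R_prev @ leg.qs[i] + t_prev
        om[i] = R_prev @ leg.omegas[i]
    R3, t3 = chain[-1]
    return {
        "p": p,
        "omega": om,
        "R": [chain[0][0], chain[1][0], chain[2][0]],
        "foot": R3 @ leg.q_end + t3,
    }


def position_jacobian(angles, leg: Optional[LegModel] = None) -> np.ndarray:
    """3x3 Jacobian dp/dtheta; column i is omega_i' x (p - q_i')."""
    leg = leg or default_leg()
    fr = joint_frames(angles, leg)
    J = np.empty((3, 3))
    for i in range(3):
        J[:, i] = np.cross(fr["omega"][i], fr["foot"] - fr["p"][i])
    return J


_FALLBACK_GUESSES = (
    (0.0, 0.0, 0.0),
    (0.0, 0.3, -1.2),
    (0.0, -0.4, 0.6),
    (0.3, -0.4, 0.6),
    (-0.3, -0.4, 0.6),
    (0.0, 0.4, -0.6),
)


def inverse_kinematics(
    target,
    leg: Optional[LegModel] = None,
    guess: JointAngles | Sequence[float] = (0.0, 0.0, 0.0),
    tol: float = 1e-6,
    max_iter: int = 200,
) -> JointAngles:
    """Joint angles placing the foot at ``target`` (mm).

    Solves p(theta) - target = 0 with MINPACK's quasi-Newton hybrid method,
    using the analytic position Jacobian, warm-started from ``guess``.  The
    3-DOF chain has a locally unique solution, so the result is deterministic
    for a fixed guess.  Raises :class:`UnreachableTargetError` when the
    residual cannot be brought below ``tol`` (mm).
    """
    leg = leg or default_leg()
    target = np.asarray(target, dtype=float).reshape(3)
    if np.linalg.norm(target - leg.qs[0]) > leg.max_reach() + 1e-9:
        raise UnreachableTargetError(target, np.linalg.norm(target - leg.qs[0]))

    def residual(th):
        return forward_kinematics(th, leg).p - target

    def jac(th):
        return position_jacobian(th, leg)

    g0 = guess.as_array() if isinstance(guess, JointAngles) else np.asarray(guess, dtype=float)
    best_r = np.inf
    for g in (g0, *(np.asarray(f) for f in _FALLBACK_GUESSES)):
        sol = fsolve(residual, g, fprime=jac, xtol=1e-13, maxfev=max_iter * 4)
        r = float(np.linalg.norm(residual(sol)))
        if r < best_r:
            best_r = r
        if r <= tol:
            return JointAngles.from_array(sol)
    raise UnreachableTargetError(target, best_r)


@dataclass
class FootPath:
    """Periodic foot trajectory: times (s), positions (mm), phase labels.

    ``phase`` is a boolean array, True during stance.  Stance runs on the
    treadmill plane (constant z) at the belt speed; swing lifts the foot,
    overshoots the touchdown point anteriorly and re-matches the belt
    velocity at touchdown.
    """

    t: np.ndarray
    points: np.ndarray
    phase: np.ndarray
    step_period: float
    treadmill_speed: float
    duty: float

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def _quintic(p0, v0, a0, p1, v1, a1, D):
    """Coefficients (ascending) of the quintic matching end pos/vel/acc."""
    A = np.array(
        [
            [1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0],
            [0, 0, 2, 0, 0, 0],
            [1, D, D**2, D**3, D**4, D**5],
            [0, 1, 2 * D, 3 * D**2, 4 * D**3, 5 * D**4],
            [0, 0, 2, 6 * D, 12 * D**2, 20 * D**3],
        ],
        dtype=float,
    )
    return np.linalg.solve(A, np.array([p0, v0, a0, p1, v1, a1], dtype=float))


# Default stance-line placement in the leg workspace (mm), on the
# knee-raised posture branch (CTr levated, tibia descending steeply to the
# ground, as in the standing insect).  Chosen once so the tibia is near
# plumb at touchdown -- small tibial bending that grows as the leg tilts
# through stance -- while the trochanterofemur carries the body weight on a
# long, nearly constant moment arm; see docs/methods.md.
STANCE_Y = 260.0
GROUND_Z = -200.0
APEX_HEIGHT = 40.0

#: IK warm-start guess selecting the knee-raised branch.
STANCE_GUESS = (0.0, 0.3, -1.2)


def generate_footpath(
    step_period: float = 4.0,
    treadmill_speed: float = 40.0,
    duty: float = 0.5,
    leg: Optional[LegModel] = None,
    fs: float = 60.0,
    stance_y: float = STANCE_Y,
    ground_z: float = GROUND_Z,
    apex_height: float = APEX_HEIGHT,
    stance_center_x: float = 0.0,
) -> FootPath:
    """Build one period of a stepping footpath.

    Stance (duration ``duty * step_period``) moves the foot posteriorly at
    ``treadmill_speed`` (mm/s) on the plane z = ``ground_z``.  Swing is a
    single quintic in x with end velocities equal to the belt velocity, which
    necessarily overshoots the touchdown point anteriorly before settling
    back -- the velocity-matched touchdown that prevents the foot bouncing on
    contact.  Vertical lift is a smooth bump of height ``apex_height``.  The
    path is C1-periodic by construction.
    """
    if not step_period > 0:
        raise ValueError("step_period must be positive")
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie strictly between 0 and 1")
    n = int(round(step_period * fs))
    t = np.arange(n) / fs
    Ts = duty * step_period
    A = treadmill_speed * Ts  # stance displacement
    x_td = stance_center_x + A / 2.0  # touchdown (anterior) x
    x_lo = stance_center_x - A / 2.0  # liftoff (posterior) x

    stance = t < Ts
    x = np.empty(n)
    z = np.full(n, ground_z)
    x[stance] = x_td - treadmill_speed * t[stance]

    D = step_period - Ts
    s = t[~stance] - Ts
    cx = _quintic(x_lo, -treadmill_speed, 0.0, x_td, -treadmill_speed, 0.0, D)
    x[~stance] = np.polynomial.polynomial.polyval(s, cx)
    z[~stance] = ground_z + apex_height * np.sin(np.pi * s / D) ** 2

    points = np.column_stack([x, np.full(n, stance_y), z])
    return FootPath(
        t=t,
        points=points,
        phase=stance,
        step_period=step_period,
        treadmill_speed=treadmill_speed,
        duty=duty,
    )


def path_to_angles(
    path: FootPath,
    leg: Optional[LegModel] = None,
    guess: Sequence[float] = STANCE_GUESS,
    max_jump: float = 0.3,
) -> np.ndarray:
    """Per-sample inverse kinematics along a footpath, warm-start chained.

    Returns an (n, 3) angle array.  Each sample's solve starts from the
    previous solution, which keeps the series on one IK branch; a jump
    larger than ``max_jump`` rad between consecutive samples raises an
    error.  Deterministic: identical inputs give bit-identical output.
    """
    leg = leg or default_leg()
    n = len(path.t)
    out = np.empty((n, 3))
    g = np.asarray(guess, dtype=float)
    for i in range(n):
        try:
            sol = inverse_kinematics(path.points[i], leg, guess=g)
        except UnreachableTargetError as err:
            raise UnreachableTargetError(err.target, err.residual, index=i) from None
        out[i] = sol.as_array()
        if i > 0 and np.max(np.abs(out[i] - out[i - 1])) > max_jump:
            raise RuntimeError(
                f"IK branch jump of {np.max(np.abs(out[i] - out[i - 1])):.3f} rad "
                f"at sample {i}"
            )
        g = out[i]
    return out
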