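"""Dynamic-scaling arithmetic linking the insect leg to the 15:1 robot.

The robot is dynamically scaled to the animal by matching the ratio of the
stepping-cycle period to the natural period of the femur-tibia (FTi) joint,
so that both systems experience a similar balance of inertial and elastic
forces.  The animal's FTi joint is treated as a rotational spring-inertia
oscillator: the leg is approximated as a slender rod pivoting about its end
(J = m*L**2/3) and the passive muscle stiffness provides the spring.  The
robot's FTi inertia is dominated by the geared servo rotor and its stiffness
by the servo's feedback controller.

With the nominal values (insect: m = 11 mg, L = 1.2 cm, k = 1e-6 N*m/rad;
robot: J = 1e-2 kg*m**2, k = 1 N*m/rad) the natural periods are ~0.14 s and
~0.63 s, and a step six natural periods long gives the robot a 4 s step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "OscillatorSpec",
    "rod_end_inertia",
    "natural_period",
    "scaled_step_period",
    "body_mass_fraction",
    "ANIMAL_FTI",
    "ROBOT_FTI",
    "PERIOD_RATIO",
]

#: Step period expressed in FTi natural periods, inferred from the animal
#: (a ~1 s step against a ~0.14 s natural period).
PERIOD_RATIO = 6.0


@dataclass(frozen=True)
class OscillatorSpec:
    """Rotational spring-inertia oscillator describing one joint.

    Parameters
    ----------
    J : float
        Rotational inertia about the joint, kg*m**2.
    k : float
        Joint rotational stiffness, N*m/rad.
    m, L : float, optional
        Segment mass (kg) and length (m) the inertia was derived from, if it
        came from the slender-rod approximation.
    """

    J: float
    k: float
    m: Optional[float] = None
    L: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.J > 0 and self.k > 0):
            raise ValueError("J and k must be positive")

    @classmethod
    def from_rod(cls, m: float, L: float, k: float) -> "OscillatorSpec":
        """Build a spec from a slender rod of mass ``m`` (kg), length ``L`` (m)."""
        return cls(J=rod_end_inertia(m, L), k=k, m=m, L=L)


def rod_end_inertia(m: float, L: float) -> float:
    """Moment of inertia of a slender rod about its end, J = m*L**2/3.

    Parameters are in SI units (kg, m).  For the insect leg
    (m = 11 mg, L = 1.2 cm) this gives 5.28e-10 kg*m**2.
    """
    if not (m > 0 and L > 0):
        raise ValueError("mass and length must be positive")
    return m * L * L / 3.0


def natural_period(spec: OscillatorSpec) -> float:
    """Small-oscillation natural period T = 2*pi*sqrt(J/k), in seconds.

    Note the period *increases* with inertia and *decreases* with stiffness;
    this is the only dimensionally consistent combination of J and k with
    units of time (up to the 2*pi of a simple harmonic oscillator).
    """
    return 2.0 * math.pi * math.sqrt(spec.J / spec.k)


def scaled_step_period(robot: OscillatorSpec, period_ratio: float = PERIOD_RATIO) -> float:
    """Step period that dynamically scales the robot: ratio * natural period.

    With the default ratio of 6 and the nominal robot FTi oscillator this is
    3.77 s, rounded to the 4 s step used on the hardware.
    """
    if not period_ratio > 0:
        raise ValueError("period_ratio must be positive")
    return period_ratio * natural_period(robot)


def body_mass_fraction(total_mass: float, moving_mass: float) -> float:
    """Fraction of the total mass concentrated in the (non-moving) body.

    The leg-and-carriage assembly weighs ``total_mass`` and only
    ``moving_mass`` of it moves relative to the carriage; the rest acts as
    body mass, mirroring the mass distribution of walking insects.
    """
    if not total_mass > 0:
        raise ValueError("total_mass must be positive")
    if not 0 <= moving_mass <= total_mass:
        raise ValueError("moving_mass must lie in [0, total_mass]")
    return (total_mass - moving_mass) / total_mass


#: Insect femur-tibia joint: 11 mg, 1.2 cm slender rod, 1e-6 N*m/rad.
ANIMAL_FTI = OscillatorSpec.from_rod(m=11e-6, L=1.2e-2, k=1e-6)

#: Robot femur-tibia joint: rotor-dominated inertia, servo feedback stiffness.
ROBOT_FTI = OscillatorSpec(J=1e-2, k=1.0)
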