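"""Derive the dynamically scaled step period for the robot leg.

Matching the ratio of step period to joint natural period between insect
and robot preserves the balance of inertial and elastic forces at 15:1
scale.
"""

from cssim import ANIMAL_FTI, ROBOT_FTI, natural_period, scaled_step_period
from cssim.scaling import body_mass_fraction

T_animal = natural_period(ANIMAL_FTI)
T_robot = natural_period(ROBOT_FTI)

print(f"animal FTi natural period: {T_animal:.4f} s (J={ANIMAL_FTI.J:.3g} kg*m^2)")
print(f"robot  FTi natural period: {T_robot:.4f} s (J={ROBOT_FTI.J:.3g} kg*m^2)")
print(f"animal step (6 natural periods): {scaled_step_period(ANIMAL_FTI):.2f} s")
print(f"robot  step (6 natural periods): {scaled_step_period(ROBOT_FTI):.2f} s "
      f"-> rounded to {round(scaled_step_period(ROBOT_FTI))} s on the hardware")
print(f"body mass fraction (800 g total, 100 g moving): "
      f"{body_mass_fraction(0.8, 0.1):.1%}")
# A ~1 s insect step maps to a ~4 s robot step; most mass rides in the
# 'body' carriage, as in walking insects.
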