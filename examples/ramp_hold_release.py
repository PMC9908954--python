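"""Phasic CS discharge to a ramp-hold-release bending load.

The fixed-leg run shows the classic large-CS response: a burst during the
ramp, adaptation during the hold, silence after release.  The free-leg run
shows that a dynamically scaled leg moving without contact generates no
strain, hence no discharge.
"""

import numpy as np

from cssim import ExperimentSpec, run_experiment

for name in ("ramp_hold_release_fixed", "ramp_hold_release_free"):
    res = run_experiment(ExperimentSpec(name, seed=1))
    y3 = res.discharges["3"].y
    t = res.discharges["3"].t
    ramp = (t >= 1.0) & (t < 1.5)
    late_hold = (t >= 3.0) & (t < 3.5)
    print(f"{name}:")
    print(f"  group 3 burst during ramp : {y3[ramp].max():8.1f} spikes/s")
    print(f"  group 3 late in the hold  : {y3[late_hold].max():8.1f} spikes/s")
    print(f"  group 3 after release     : {y3[t > 4.2].max():8.1f} spikes/s")
# The burst-then-adapt profile encodes the rate of load change ('yank'),
# not the sustained load; with the leg free everything stays at zero.
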