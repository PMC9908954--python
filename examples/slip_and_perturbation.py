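"""Unexpected load events: mid-stance foot slip and a transient pull.

When the foot slips, the tibial bending moment collapses: the axial tibia
group (6B) falls silent and the transverse group (6A) -- normally active
only at stance end -- bursts in mid-stance, an unambiguous slip signal.
A transient downward pull on the body instead *raises* the axial groups'
discharge while it acts.
"""

import numpy as np

from cssim import ExperimentSpec, run_experiment

base = run_experiment(ExperimentSpec("stepping_load", {"n_steps": 5}, seed=1))
slip = run_experiment(ExperimentSpec("slip", {"n_steps": 5}, seed=1))
pert = run_experiment(ExperimentSpec("transient_load", {"n_steps": 5}, seed=1))


def mask(res, label):
    t = res.strain.t
    m = np.zeros(len(t), bool)
    for _, ev in res.events[res.events.label == label].iterrows():
        m |= (t >= ev.t0) & (t <= ev.t1)
    return m


w = mask(slip, "slip")
print("inside the slip window (0.9-1.3 s of stance):")
print(f"  6A peak, slip run     : {slip.discharges['6A'].y[w].max():7.1f} spikes/s")
print(f"  6A peak, baseline run : {base.discharges['6A'].y[w].max():7.1f} spikes/s")
print(f"  6B mean, slip run     : {slip.discharges['6B'].y[w].mean():7.1f} spikes/s")
print(f"  6B mean, baseline run : {base.discharges['6B'].y[w].mean():7.1f} spikes/s")

w = mask(pert, "perturbation")
print("inside the perturbation window (half-sine pull, 5 N):")
for g in ("3", "6B"):
    print(f"  group {g} mean: {pert.discharges[g].y[w].mean():7.1f} "
          f"(baseline {base.discharges[g].y[w].mean():7.1f}) spikes/s")
# The 6A mid-stance burst exists only in the slip run; the perturbation
# elevates axial-group discharge while the extra load is applied.
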