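"""Directional tuning of the two rosette channels (asterisk protocol).

The held foot is loaded in 12 directions, 30 degrees apart, cycling
dorsal -> anterior -> ventral -> posterior.  The axial channel peaks for
dorsally directed force (CS group 3's preference), the transverse channel
for ventrally directed force (group 4), with cosine falloff.
"""

from cssim import ExperimentSpec, run_experiment

res = run_experiment(ExperimentSpec("asterisk", seed=1))
s = res.summaries
print(f"{'dir (deg)':>9} {'tf_axial':>10} {'tf_transverse':>14}")
for _, row in s.iterrows():
    print(f"{row.direction_deg:9.0f} {row.tf_axial:10.6f} {row.tf_transverse:14.6f}")
print(f"axial max at      {s.direction_deg[s.tf_axial.idxmax()]:.0f} deg (dorsal)")
print(f"transverse max at {s.direction_deg[s.tf_transverse.idxmax()]:.0f} deg (ventral)")
# Positive strain = compression of the gauged dorsal face; the two
# channels form an antagonistic pair 180 degrees apart.
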