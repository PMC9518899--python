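"""Tristability of the self-activation switch: bifurcation along kg0.

Sweeps the maximal host growth rate kg0 for the self-activating circuit,
locating all saddle-node bifurcations and classifying the multistability of
each interval.  The circuit's own cooperative switch contributes one
bistable range and the growth feedback a second; where they overlap the
system is tristable (OFF / ON / super-ON).
"""

import growthfeedback as g

model = g.reference_fixtures()["self_activation"]
states = g.find_steady_states(model)
print(f"at kg0 = {model.gf.kg0}: {len(states)} steady states, "
      f"{sum(s.stability == 'stable' for s in states)} stable")
for s in states:
    print(f"  x = {s.x:8.4f}  {s.stability:8s}  growth rate = {s.growth_rate:.4f}/h")

diagram = g.branch_scan(model, "kg0", (0.02, 2.0), n_grid=61)
print("\nbifurcation events along kg0:")
for e in diagram.events:
    print(f"  {e.label}: {e.type} at kg0 = {e.param_value:.6f}, x = {e.state[0]:.4f}")

print("\nmultistability classes between events:")
for r in g.classify_regions(diagram):
    print(f"  kg0 in ({r.param_lo:.4f}, {r.param_hi:.4f}): {r.label} "
          f"({r.n_stable} stable of {r.n_states})")
print("\nFour saddle nodes bound two overlapping bistable ranges; the overlap"
      "\n(between the middle two) is the tristable window.")
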