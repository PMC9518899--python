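"""Bistability of a constitutive circuit created purely by growth feedback.

Enumerates the fixed points of the one-gene constitutive circuit at the
reference parameters, classifies their stability, and shows with two
trajectories that the unstable state is the threshold separating the
fast-growth/low-expression basin from the slow-growth/high-expression one.
"""

import growthfeedback as g

model = g.reference_fixtures()["constitutive"]
print(f"constitutive circuit: k0={model.k0}, d0={model.d0}, "
      f"kg0={model.gf.kg0}, J={model.gf.J}, m={model.gf.m}")

states = g.find_steady_states(model)
print(f"\n{len(states)} steady states:")
for s in states:
    print(f"  x = {s.x:8.4f}  {s.stability:8s}  growth rate = {s.growth_rate:.4f}/h")
lo, thr, hi = states
print("\nThe circuit has no positive feedback, yet two stable states coexist:"
      "\nthe host either grows fast with the gene diluted low, or grows slowly"
      "\nwith the gene accumulated high; the middle (unstable) state is the"
      "\nswitching threshold.")

below = g.integrate_trajectory(model, [0.8 * thr.x], t_end=20000.0)
above = g.integrate_trajectory(model, [1.2 * thr.x], t_end=20000.0)
print(f"\nstart at {0.8 * thr.x:.2f} (below threshold) -> x = "
      f"{below.states[-1, 0]:.4f} (the low state at {lo.x:.4f})")
print(f"start at {1.2 * thr.x:.2f} (above threshold) -> x = "
      f"{above.states[-1, 0]:.4f} (the high state at {hi.x:.4f})")
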