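"""The closed-form condition for growth-feedback bistability.

The constitutive circuit is bistable only if the loss curve
d(x) = (d0 + GR(x)) x is nonmonotonic, which happens exactly when
kg0/d0 > 4m/(m-1)^2, and if the production rate k0 lies between the local
minimum and maximum of d(x).  This script evaluates both conditions at the
reference parameters and cross-checks them against direct enumeration.
"""

import growthfeedback as g

model = g.reference_fixtures()["constitutive"]
m, kg0, d0 = model.gf.m, model.gf.kg0, model.d0

thr = g.nonmonotonicity_threshold(m)
print(f"m = {m}: nonmonotonicity requires kg0/d0 > 4m/(m-1)^2 = {thr:g}")
print(f"actual kg0/d0 = {kg0 / d0:g}  ->  "
      f"{'nonmonotonic' if kg0 / d0 > thr else 'monotonic'} loss curve")

ext = g.loss_curve_extrema(model)
print(f"\nloss-curve extrema: local max d({ext.x_at_max:.3f}) = {ext.d_at_max:.4f},"
      f" local min d({ext.x_at_min:.3f}) = {ext.d_at_min:.4f}")
lo, hi = g.bistable_k0_range(model)
print(f"bistable production window: {lo:.4f} < k0 < {hi:.4f} "
      f"(reference k0 = {model.k0} lies inside)")

for k0, where in [(model.k0, "inside"), (0.5 * lo, "below"), (2 * hi, "above")]:
    n = len(g.find_steady_states(model.replace(k0=k0)))
    print(f"  k0 = {k0:.4f} ({where} the window): {n} steady state(s)")
print("\nThree intersections of production with the loss curve inside the"
      "\nwindow = bistability; outside it the curves cross once.")
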