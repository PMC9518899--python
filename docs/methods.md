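# Methods

## Model

All three circuits share one structure: per-gene production minus first-order
degradation minus dilution by host growth,

    dx_i/dt = f_i(x) − d0_i x_i − GR(x) x_i,
    GR(x)   = kg0 / ((Σ_i x_i / J)^m + 1).

The growth rate depends on the *summed* circuit expression — the burden
proxy — so the one-gene circuits are the special case of the general form
used by the toggle switch. Production is circuit-specific: constant `k0`
(constitutive), an activating Hill term (self-activation), or a repressing
Hill term driven by the partner gene (toggle). Growth rate does not feed
back on production: the model captures dilution-mediated coupling only,
which is the general, promoter-independent part of the interaction. The
analysis assumes exponential-phase growth, where a constant-coefficient ODE
in concentrations is appropriate.

Units are arbitrary expression units (a.u.) and hours throughout; `m` is a
continuous real parameter (fitted values such as 1.456 are non-integer), and
powers of zero use the convention `0^p = 0` for `p > 0`.

### Parameters that matter

| parameter | meaning | default/reference | notes |
|---|---|---|---|
| `kg0` | unburdened maximal growth rate [1/h] | 0.9–1.0; plausible range 0–2 | swept in most analyses |
| `J` | expression capacity (half-max growth) [a.u.] | 1 | pure scale: rescaling J rescales x |
| `m` | burden sensitivity (Hill coeff.) | 2 in the reference sets; fits give 1.42–1.76 | m > 1 required for growth-induced bistability |
| `d0` | degradation [1/h] | 0.0015 (constitutive), 0.01–0.02 (others) | constitutive value is below the GFP-derived range 0.012–0.45, kept so the fixture reproduces the published portraits |
| `k0, k1, K, n` | circuit production/regulation | per fixture | `n ≥ 1`; `k0 > 0` assumed (see below) |

The four shipped reference sets (`reference_fixtures()`, also as YAML under
`growthfeedback/configs/`) are the printed demonstration values:
constitutive (k0=0.1, d0=0.0015, kg0=0.9), self-activation (k0=0.002,
k1=0.36, K=0.1, n=2, d0=0.02, kg0=1), toggle tristable (k0=0.001, k1=0.2,
K=5, n=2, d0=0.01, kg0=0.9) and toggle quadstable (K=3, kg0=0.95, rest
unchanged), all with J=1 and m=2 by default.

## Closed-form bistability condition (constitutive circuit)

With `u = (x/J)^m`, stationarity of the loss curve `d(x) = (d0 + GR(x)) x`
reduces to `g(u) = ((m−1)u − 1)/(1+u)² = d0/kg0`. `g` is single-humped with
peak `(m−1)²/(4m)` at `u* = (m+1)/(m−1)`, giving the boundary
`kg0/d0 > 4m/(m−1)²` — independent of `J`, and divergent as `m → 1⁺`
(returned as `+inf`, not an exception). The two roots are bracketed in
`(1/(m−1), u*)` and `(u*, U)` with `U` doubled until sign change, then
solved by Brent's method to relative tolerance 9e-16; this guarantees both
roots without heuristic grids. The smaller root is the local maximum of
`d` (the flow's last defense against accumulation), the larger the local
minimum; the bistable production window is `d(x_min) < k0 < d(x_max)`.
Draws within 1e-9 relative of the boundary are reported as monotonic with a
`marginal` flag so the Boolean contract stays testable at tangency.

## Steady-state enumeration

- **1-D**: the right-hand side is evaluated on a combined linear + log grid
  of ~12,000 points on `(0, x_ub]` with
  `x_ub = 1.05 · Σ(k0_i + k1_i)/min d0_i` (no fixed point can exceed this:
  at equilibrium `x_i = f_i/(d0_i + GR) ≤ (k0_i+k1_i)/d0_i`), and every sign
  change is polished by Brent's method.
- **2-D**: a damped Newton iteration using the analytic 2×2 Jacobian runs
  vectorised over ~600 seeds (per-axis linear grid plus log-spaced points
  condensed toward the axes, where the (high, low) toggle branches live).
  Steps are capped at a quarter of the search box and iterates clipped to
  nonnegative values; only seeds converged to residual < 1e-13·(production
  scale) are kept, then deduplicated at 1e-6·x_ub (lower residual wins).
  Fixture state counts are invariant when the seed density is doubled
  (tested), and the 1-D count matches a 350,000-point sign-change oracle on
  random parameter draws (tested).
- Stability is the sign of the largest real part of the analytic Jacobian's
  eigenvalues, with a ±1e-8/h band labelled `marginal`. `classify_stability`
  refuses states whose residual exceeds 10× the enumeration tolerance, so a
  caller cannot classify a non-fixed point.
- `k0 = 0` configurations are rejected with a clear message: the origin
  would become a fixed point and the sign-change logic assumes
  `rhs(0) > 0` componentwise.

Nullclines are extracted with marching squares on a quadratically warped
grid (`x = ub·t²`), which resolves the near-axis branches a uniform grid
misses; intersections are computed with polyline intersection (shapely) and
reproduce the enumerated fixed points.

## Bifurcation analysis

The continuation strategy is enumerate-and-link rather than
pseudo-arclength: every grid value of the swept parameter gets a full global
enumeration, states are linked into branches by nearest-neighbour matching,
and the grid is adaptively bisected wherever the fixed-point count changes,
down to 1e-6 of the sweep width. Global enumeration is cheap in 1–2
dimensions, cannot lose disconnected branches, and has no failure mode at
the pitchfork. Two folds closer than the scan resolution are reported as a
single event with a `merged` flag.

Event classification works on the annihilating pair: each state on the
state-poor side of the event claims its nearest counterpart on the rich
side, and the two unclaimed states are the pair. In an exactly symmetric
toggle, a pair that are swap-images of each other (`(x1,x2)` and `(x2,x1)`,
off-diagonal) marks a pitchfork; anything else is a saddle node. Saddle
nodes are then sharpened by Newton on the extended system
`{rhs = 0, det J = 0}` in (state, parameter) — residuals reach machine
precision, which is what lets the k0-sweep folds match the analytic window
to ~1e-16 relative — with bisection on the state count (to ~1e-13 relative)
as fallback; the method used is recorded on the event. The pitchfork is
located on the diagonal subspace, where the Jacobian has the form
`[[a, b], [b, a]]`: bisection finds the zero crossing of the
antisymmetric-mode eigenvalue `a − b`, the symmetric mode `a + b` staying
negative across it. Requesting a pitchfork on an asymmetric model raises.
Events are labelled SN1…SNk / PF in ascending order of the swept parameter.

Two-parameter boundaries repeat the sweep at each value of the second
parameter and stitch events into labelled curves by same-type
nearest-parameter matching against the event-richest row. The default
grids are deliberately coarse (tens of points per sweep, a handful of `m`
values); the structural claims tested — fold pairs merging as `m → 1`,
growth folds insensitive to the circuit Hill coefficient `n` while circuit
folds shift — are robust at this resolution, and everything refines by
passing larger `n_grid`/`p1_values`. "Insensitive to n" is asserted as a
displacement below 0.02 in `kg0` (the growth folds do move by ~1e-2 since
total production enters the burden), an order of magnitude less than the
circuit folds' shift.

## Growth-rate fitting

`fit_growth_hill` performs nonlinear least squares on
`GR(x) = kg0/((x/J)^m + 1)` in log-parameter space (positivity by
construction), multi-started from a heuristic initialization (kg0 = max
observed rate, J at the interpolated half-maximum, m = 1.5 — the midpoint
of the plausible fitted range) with seeded log-normal perturbations; the
best residual sum of squares wins, deterministically for a fixed seed. The
loss is ordinary least squares on the growth rate (no weighting is implied
by the data); relative-error weighting is available behind a flag.
Confidence intervals come from the Gauss–Newton curvature at the optimum
(t-based, in log space, delta-method back to natural scale) and are
documented as approximate. A fit with `se(log m) > 0.5` is flagged weakly
identified — typically when expression never reaches the capacity `J` — and
the ultrasensitivity verdict (`m > 1` supported iff the lower 95% bound
exceeds 1) is withheld for such fits. A joint-fit variant shares `(J, m)`
across media conditions while letting `kg0` vary per condition; the
default remains fully per-condition fits, since nothing in the source data
constrains the choice.

## Synthetic data generator

The generator emulates burden-titration data: growth rate versus exogenous
expression for a media condition, with ground truths in the ultrasensitive
range (the three reference truths are m = 1.456, 1.76, 1.424). The default
design uses 12–20 points on `[0, 4J]`, ~60% of them log-spaced below `J`
(titration data concentrate at the shoulder) — this design is an invention,
as are the noise models (multiplicative Gaussian, default σ = 5%, or
additive Gaussian scaled by kg0), since the source scatter plots state no
noise model. Rates are truncated at zero, and a dataset with more than half
its points truncated raises. Everything is reproducible from the seed,
byte-for-byte.

What passing the synthetic tests shows: the estimator recovers `(kg0, J, m)`
exactly on clean data and with median `|m̂ − m| ≈ 0.05` at 5% noise and
n = 20. What it does not show: anything about real measurement error
structure (heteroscedasticity, expression-axis error, between-replicate
drift), and it cannot reproduce the specific fitted values 1.456/1.76/1.424,
whose underlying digitized data are not published. Note also a resolution
limit: truths 1.456 and 1.424 differ by 0.032, below the estimator's noise
floor at these settings, so only the 1.76 condition is reliably
rank-identified (~99% of seeds); a full three-way rank ordering succeeds in
only ~57% of seeds and is not a meaningful test at this noise level.

## Numerical choices and degenerate inputs

- Integration uses LSODA with the analytic Jacobian, rtol 1e-8 / atol 1e-10:
  rate constants span three orders of magnitude (d0 = 0.0015 vs kg0 = 0.9),
  which is mildly stiff. Nonnegativity is enforced by solver accuracy, not
  by projection — projection would mask model errors — and a run producing
  significantly negative states raises.
- The constitutive circuit's relaxation time is ~1/d0 ≈ 700 h, so
  basin-convergence demonstrations integrate for 2×10⁴ h.
- `m ≤ 1`: the nonmonotonicity threshold returns `+inf` (a sentinel, not an
  error); all fold machinery then correctly finds nothing.
- `kg0 = 0`: growth feedback off; the loss curve is linear and the single
  fixed point is `k0/d0`.
- `J → ∞`: growth rate becomes the constant `kg0`; the model reduces to a
  linear birth-death system with fixed point `k0/(d0 + kg0)` (tested).

## Known limitations

- Global enumeration scales exponentially with dimension; the package
  supports the 1- and 2-gene circuits it was built for, not large networks.
- No Hopf detection: these models have no oscillatory instabilities (the
  Jacobian structure keeps the relevant eigenvalues real near events), and
  growth-rate-dependent production — which can produce damped oscillations —
  is out of scope.
- Stochastic (Gillespie) simulation, basins-of-attraction volumes, and
  switching-rate estimates between states are out of scope.
- With a strongly asymmetric toggle (e.g. k1_1 = 2.1 against k1_2 = 0.2,
  a 10.5× imbalance) the dominant gene saturates the burden term and the
  sweep is monostable throughout; the multi-fold asymmetric structure
  appears at moderate asymmetries (tested at 1% and 5%).
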