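"""Fixed-point enumeration, stability classification, nullclines, flow field.

Steady states are intersections of production and loss: in one dimension the
right-hand side is scanned densely for sign changes and each bracket polished
by Brent's method; in two dimensions a damped Newton iteration (vectorised
over a linear + log-spaced seed grid, the log part catching states hugging
the axes) converges every seed, and distinct roots are deduplicated.
Stability comes from the eigenvalues of the analytic Jacobian: a state is
stable when every real part is below -tol, a saddle/unstable state when any
real part exceeds +tol, marginal within tol of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_models import growth_rate

__all__ = [
    "SteadyState",
    "NullclineSet",
    "DirectionField",
    "find_steady_states",
    "classify_stability",
    "nullclines",
    "direction_field",
    "search_upper_bound",
    "steady_states_table",
]

MARGINAL_TOL = 1e-8  # [1/h] eigenvalue real parts within this are "marginal"
RESIDUAL_RTOL = 1e-9  # residual < RESIDUAL_RTOL * production scale
DEDUP_FRAC = 1e-6  # roots closer than this fraction of the search box merge


@dataclass
class SteadyState:
    """A fixed point with stability label and local spectrum."""

    state: np.ndarray
    stability: str  # "stable" | "unstable" | "marginal"
    eigenvalues: np.ndarray
    growth_rate: float
    residual: float

    @property
    def x(self) -> float:
        """Convenience scalar accessor for one-dimensional circuits."""
        return float(self.state[0])


def search_upper_bound(model) -> float:
    """Upper bound on any fixed-point coordinate.

    At a fixed point x_i = f_i(x)/(d0_i + GR) <= (k0_i + k1_i)/d0_i, so the
    summed maximal production over the smallest degradation rate (x 1.05
    margin) bounds the search box.
    """
    return 1.05 * float(model.max_production.sum() / model._d0_vec.min())


def _scale(model) -> float:
    return max(float(model.max_production.max()), 1e-30)


def classify_stability(model, state, *, residual_rtol: float = RESIDUAL_RTOL):
    """Return (label, eigenvalues) for a fixed point; refuses non-fixed points."""
    state = np.atleast_1d(np.asarray(state, dtype=float))
    resid = float(np.max(np.abs(model.rhs(state))))
    if resid > 10 * residual_rtol * _scale(model):
        raise ValueError(
            f"state residual {resid:.3g} too large; not a fixed point"
        )
    jac = model.jacobian(state)
    eig = np.linalg.eigvals(jac) if model.dimension > 1 else jac.reshape(1)
    eig = np.atleast_1d(eig)
    top = float(np.max(eig.real))
    if top < -MARGINAL_TOL:
        label = "stable"
    elif top > MARGINAL_TOL:
        label = "unstable"
    else:
        label = "marginal"
    return label, eig


def _make_state(model, x: np.ndarray) -> SteadyState:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    label, eig = classify_stability(model, x)
    return SteadyState(
        state=x,
        stability=label,
        eigenvalues=eig,
        growth_rate=float(growth_rate(model.gf, x.sum())),
        residual=float(np.max(np.abs(model.rhs(x)))),
    )


def _scan_grid(x_ub: float, n_scan: int) -> np.ndarray:
    lin = np.linspace(x_ub / n_scan, x_ub, n_scan)
    log = np.geomspace(x_ub * 1e-9, x_ub, n_scan)
    return np.unique(np.concatenate(([0.0], lin, log)))


def _roots_1d(model, x_ub: float, n_scan: int) -> List[float]:
    grid = _scan_grid(x_ub, n_scan)
    vals = model.rhs(grid[:, None])[:, 0]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite rhs encountered during scan")
    roots: List[float] = []
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    f = lambda x: float(model.rhs(np.array([x]))[0])
    for i in idx:
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-300, rtol=9e-16))
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(grid[i]))
    return sorted(roots)


def _seed_grid_2d(model, n_lin: int, n_log: int) -> np.ndarray:
    ubs = 1.05 * model.max_production / model._d0_vec
    axes = []
    for ub in ubs:
        vals = np.concatenate(
            [np.linspace(0.0, ub, n_lin), np.geomspace(ub * 1e-5, 0.5 * ub, n_log)]
        )
        axes.append(np.unique(vals))
    g1, g2 = np.meshgrid(axes[0], axes[1], indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel()])


def _newton_2d(model, seeds: np.ndarray, x_ub: float, *, maxit: int = 120):
    """Damped Newton on all seeds at once; returns converged roots."""
    x = np.clip(seeds.copy(), 0.0, None)
    tol = 1e-13 * max(_scale(model), 1.0)
    for _ in range(maxit):
        F = model.rhs(x)
        if np.all(np.abs(F) < tol):
            break
        J = model.jacobian(x)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        ok = np.abs(det) > 1e-300
        inv_det = np.where(ok, det, 1.0)
        dx1 = (J[:, 1, 1] * F[:, 0] - J[:, 0, 1] * F[:, 1]) / inv_det
        dx2 = (-J[:, 1, 0] * F[:, 0] + J[:, 0, 0] * F[:, 1]) / inv_det
        step = np.column_stack([dx1, dx2])
        step[~ok] = 0.0
        # damp: cap the step at a fraction of the box to avoid overshooting
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        cap = 0.25 * x_ub
        step = np.where(norm > cap, step * (cap / np.maximum(norm, 1e-300)), step)
        x = np.clip(x - step, 0.0, 1.5 * x_ub)
    F = model.rhs(x)
    good = np.all(np.abs(F) < tol, axis=1)
    return x[good]


def _dedupe(points: np.ndarray, tol: float) -> List[np.ndarray]:
    out: List[np.ndarray] = []
    for p in points:
        if all(np.max(np.abs(p - q)) > tol for q in out):
            out.append(p)
    return out


def find_steady_states(
    model,
    *,
    x_ub: Optional[float] = None,
    n_scan: int = 6000,
    seeds_per_axis: Tuple[int, int] = (16, 12),
) -> List[SteadyState]:
    """Enumerate all fixed points of the circuit, sorted by first coordinate.

    Raises if basal production is zero (the origin would become a fixed point
    and the sign-change machinery assumes rhs(0) > 0 componentwise).
    """
    if np.any(model.basal_production <= 0):
        raise ValueError(
            "basal production must be positive for every gene; k0 = 0 "
            "configurations are not supported by the fixed-point search"
        )
    if x_ub is None:
        x_ub = search_upper_bound(model)

    if model.dimension == 1:
        roots = [np.array([r]) for r in _roots_1d(model, x_ub, n_scan)]
    else:
        seeds = _seed_grid_2d(model, *seeds_per_axis)
        converged = _newton_2d(model, seeds, x_ub)
        if not np.all(np.isfinite(converged)):
            raise ValueError("non-finite states from Newton iteration")
        roots = _dedupe(converged, DEDUP_FRAC * x_ub)
        roots.sort(key=lambda p: (p[0], p[1]))
    if not roots:
        raise RuntimeError("no fixed points found (rhs(0) > 0 should force one)")
    return [_make_state(model, r) for r in roots]


@dataclass
class NullclineSet:
    """Zero-level curves of each rhs component for a two-gene circuit."""

    curves: Dict[int, List[np.ndarray]] = field(default_factory=dict)
    box: Tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)

    def intersections(self, tol: float = 1e-3) -> List[np.ndarray]:
        """Pairwise intersection points of the two nullcline families."""
        from shapely.geometry import LineString

        pts: List[np.ndarray] = []
        for a in self.curves.get(0, []):
            if len(a) < 2:
                continue
            la = LineString(a)
            for b in self.curves.get(1, []):
                if len(b) < 2:
                    continue
                inter = la.intersection(LineString(b))
                if inter.is_empty:
                    continue
                geoms = getattr(inter, "geoms", [inter])
                for g in geoms:
                    if g.geom_type == "Point":
                        pts.append(np.array([g.x, g.y]))
                    else:  # overlapping segment: take its midpoint
                        c = g.centroid
                        pts.append(np.array([c.x, c.y]))
        # dedupe relative to box size
        scale = max(self.box[1] - self.box[0], self.box[3] - self.box[2])
        return _dedupe(np.array(pts) if pts else np.empty((0, 2)), tol * scale)


def nullclines(model, box=None, resolution: int = 500) -> NullclineSet:
    """Extract dx1/dt = 0 and dx2/dt = 0 curves by contouring on a warped grid.

    The grid is quadratically condensed toward the axes (x = ub * t^2) so that
    near-axis states — e.g. the (high, low) toggle branches — are resolved.
    """
    from skimage.measure import find_contours

    if model.dimension != 2:
        raise ValueError("nullclines are defined for two-gene circuits")
    if box is None:
        ubs = 1.05 * model.max_production / model._d0_vec
        box = (0.0, float(ubs[0]), 0.0, float(ubs[1]))
    t = np.linspace(0.0, 1.0, resolution)
    ax1 = box[0] + (box[1] - box[0]) * t**2
    ax2 = box[2] + (box[3] - box[2]) * t**2
    g1, g2 = np.meshgrid(ax1, ax2, indexing="ij")
    states = np.stack([g1, g2], axis=-1)
    rhs = model.rhs(states)
    ns = NullclineSet(box=box)
    for comp in (0, 1):
        curves = []
        for contour in find_contours(rhs[..., comp], 0.0):
            i, j = contour[:, 0], contour[:, 1]
            x1 = np.interp(i, np.arange(resolution), ax1)
            x2 = np.interp(j, np.arange(resolution), ax2)
            curves.append(np.column_stack([x1, x2]))
        ns.curves[comp] = curves
    return ns


@dataclass
class DirectionField:
    """Normalized flow vectors on a grid; zero_mask flags (near-)fixed points."""

    points: np.ndarray  # (N, dim)
    vectors: np.ndarray  # (N, dim) unit vectors (zero rows where flagged)
    zero_mask: np.ndarray  # (N,) bool


def direction_field(model, box, grid: int = 20, *, zero_tol_frac: float = 1e-9):
    """Evaluate the (normalized) flow direction on a regular grid.

    ``box`` is (lo, hi) for one-dimensional circuits or (lo1, hi1, lo2, hi2)
    for two-gene circuits.
    """
    if model.dimension == 1:
        lo, hi = box
        pts = np.linspace(lo, hi, grid)[:, None]
    else:
        lo1, hi1, lo2, hi2 = box
        g1, g2 = np.meshgrid(
            np.linspace(lo1, hi1, grid), np.linspace(lo2, hi2, grid), indexing="ij"
        )
        pts = np.column_stack([g1.ravel(), g2.ravel()])
    vec = model.rhs(pts)
    norm = np.linalg.norm(vec, axis=1)
    zero = norm < zero_tol_frac * _scale(model)
    unit = np.zeros_like(vec)
    unit[~zero] = vec[~zero] / norm[~zero, None]
    return DirectionField(points=pts, vectors=unit, zero_mask=zero)


def steady_states_table(states: Sequence[SteadyState]) -> pd.DataFrame:
    """Tabulate steady states (columns x1[, x2], stability, eigenvalue real
    parts, growth_rate, residual) for delimited-text export."""
    rows = []
    for s in states:
        row = {f"x{i + 1}": s.state[i] for i in range(len(s.state))}
        for i, ev in enumerate(np.atleast_1d(s.eigenvalues)):
            row[f"eig_re_{i + 1}"] = ev.real
        row["stability"] = s.stability
        row["growth_rate"] = s.growth_rate
        row["residual"] = s.residual
        rows.append(row)
    return pd.DataFrame(rows)
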