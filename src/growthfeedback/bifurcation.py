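"""Branch scans, saddle-node and pitchfork location, two-parameter boundaries.

The continuation strategy is enumerate-and-link: at every swept parameter
value all fixed points are enumerated globally (cheap in one and two
dimensions), linked into branches by nearest-neighbour matching, and the scan
grid bisected adaptively wherever the fixed-point count changes.  This cannot
lose disconnected branches and is robust arbitrarily close to a pitchfork,
where pseudo-arclength continuation needs special handling.

Saddle nodes are sharpened by Newton on the extended system
{rhs(x; p) = 0, det J(x; p) = 0}; the pitchfork of the exactly symmetric
toggle is found on the diagonal subspace x1 = x2, where the Jacobian is of
the form [[a, b], [b, a]] and the antisymmetric-mode eigenvalue a - b
crossing zero marks the symmetry-breaking point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, root

from .steady_states import SteadyState, find_steady_states, search_upper_bound

__all__ = [
    "BifurcationEvent",
    "BifurcationDiagram",
    "Branch",
    "RegionClass",
    "TwoParamBoundary",
    "branch_scan",
    "locate_fold",
    "locate_pitchfork",
    "classify_regions",
    "two_parameter_boundary",
]

#: adaptive refinement stops at this fraction of the sweep width
PARAM_RESOLUTION_FRAC = 1e-6

_CLASS_NAMES = {1: "mono", 2: "bi", 3: "tri", 4: "quad"}


@dataclass
class BifurcationEvent:
    """A detected codimension-one event along a parameter sweep."""

    type: str  # "saddle_node" | "pitchfork"
    param_value: float
    state: np.ndarray
    label: str = ""
    method: str = "scan"  # "newton" | "bisection" | "scan"
    merged: bool = False  # two events closer than the scan resolution
    bracket: Tuple[float, float] = (np.nan, np.nan)


@dataclass
class Branch:
    param_values: List[float] = field(default_factory=list)
    states: List[np.ndarray] = field(default_factory=list)
    stabilities: List[str] = field(default_factory=list)


@dataclass
class BifurcationDiagram:
    model: object
    param_name: str
    grid: np.ndarray
    states_by_param: List[List[SteadyState]]
    branches: List[Branch]
    events: List[BifurcationEvent]

    @property
    def saddle_nodes(self) -> List[BifurcationEvent]:
        return [e for e in self.events if e.type == "saddle_node"]

    @property
    def pitchforks(self) -> List[BifurcationEvent]:
        return [e for e in self.events if e.type == "pitchfork"]


def _states_at(model, param_name, value, find_kwargs) -> List[SteadyState]:
    return find_steady_states(model.replace(**{param_name: value}), **find_kwargs)


def _annihilating_pair(
    rich: Sequence[SteadyState], poor: Sequence[SteadyState]
) -> Tuple[np.ndarray, np.ndarray]:
    """The two rich-side states without a counterpart on the poor side.

    Each poor-side state greedily claims its nearest rich-side state; with a
    count change of two the leftover pair is the one annihilating at the
    event.  If matching is degenerate, falls back to the closest rich pair.
    """
    remaining = list(range(len(rich)))
    for s in poor:
        if not remaining:
            break
        dists = [float(np.max(np.abs(rich[i].state - s.state))) for i in remaining]
        remaining.pop(int(np.argmin(dists)))
    if len(remaining) != 2:
        best = (np.inf, 0, 1)
        for i in range(len(rich)):
            for j in range(i + 1, len(rich)):
                d = float(np.max(np.abs(rich[i].state - rich[j].state)))
                if d < best[0]:
                    best = (d, i, j)
        remaining = [best[1], best[2]]
    return rich[remaining[0]].state, rich[remaining[1]].state


def _event_type(
    model, s_lo: Sequence[SteadyState], s_hi: Sequence[SteadyState]
) -> Tuple[str, np.ndarray]:
    """Classify the event from the states on either side of its bracket.

    In an exactly symmetric toggle a pitchfork annihilates a swap-image pair
    (x, swap(x)) with x off the diagonal; a saddle node annihilates two
    states that are each (near-)symmetric or that are not swap images.
    """
    rich, poor = (s_lo, s_hi) if len(s_lo) > len(s_hi) else (s_hi, s_lo)
    a, b = _annihilating_pair(rich, poor)
    mid = 0.5 * (a + b)
    symmetric = getattr(model, "is_symmetric", False) and model.dimension == 2
    if symmetric:
        sep = float(np.linalg.norm(a - b))
        swap_err = float(np.linalg.norm(b - a[::-1]))
        if sep > 0 and swap_err < 1e-3 * sep:
            return "pitchfork", mid
    return "saddle_node", mid


def _refine_count_changes(
    model, param_name, p_lo, s_lo, p_hi, s_hi, tol, find_kwargs, out
):
    """Recursively bisect (p_lo, p_hi) where the fixed-point count changes."""
    if len(s_lo) == len(s_hi):
        return
    if p_hi - p_lo <= tol:
        out.append((p_lo, s_lo, p_hi, s_hi))
        return
    mid = 0.5 * (p_lo + p_hi)
    s_mid = _states_at(model, param_name, mid, find_kwargs)
    _refine_count_changes(
        model, param_name, p_lo, s_lo, mid, s_mid, tol, find_kwargs, out
    )
    _refine_count_changes(
        model, param_name, mid, s_mid, p_hi, s_hi, tol, find_kwargs, out
    )


def _link_branches(grid, states_by_param, x_ub) -> List[Branch]:
    open_branches: List[Branch] = []
    all_branches: List[Branch] = []
    thresh = 0.2 * x_ub
    for p, states in zip(grid, states_by_param):
        unmatched = list(states)
        next_open: List[Branch] = []
        for br in open_branches:
            last = br.states[-1]
            if unmatched:
                dists = [float(np.max(np.abs(s.state - last))) for s in unmatched]
                k = int(np.argmin(dists))
                if dists[k] < thresh:
                    s = unmatched.pop(k)
                    br.param_values.append(float(p))
                    br.states.append(s.state)
                    br.stabilities.append(s.stability)
                    next_open.append(br)
                    continue
            # branch ends here
        for s in unmatched:
            br = Branch([float(p)], [s.state], [s.stability])
            all_branches.append(br)
            next_open.append(br)
        open_branches = next_open
    return all_branches


def branch_scan(
    model,
    param_name: str,
    prange: Tuple[float, float],
    *,
    n_grid: int = 81,
    refine_events: bool = True,
    find_kwargs: Optional[dict] = None,
) -> BifurcationDiagram:
    """Sweep a parameter, enumerate all steady states, and detect events.

    Events are located by adaptive bisection of the fixed-point count down to
    a parameter resolution of 1e-6 of the sweep width, then (optionally)
    sharpened by the dedicated Newton/bisection locators.  Saddle nodes are
    labelled SN1, SN2, ... and pitchforks PF (PF1, PF2, ... if several) in
    ascending order of the swept parameter.
    """
    find_kwargs = find_kwargs or {}
    p_lo, p_hi = prange
    if not p_hi > p_lo:
        raise ValueError("empty parameter range")
    # validate the name early (replace raises on unknown keys)
    model.replace(**{param_name: model.get_param(param_name)})
    grid = np.linspace(p_lo, p_hi, n_grid)
    states_by_param = [_states_at(model, param_name, p, find_kwargs) for p in grid]

    tol = PARAM_RESOLUTION_FRAC * (p_hi - p_lo)
    raw_events: List[Tuple[float, List[SteadyState], float, List[SteadyState]]] = []
    for i in range(n_grid - 1):
        _refine_count_changes(
            model,
            param_name,
            grid[i],
            states_by_param[i],
            grid[i + 1],
            states_by_param[i + 1],
            tol,
            find_kwargs,
            raw_events,
        )

    events: List[BifurcationEvent] = []
    for q_lo, s_lo, q_hi, s_hi in raw_events:
        etype, state = _event_type(model, s_lo, s_hi)
        ev = BifurcationEvent(
            type=etype,
            param_value=0.5 * (q_lo + q_hi),
            state=state,
            merged=abs(len(s_lo) - len(s_hi)) > 2,
            bracket=(q_lo, q_hi),
        )
        if refine_events and not ev.merged:
            pad = max(10 * tol, 1e-12)
            bracket = (max(q_lo - pad, p_lo), min(q_hi + pad, p_hi))
            try:
                if etype == "saddle_node":
                    ev = locate_fold(
                        model, param_name, bracket, find_kwargs=find_kwargs
                    )
                else:
                    ev = locate_pitchfork(model, bracket, param_name=param_name)
            except Exception:
                ev.method = "scan"
        events.append(ev)
    events.sort(key=lambda e: e.param_value)
    n_sn = 0
    n_pf = sum(1 for e in events if e.type == "pitchfork")
    pf_seen = 0
    for e in events:
        if e.type == "saddle_node":
            n_sn += 1
            e.label = f"SN{n_sn}"
        else:
            pf_seen += 1
            e.label = "PF" if n_pf == 1 else f"PF{pf_seen}"

    x_ub = search_upper_bound(model)
    branches = _link_branches(grid, states_by_param, x_ub)
    return BifurcationDiagram(
        model=model,
        param_name=param_name,
        grid=grid,
        states_by_param=states_by_param,
        branches=branches,
        events=events,
    )


def _count_states(model, param_name, value, find_kwargs) -> int:
    return len(_states_at(model, param_name, value, find_kwargs))


def locate_fold(
    model,
    param_name: str,
    bracket: Tuple[float, float],
    *,
    find_kwargs: Optional[dict] = None,
) -> BifurcationEvent:
    """Sharpen a saddle node inside ``bracket`` (state count changes by 2).

    Newton solves the extended system {rhs = 0, det J = 0} in (state, param);
    if Newton diverges or leaves the bracket, falls back to bisection on the
    state count (method recorded on the returned event).
    """
    find_kwargs = find_kwargs or {}
    q_lo, q_hi = bracket
    s_lo = _states_at(model, param_name, q_lo, find_kwargs)
    s_hi = _states_at(model, param_name, q_hi, find_kwargs)
    if len(s_lo) == len(s_hi):
        raise ValueError("bracket does not contain a state-count change")
    _, x0 = _event_type(model, s_lo, s_hi)
    p0 = 0.5 * (q_lo + q_hi)
    dim = model.dimension

    def extended(z):
        x, p = np.maximum(z[:dim], 0.0), z[dim]
        mod = model.replace(**{param_name: p})
        F = mod.rhs(x)
        J = mod.jacobian(x)
        return np.append(F, np.linalg.det(J))

    sol = root(extended, np.append(x0, p0), method="hybr", tol=1e-14)
    p_star = float(sol.x[dim])
    resid = float(np.max(np.abs(extended(sol.x))))
    if sol.success and resid < 1e-10 and q_lo - 1e-9 <= p_star <= q_hi + 1e-9:
        return BifurcationEvent(
            type="saddle_node",
            param_value=p_star,
            state=np.maximum(sol.x[:dim], 0.0),
            method="newton",
            bracket=bracket,
        )
    # fallback: bisect on the state count
    lo, hi = q_lo, q_hi
    n_lo = len(s_lo)
    for _ in range(200):
        if hi - lo < 1e-13 * max(abs(hi), 1.0):
            break
        mid = 0.5 * (lo + hi)
        if _count_states(model, param_name, mid, find_kwargs) == n_lo:
            lo = mid
        else:
            hi = mid
    _, x_mid = _event_type(
        model,
        _states_at(model, param_name, lo, find_kwargs),
        _states_at(model, param_name, hi, find_kwargs),
    )
    return BifurcationEvent(
        type="saddle_node",
        param_value=0.5 * (lo + hi),
        state=x_mid,
        method="bisection",
        bracket=bracket,
    )


def _symmetric_sub_roots(model, n_scan: int = 4000) -> List[float]:
    """Fixed points of the symmetric toggle restricted to the diagonal x1 = x2."""
    ub = search_upper_bound(model)

    def psi(x):
        return float(model.rhs(np.array([x, x]))[0])

    lin = np.linspace(ub / n_scan, ub, n_scan)
    log = np.geomspace(ub * 1e-9, ub, n_scan)
    grid = np.unique(np.concatenate(([0.0], lin, log)))
    vals = model.rhs(np.column_stack([grid, grid]))[:, 0]
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    return [brentq(psi, grid[i], grid[i + 1], xtol=1e-300, rtol=9e-16) for i in idx]


def _max_antisymmetric_eigenvalue(model) -> Tuple[float, Optional[np.ndarray]]:
    best, best_state = -np.inf, None
    for r in _symmetric_sub_roots(model):
        state = np.array([r, r])
        J = model.jacobian(state)
        lam = float(J[0, 0] - J[0, 1])  # antisymmetric (1, -1) mode
        if lam > best:
            best, best_state = lam, state
    return best, best_state


def locate_pitchfork(
    model,
    bracket: Tuple[float, float],
    *,
    param_name: str = "kg0",
) -> BifurcationEvent:
    """Locate the symmetry-breaking pitchfork of an exactly symmetric toggle.

    On the diagonal the system reduces to one dimension; the pitchfork is
    where the antisymmetric-mode eigenvalue a - b of the full Jacobian
    [[a, b], [b, a]] crosses zero, found by bisection over the bracket.
    """
    if model.dimension != 2 or not getattr(model, "is_symmetric", False):
        raise ValueError(
            "pitchfork location requires a perfectly symmetric toggle "
            "parameter setting"
        )

    def phi(p):
        lam, _ = _max_antisymmetric_eigenvalue(model.replace(**{param_name: p}))
        return lam

    q_lo, q_hi = bracket
    f_lo, f_hi = phi(q_lo), phi(q_hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            "bracket does not straddle an antisymmetric eigenvalue crossing"
        )
    p_star = brentq(phi, q_lo, q_hi, xtol=1e-300, rtol=9e-16)
    _, state = _max_antisymmetric_eigenvalue(model.replace(**{param_name: p_star}))
    return BifurcationEvent(
        type="pitchfork",
        param_value=p_star,
        state=state,
        label="PF",
        method="bisection",
        bracket=bracket,
    )


@dataclass
class RegionClass:
    param_lo: float
    param_hi: float
    n_stable: int
    n_states: int
    label: str


def classify_regions(
    diagram: BifurcationDiagram, *, find_kwargs: Optional[dict] = None
) -> List[RegionClass]:
    """Multistability class of each interval between consecutive events.

    The class is verified by direct enumeration of stable states at the
    interval midpoint ("mono", "bi", "tri", "quad", else "multi-k").
    """
    find_kwargs = find_kwargs or {}
    edges = (
        [float(diagram.grid[0])]
        + [e.param_value for e in diagram.events]
        + [float(diagram.grid[-1])]
    )
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        mid = 0.5 * (lo + hi)
        states = _states_at(diagram.model, diagram.param_name, mid, find_kwargs)
        n_stable = sum(1 for s in states if s.stability == "stable")
        out.append(
            RegionClass(
                param_lo=lo,
                param_hi=hi,
                n_stable=n_stable,
                n_states=len(states),
                label=_CLASS_NAMES.get(n_stable, f"multi-{n_stable}"),
            )
        )
    return out


@dataclass
class TwoParamBoundary:
    """Fold/pitchfork curves in a two-parameter plane (p1 swept outer, p2 inner)."""

    p1_name: str
    p2_name: str
    p1_values: np.ndarray
    events_by_p1: Dict[float, List[BifurcationEvent]]
    curves: Dict[str, List[Tuple[float, float]]]  # label -> [(p1, p2), ...]
    model: object

    def stable_state_count(self, p1: float, p2: float) -> int:
        mod = self.model.replace(**{self.p1_name: p1, self.p2_name: p2})
        return sum(1 for s in find_steady_states(mod) if s.stability == "stable")


def two_parameter_boundary(
    model,
    p1_name: str = "m",
    p2_name: str = "kg0",
    p1_values=None,
    p2_range: Tuple[float, float] = (0.02, 2.0),
    *,
    n_grid: int = 61,
    refine_events: bool = True,
    find_kwargs: Optional[dict] = None,
) -> TwoParamBoundary:
    """Trace bifurcation-event curves over a (p1, p2) plane.

    For each p1 value a full p2 branch scan locates every event; events are
    then stitched into labelled curves by matching each event to the nearest
    same-type event of the previous p1 row.  Labels are assigned from the row
    with the most events (ascending p2).
    """
    if p1_values is None:
        p1_values = np.linspace(1.2, 3.0, 7)
    p1_values = np.asarray(p1_values, dtype=float)
    events_by_p1: Dict[float, List[BifurcationEvent]] = {}
    for p1 in p1_values:
        mod = model.replace(**{p1_name: p1})
        diag = branch_scan(
            mod,
            p2_name,
            p2_range,
            n_grid=n_grid,
            refine_events=refine_events,
            find_kwargs=find_kwargs,
        )
        events_by_p1[float(p1)] = diag.events

    # anchor labels on the row with the most events
    anchor_p1 = max(events_by_p1, key=lambda p: len(events_by_p1[p]))
    anchor = sorted(events_by_p1[anchor_p1], key=lambda e: e.param_value)
    labels = [e.label for e in anchor]
    curves: Dict[str, List[Tuple[float, float]]] = {lab: [] for lab in labels}
    for p1 in sorted(events_by_p1):
        evs = events_by_p1[p1]
        used = set()
        for ev in evs:
            cands = [
                (abs(ev.param_value - a.param_value), i)
                for i, a in enumerate(anchor)
                if a.type == ev.type and i not in used
            ]
            if not cands:
                continue
            _, i = min(cands)
            used.add(i)
            curves[labels[i]].append((float(p1), float(ev.param_value)))
    return TwoParamBoundary(
        p1_name=p1_name,
        p2_name=p2_name,
        p1_values=p1_values,
        events_by_p1=events_by_p1,
        curves=curves,
        model=model,
    )
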