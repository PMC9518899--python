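"""Gene-circuit ODE models coupled to ultrasensitive growth feedback.

All circuits share the host-coupling structure

    dx_i/dt = f_i(x) - d0_i * x_i - GR(x) * x_i,
    GR(x)   = kg0 / ((sum_i x_i / J)^m + 1),

where ``f_i`` is circuit-specific production, ``d0_i`` is first-order
degradation, and the last term is dilution by host growth.  Expression of the
circuit burdens the host (GR decreases with total expression, with Hill
sensitivity ``m``), and growth in turn dilutes the circuit product — a
double-negative feedback loop between circuit and host.

Units: expression in arbitrary units (a.u.), time in hours; rates in a.u./h
or 1/h.  States are arrays whose *last* axis is the circuit dimension, so all
model methods broadcast over batches of states.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import ClassVar, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GrowthFeedbackParams",
    "ConstitutiveCircuit",
    "SelfActivationCircuit",
    "ToggleCircuit",
    "Trajectory",
    "growth_rate",
    "growth_rate_gradient",
    "integrate_trajectory",
]


def _xpow(x, p):
    """x**p for x >= 0 with the conventions 0**p = 0 (p > 0) and 0**0 = 1."""
    x = np.asarray(x, dtype=float)
    if p == 0:
        return np.ones_like(x)
    safe = np.where(x > 0.0, x, 1.0)
    return np.where(x > 0.0, np.power(safe, p), 0.0)


@dataclass(frozen=True)
class GrowthFeedbackParams:
    """Parameters of the growth-rate Hill function GR(x) = kg0/((x/J)^m + 1).

    kg0 : maximal host growth rate without burden [1/h]
    J   : expression capacity — total expression at half-maximal growth [a.u.]
    m   : metabolic-burden sensitivity (Hill coefficient); m > 1 means
          ultrasensitive growth feedback
    """

    kg0: float
    J: float
    m: float

    def __post_init__(self):
        if not self.kg0 >= 0:
            raise ValueError(f"kg0 must be >= 0, got {self.kg0}")
        if not self.J > 0:
            raise ValueError(f"J must be > 0, got {self.J}")
        if not self.m >= 0:
            raise ValueError(f"m must be >= 0, got {self.m}")


def growth_rate(gf: GrowthFeedbackParams, total_expression):
    """Host growth rate at a given total circuit expression [1/h].

    Strictly decreasing in expression for m > 0, bounded in [0, kg0];
    GR(0) = kg0 and GR(J) = kg0/2 for any m.
    """
    x = np.asarray(total_expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("total expression must be nonnegative")
    u = _xpow(x / gf.J, gf.m)
    out = gf.kg0 / (u + 1.0)
    return out if out.ndim else float(out)


def growth_rate_gradient(gf: GrowthFeedbackParams, total_expression):
    """dGR/dx at total expression x (nonpositive for m > 0).

    At x = 0 the one-sided derivative is 0 for m > 1, -kg0*m/J for m = 1, and
    -inf for 0 < m < 1 (outside the regime of interest m >= 1).
    """
    x = np.asarray(total_expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("total expression must be nonnegative")
    kg0, J, m = gf.kg0, gf.J, gf.m
    if m == 0:
        return np.zeros_like(x) if x.ndim else 0.0
    u = _xpow(x / J, m)
    safe_x = np.where(x > 0.0, x, 1.0)
    grad_pos = -kg0 * m * u / (safe_x * (1.0 + u) ** 2)
    if m > 1:
        at0 = 0.0
    elif m == 1:
        at0 = -kg0 * m / J
    else:
        at0 = -np.inf
    out = np.where(x > 0.0, grad_pos, at0)
    return out if out.ndim else float(out)


@dataclass
class Trajectory:
    """A solved time course: times [h], states [a.u.], growth rates [1/h]."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, dimension)
    growth_rates: np.ndarray

    def __post_init__(self):
        if not (len(self.times) == len(self.states) == len(self.growth_rates)):
            raise ValueError("times/states/growth_rates length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


class CircuitModel:
    """Shared machinery for growth-feedback-coupled circuits.

    Subclasses provide ``production_rate`` and ``_production_jacobian`` plus
    parameter bookkeeping; the loss term (degradation + dilution), the full
    right-hand side, and the analytic Jacobian are common.
    """

    kind: ClassVar[str]
    dimension: ClassVar[int]

    gf: GrowthFeedbackParams

    # -- state handling ---------------------------------------------------
    def _prep(self, state) -> np.ndarray:
        arr = np.asarray(state, dtype=float)
        if self.dimension == 1:
            if arr.ndim == 0 or arr.shape[-1] != 1:
                arr = arr[..., None]
        elif arr.ndim == 0 or arr.shape[-1] != self.dimension:
            raise ValueError(
                f"state last axis must have length {self.dimension}, "
                f"got shape {arr.shape}"
            )
        if np.any(arr < 0):
            raise ValueError("state must be nonnegative")
        return arr

    def total_expression(self, state):
        return self._prep(state).sum(axis=-1)

    @property
    def _d0_vec(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def basal_production(self) -> np.ndarray:
        """Per-gene production at the origin (must be positive for the
        fixed-point machinery: rhs(0) > 0 componentwise)."""
        raise NotImplementedError

    @property
    def max_production(self) -> np.ndarray:
        raise NotImplementedError

    # -- rates -------------------------------------------------------------
    def production_rate(self, state) -> np.ndarray:
        raise NotImplementedError

    def _production_jacobian(self, state) -> np.ndarray:
        raise NotImplementedError

    def loss_rate(self, state) -> np.ndarray:
        """Per-gene loss (d0_i + GR(sum x)) * x_i [a.u./h].

        Bounded between the pure-degradation line d0*x and the maximal
        dilution line (d0 + kg0)*x.
        """
        x = self._prep(state)
        gr = growth_rate(self.gf, x.sum(axis=-1))
        return (self._d0_vec + np.asarray(gr)[..., None]) * x

    def rhs(self, state) -> np.ndarray:
        """Time derivative of the state: production - (degradation + dilution)."""
        x = self._prep(state)
        return self.production_rate(x) - self.loss_rate(x)

    def jacobian(self, state) -> np.ndarray:
        """Analytic Jacobian of ``rhs``, shape (..., dim, dim).

        Includes the growth-coupling cross terms -x_i * dGR/dx_j (dGR/dx_j is
        the same for every j because GR depends on the summed expression).
        """
        x = self._prep(state)
        total = x.sum(axis=-1)
        gr = np.asarray(growth_rate(self.gf, total))
        grad = np.asarray(growth_rate_gradient(self.gf, total))
        jac = self._production_jacobian(x).copy()
        jac -= x[..., :, None] * grad[..., None, None]
        diag = self._d0_vec + gr[..., None]
        idx = np.arange(self.dimension)
        jac[..., idx, idx] -= diag
        return jac

    # -- parameter access --------------------------------------------------
    _GF_KEYS: ClassVar[Tuple[str, ...]] = ("kg0", "J", "m")

    def _own_replace(self, changes: dict) -> "CircuitModel":
        raise NotImplementedError

    def replace(self, **changes) -> "CircuitModel":
        """Return a copy with named parameters replaced (e.g. kg0=1.2, k1_1=0.21)."""
        gf_changes = {k: changes.pop(k) for k in list(changes) if k in self._GF_KEYS}
        out = self._own_replace(changes) if changes else self
        if gf_changes:
            out = dataclasses.replace(out, gf=dataclasses.replace(out.gf, **gf_changes))
        return out

    def get_param(self, name: str) -> float:
        if name in self._GF_KEYS:
            return getattr(self.gf, name)
        return self._own_get(name)

    def _own_get(self, name: str) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class ConstitutiveCircuit(CircuitModel):
    """One gene under a constitutive promoter: f(x) = k0 (state-independent)."""

    k0: float
    d0: float
    gf: GrowthFeedbackParams
    kind: ClassVar[str] = "constitutive"
    dimension: ClassVar[int] = 1
    _PARAM_NAMES: ClassVar[Tuple[str, ...]] = ("k0", "d0")

    def __post_init__(self):
        if not self.k0 >= 0:
            raise ValueError("k0 must be >= 0")
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")

    @property
    def _d0_vec(self):
        return np.array([self.d0])

    @property
    def basal_production(self):
        return np.array([self.k0])

    @property
    def max_production(self):
        return np.array([self.k0])

    def production_rate(self, state):
        x = self._prep(state)
        return np.broadcast_to(self.k0, x.shape).copy()

    def _production_jacobian(self, state):
        x = self._prep(state)
        return np.zeros(x.shape + (1,))

    def _own_replace(self, changes):
        for key in changes:
            if key not in self._PARAM_NAMES:
                raise ValueError(f"unknown {self.kind} parameter {key!r}")
        return dataclasses.replace(self, **changes)

    def _own_get(self, name):
        if name not in self._PARAM_NAMES:
            raise ValueError(f"unknown {self.kind} parameter {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class SelfActivationCircuit(CircuitModel):
    """One self-activating gene: f(x) = k0 + k1 * x^n / (x^n + K^n).

    k0 basal production, k1 maximal inducible production [a.u./h], K the
    activation dissociation constant [a.u.], n the circuit Hill coefficient.
    """

    k0: float
    k1: float
    K: float
    n: float
    d0: float
    gf: GrowthFeedbackParams
    kind: ClassVar[str] = "self_activation"
    dimension: ClassVar[int] = 1
    _PARAM_NAMES: ClassVar[Tuple[str, ...]] = ("k0", "k1", "K", "n", "d0")

    def __post_init__(self):
        if self.k0 < 0 or self.k1 < 0:
            raise ValueError("k0 and k1 must be >= 0")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if not self.n >= 1:
            raise ValueError("n must be >= 1")
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")

    @property
    def _d0_vec(self):
        return np.array([self.d0])

    @property
    def basal_production(self):
        return np.array([self.k0])

    @property
    def max_production(self):
        return np.array([self.k0 + self.k1])

    def production_rate(self, state):
        x = self._prep(state)[..., 0]
        xn = _xpow(x, self.n)
        return (self.k0 + self.k1 * xn / (xn + self.K**self.n))[..., None]

    def _production_jacobian(self, state):
        x = self._prep(state)[..., 0]
        xn = _xpow(x, self.n)
        Kn = self.K**self.n
        deriv = self.k1 * self.n * Kn * _xpow(x, self.n - 1.0) / (xn + Kn) ** 2
        return deriv[..., None, None]

    def _own_replace(self, changes):
        for key in changes:
            if key not in self._PARAM_NAMES:
                raise ValueError(f"unknown {self.kind} parameter {key!r}")
        return dataclasses.replace(self, **changes)

    def _own_get(self, name):
        if name not in self._PARAM_NAMES:
            raise ValueError(f"unknown {self.kind} parameter {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class ToggleCircuit(CircuitModel):
    """Two mutually repressing genes sharing the host's growth feedback.

    dx_i/dt = k0_i + k1_i * K_i^n_i / (x_j^n_i + K_i^n_i)
              - d0_i * x_i - GR(x1 + x2) * x_i     (j != i)

    k0_i basal and k1_i maximal inducible expression [a.u./h]; K_i the
    repressor level giving half inhibition [a.u.]; n_i the repression
    sensitivity.  Parameters are (gene-1, gene-2) pairs.
    """

    k0: Tuple[float, float]
    k1: Tuple[float, float]
    K: Tuple[float, float]
    n: Tuple[float, float]
    d0: Tuple[float, float]
    gf: GrowthFeedbackParams
    kind: ClassVar[str] = "toggle"
    dimension: ClassVar[int] = 2

    def __post_init__(self):
        for name in ("k0", "k1", "K", "n", "d0"):
            val = getattr(self, name)
            if len(val) != 2:
                raise ValueError(f"{name} must be a (gene-1, gene-2) pair")
            object.__setattr__(self, name, (float(val[0]), float(val[1])))
        if any(v < 0 for v in self.k0 + self.k1):
            raise ValueError("rates must be >= 0")
        if any(v <= 0 for v in self.K):
            raise ValueError("K must be > 0")
        if any(v < 1 for v in self.n):
            raise ValueError("n must be >= 1")
        if any(v <= 0 for v in self.d0):
            raise ValueError("d0 must be > 0")

    @property
    def is_symmetric(self) -> bool:
        return all(
            getattr(self, name)[0] == getattr(self, name)[1]
            for name in ("k0", "k1", "K", "n", "d0")
        )

    @property
    def _d0_vec(self):
        return np.asarray(self.d0, dtype=float)

    @property
    def basal_production(self):
        return np.asarray(self.k0, dtype=float)

    @property
    def max_production(self):
        return np.asarray(self.k0, dtype=float) + np.asarray(self.k1, dtype=float)

    def production_rate(self, state):
        x = self._prep(state)
        out = np.empty_like(x)
        for i, j in ((0, 1), (1, 0)):
            Kn = self.K[i] ** self.n[i]
            xn = _xpow(x[..., j], self.n[i])
            out[..., i] = self.k0[i] + self.k1[i] * Kn / (xn + Kn)
        return out

    def _production_jacobian(self, state):
        x = self._prep(state)
        jac = np.zeros(x.shape + (2,))
        for i, j in ((0, 1), (1, 0)):
            Kn = self.K[i] ** self.n[i]
            xn = _xpow(x[..., j], self.n[i])
            jac[..., i, j] = (
                -self.k1[i]
                * Kn
                * self.n[i]
                * _xpow(x[..., j], self.n[i] - 1.0)
                / (xn + Kn) ** 2
            )
        return jac

    _PAIR_KEYS: ClassVar[Tuple[str, ...]] = ("k0", "k1", "K", "n", "d0")

    def _own_replace(self, changes):
        fields: dict = {}
        for key, val in changes.items():
            if key in self._PAIR_KEYS:
                fields[key] = (float(val), float(val))
                continue
            base, _, idx = key.rpartition("_")
            if base in self._PAIR_KEYS and idx in ("1", "2"):
                pair = list(fields.get(base, getattr(self, base)))
                pair[int(idx) - 1] = float(val)
                fields[base] = tuple(pair)
            else:
                raise ValueError(f"unknown toggle parameter {key!r}")
        return dataclasses.replace(self, **fields)

    def _own_get(self, name):
        base, _, idx = name.rpartition("_")
        if base in self._PAIR_KEYS and idx in ("1", "2"):
            return getattr(self, base)[int(idx) - 1]
        raise ValueError(f"unknown toggle parameter {name!r}")


def integrate_trajectory(
    model,
    x0,
    t_end: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    n_eval: int = 200,
) -> Trajectory:
    """Integrate the circuit ODE from ``x0`` for ``t_end`` hours.

    Uses a stiff-capable solver by default: degradation and growth rates span
    about three orders of magnitude in the reference parameter sets, which
    makes the flow moderately stiff.  States are kept nonnegative by solver
    accuracy (no projection), so a failed run raises rather than clipping.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (model.dimension,):
        raise ValueError(f"x0 must have shape ({model.dimension},)")
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")

    def f(_t, y):
        return model.rhs(np.maximum(y, 0.0))

    def jac(_t, y):
        return model.jacobian(np.maximum(y, 0.0))

    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(
        f,
        (0.0, t_end),
        x0,
        method=method,
        jac=jac if method in ("LSODA", "BDF", "Radau") else None,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T
    if np.any(states < -10 * atol):
        raise RuntimeError("integration produced significantly negative states")
    totals = np.maximum(states, 0.0).sum(axis=1)
    grs = np.asarray(growth_rate(model.gf, totals))
    return Trajectory(times=sol.t, states=states, growth_rates=grs)
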