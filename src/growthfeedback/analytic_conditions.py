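"""Closed-form analysis of the constitutive circuit's loss curve.

For the constitutive circuit the loss (degradation + dilution) curve is

    d(x) = (d0 + kg0 / ((x/J)^m + 1)) * x.

Bistability requires d(x) to be nonmonotonic (a local maximum followed by a
local minimum) with the constant production k0 between the two extreme loss
values.  Substituting u = (x/J)^m, the stationarity condition d'(x) = 0 reads

    g(u) := ((m - 1) u - 1) / (1 + u)^2 = d0 / kg0,

and g peaks at u* = (m + 1)/(m - 1) with g(u*) = (m - 1)^2 / (4 m).  Hence
extrema exist iff kg0/d0 > 4 m / (m - 1)^2 — a boundary independent of J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_models import ConstitutiveCircuit

__all__ = [
    "LossCurveExtrema",
    "nonmonotonicity_threshold",
    "loss_curve_extrema",
    "bistable_k0_range",
    "delta_d_surface",
    "delta_d_table",
]

#: draws closer to the boundary than this (relative) are reported as marginal
TANGENCY_RTOL = 1e-9


def nonmonotonicity_threshold(m: float) -> float:
    """Critical kg0/d0 ratio above which the loss curve d(x) is nonmonotonic.

    Returns 4m/(m-1)^2; +inf for m <= 1 (no burden ultrasensitivity, no
    nonmonotonicity, hence no growth-feedback bistability).  The threshold
    does not involve J.
    """
    if m <= 1:
        return math.inf
    return 4.0 * m / (m - 1.0) ** 2


@dataclass(frozen=True)
class LossCurveExtrema:
    """Local maximum/minimum of d(x), when they exist (x_at_max < x_at_min)."""

    exists: bool
    marginal: bool = False
    x_at_max: Optional[float] = None
    x_at_min: Optional[float] = None
    d_at_max: Optional[float] = None
    d_at_min: Optional[float] = None

    @property
    def delta_d(self) -> float:
        """d(x_max) - d(x_min); 0 when the curve is monotonic."""
        if not self.exists:
            return 0.0
        return self.d_at_max - self.d_at_min


def _g(u: float, m: float) -> float:
    return ((m - 1.0) * u - 1.0) / (1.0 + u) ** 2


def _d_of_x(p: ConstitutiveCircuit, x: float) -> float:
    u = (x / p.gf.J) ** p.gf.m
    return (p.d0 + p.gf.kg0 / (1.0 + u)) * x


def loss_curve_extrema(p: ConstitutiveCircuit) -> LossCurveExtrema:
    """Locate the local maximum and minimum of the loss curve d(x).

    The stationarity equation is solved in u = (x/J)^m space, where the
    left-hand side is single-humped: one root is bracketed in
    (1/(m-1), u*) and the other in (u*, U) with u* = (m+1)/(m-1) and U grown
    geometrically until the sign changes.  The smaller root maps to the local
    maximum of d (d' changes + to -), the larger to the local minimum.
    """
    m, kg0, J = p.gf.m, p.gf.kg0, p.gf.J
    if m <= 1 or kg0 <= 0:
        return LossCurveExtrema(exists=False)
    ratio = p.d0 / kg0
    peak = (m - 1.0) ** 2 / (4.0 * m)
    if ratio >= peak * (1.0 - TANGENCY_RTOL):
        return LossCurveExtrema(
            exists=False, marginal=abs(ratio - peak) <= peak * TANGENCY_RTOL
        )

    u_star = (m + 1.0) / (m - 1.0)

    def h(u):
        return _g(u, m) - ratio

    u_lo = brentq(h, 1.0 / (m - 1.0), u_star, xtol=1e-300, rtol=9e-16)
    hi = u_star * 2.0
    while h(hi) > 0.0:
        hi *= 2.0
        if hi > 1e300:  # pragma: no cover - ratio > 0 guarantees termination
            raise RuntimeError("failed to bracket upper extremum")
    u_hi = brentq(h, u_star, hi, xtol=1e-300, rtol=9e-16)

    x_max = J * u_lo ** (1.0 / m)
    x_min = J * u_hi ** (1.0 / m)
    return LossCurveExtrema(
        exists=True,
        x_at_max=x_max,
        x_at_min=x_min,
        d_at_max=_d_of_x(p, x_max),
        d_at_min=_d_of_x(p, x_min),
    )


def bistable_k0_range(p: ConstitutiveCircuit) -> Optional[Tuple[float, float]]:
    """Open interval of production rates k0 giving three steady states.

    Returns (d(x_min), d(x_max)) when the loss curve is nonmonotonic, else
    None: any k0 strictly inside the interval intersects d(x) three times.
    """
    ext = loss_curve_extrema(p)
    if not ext.exists:
        return None
    return (ext.d_at_min, ext.d_at_max)


def delta_d_surface(
    d0: float,
    J: float,
    m_values,
    kg0_values,
) -> np.ndarray:
    """Grid of delta_d = d(x_max) - d(x_min) over (m, kg0).

    Shape (len(m_values), len(kg0_values)); 0 where the curve is monotonic.
    The positive region coincides with kg0/d0 > 4m/(m-1)^2 and delta_d grows
    with both m and kg0, so larger burden sensitivity or faster maximal
    growth widens the k0 window for bistability.
    """
    from .core_models import GrowthFeedbackParams

    m_values = np.asarray(m_values, dtype=float)
    kg0_values = np.asarray(kg0_values, dtype=float)
    out = np.zeros((m_values.size, kg0_values.size))
    for i, m in enumerate(m_values):
        for j, kg0 in enumerate(kg0_values):
            p = ConstitutiveCircuit(
                k0=1.0, d0=d0, gf=GrowthFeedbackParams(kg0=kg0, J=J, m=m)
            )
            out[i, j] = loss_curve_extrema(p).delta_d
    return out


def delta_d_table(d0: float, J: float, m_values, kg0_values) -> pd.DataFrame:
    """Long-format (m, kg0, delta_d) table, convenient for export/plotting."""
    surface = delta_d_surface(d0, J, m_values, kg0_values)
    mm, kk = np.meshgrid(m_values, kg0_values, indexing="ij")
    return pd.DataFrame(
        {"m": mm.ravel(), "kg0": kk.ravel(), "delta_d": surface.ravel()}
    )
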