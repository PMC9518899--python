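"""Nonlinear least-squares fitting of the growth-rate Hill function.

Fits GR(x) = kg0 / ((x/J)^m + 1) to (expression, growth-rate) observations
and reports the metabolic-burden sensitivity m with approximate confidence
intervals.  Positivity of all three parameters is enforced by optimising in
log space; identifiability is fragile when the data do not straddle J, so the
fit flags weakly constrained m estimates and the ultrasensitivity verdict is
withheld in that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .core_models import GrowthFeedbackParams, growth_rate

__all__ = [
    "GrowthDataset",
    "FitResult",
    "fit_growth_hill",
    "fit_growth_hill_joint",
    "predict",
    "ultrasensitivity_test",
    "read_growth_data",
    "write_growth_data",
]

MIN_OBSERVATIONS = 4  # three parameters need at least four points
#: standard error of log(m) above which the fit is flagged weakly identified
WEAK_SE_LOG_M = 0.5


@dataclass
class GrowthDataset:
    """Growth-rate-vs-expression observations for one culture condition."""

    expression: np.ndarray
    growth_rate: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        self.growth_rate = np.asarray(self.growth_rate, dtype=float)
        if self.expression.shape != self.growth_rate.shape:
            raise ValueError("expression and growth_rate must match in length")
        if np.any(self.expression < 0) or np.any(self.growth_rate < 0):
            raise ValueError("expression and growth rate must be nonnegative")

    def __len__(self) -> int:
        return self.expression.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expression": self.expression,
                "growth_rate": self.growth_rate,
                "condition": self.condition,
            }
        )


def read_growth_data(path) -> Dict[str, GrowthDataset]:
    """Read delimited text with columns expression, growth_rate, condition."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "condition" not in df.columns:
        df["condition"] = ""
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        out[str(cond)] = GrowthDataset(
            expression=grp["expression"].to_numpy(),
            growth_rate=grp["growth_rate"].to_numpy(),
            condition=str(cond),
        )
    return out


def write_growth_data(datasets: Sequence[GrowthDataset], path) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class FitResult:
    """Fitted (kg0, J, m) with curvature-based approximate 95% intervals."""

    kg0: float
    J: float
    m: float
    rss: float
    n_obs: int
    converged: bool
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    se_log: Dict[str, float] = field(default_factory=dict)
    weak_identifiability: bool = False
    condition: str = ""

    @property
    def params(self) -> GrowthFeedbackParams:
        return GrowthFeedbackParams(kg0=self.kg0, J=self.J, m=self.m)


def _default_init(data: GrowthDataset) -> np.ndarray:
    kg0 = float(np.max(data.growth_rate))
    if kg0 <= 0:
        kg0 = 1.0
    half = 0.5 * kg0
    order = np.argsort(data.expression)
    x_s, y_s = data.expression[order], data.growth_rate[order]
    below = np.nonzero(y_s <= half)[0]
    if below.size and below[0] > 0:
        i = below[0]
        # linear interpolation of the half-max crossing
        x0, x1, y0, y1 = x_s[i - 1], x_s[i], y_s[i - 1], y_s[i]
        J = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x1
    else:
        J = float(np.median(x_s[x_s > 0])) if np.any(x_s > 0) else 1.0
    J = max(J, 1e-6)
    return np.array([kg0, J, 1.5])  # m = 1.5: midpoint of the plausible range


def _residuals(theta_log: np.ndarray, x: np.ndarray, y: np.ndarray, weights):
    kg0, J, m = np.exp(theta_log)
    u = np.where(x > 0, (x / J) ** m, 0.0)
    r = kg0 / (u + 1.0) - y
    return r * weights if weights is not None else r


def fit_growth_hill(
    data: GrowthDataset,
    *,
    init: Optional[Tuple[float, float, float]] = None,
    n_restarts: int = 8,
    seed: int = 0,
    relative_weighting: bool = False,
) -> FitResult:
    """Fit GR(x) = kg0/((x/J)^m + 1) by multi-start nonlinear least squares.

    Ordinary (unweighted) least squares on the growth rate by default;
    ``relative_weighting`` divides residuals by the observed rates instead.
    Restarts perturb the heuristic initialization (kg0 = max rate, J at the
    interpolated half-maximum, m = 1.5) in log space; the best residual sum
    of squares wins.  Deterministic for a fixed seed.
    """
    if len(data) < MIN_OBSERVATIONS:
        raise ValueError(
            f"need at least {MIN_OBSERVATIONS} observations, got {len(data)}"
        )
    if not np.any(data.expression > 0):
        raise ValueError("all expression values are zero; J and m unidentifiable")

    x, y = data.expression, data.growth_rate
    weights = None
    if relative_weighting:
        weights = 1.0 / np.maximum(y, 1e-3 * max(float(np.max(y)), 1e-30))

    theta0 = np.log(np.asarray(init, dtype=float) if init is not None else _default_init(data))
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.normal(scale=0.5, size=3) for _ in range(max(n_restarts - 1, 0))
    ]

    best = None
    for start in starts:
        try:
            sol = least_squares(
                _residuals,
                start,
                args=(x, y, weights),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        rss = float(np.sum(_residuals(sol.x, x, y, None) ** 2))
        if best is None or rss < best[0] - 1e-30:
            best = (rss, sol)
    if best is None:
        return FitResult(
            kg0=np.nan, J=np.nan, m=np.nan, rss=np.inf, n_obs=len(data),
            converged=False, condition=data.condition,
        )
    rss, sol = best
    kg0, J, m = np.exp(sol.x)

    # curvature-based covariance in log space (approximate: reported because
    # the optimum is a nonlinear least-squares point estimate, not exact)
    n, p = len(data), 3
    ci: Dict[str, Tuple[float, float]] = {}
    se_log: Dict[str, float] = {}
    weak = True
    if n > p:
        Jm = sol.jac
        try:
            cov = np.linalg.inv(Jm.T @ Jm) * rss / (n - p)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            tcrit = stats.t.ppf(0.975, n - p)
            for name, val, s in zip(("kg0", "J", "m"), (kg0, J, m), se):
                se_log[name] = float(s)
                ci[name] = (float(val * np.exp(-tcrit * s)), float(val * np.exp(tcrit * s)))
            weak = se_log["m"] > WEAK_SE_LOG_M or not np.all(np.isfinite(se))
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        kg0=float(kg0),
        J=float(J),
        m=float(m),
        rss=rss,
        n_obs=n,
        converged=bool(sol.success),
        ci=ci,
        se_log=se_log,
        weak_identifiability=weak,
        condition=data.condition,
    )


def fit_growth_hill_joint(
    datasets: Sequence[GrowthDataset],
    *,
    share: Tuple[str, ...] = ("J", "m"),
    seed: int = 0,
) -> Dict[str, FitResult]:
    """Joint fit across conditions with selected parameters shared.

    By default kg0 varies per condition (media set the unburdened growth
    rate) while J and m are common.  Returns a per-condition FitResult whose
    shared entries are identical.
    """
    if not datasets:
        raise ValueError("no datasets")
    for d in datasets:
        if len(d) < MIN_OBSERVATIONS:
            raise ValueError("every dataset needs at least 4 observations")
    names = ("kg0", "J", "m")
    shared_idx = [i for i, nm in enumerate(names) if nm in share]
    free_idx = [i for i in range(3) if i not in shared_idx]
    k = len(datasets)

    inits = np.array([np.log(_default_init(d)) for d in datasets])
    theta0 = np.concatenate(
        [inits[:, free_idx].ravel(), inits[:, shared_idx].mean(axis=0)]
    )

    def unpack(theta):
        per = theta[: k * len(free_idx)].reshape(k, len(free_idx))
        shared = theta[k * len(free_idx):]
        full = np.empty((k, 3))
        full[:, free_idx] = per
        full[:, shared_idx] = shared
        return full

    def resid(theta):
        full = unpack(theta)
        return np.concatenate(
            [
                _residuals(full[i], d.expression, d.growth_rate, None)
                for i, d in enumerate(datasets)
            ]
        )

    sol = least_squares(resid, theta0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    full = np.exp(unpack(sol.x))
    out = {}
    for i, d in enumerate(datasets):
        kg0, J, m = full[i]
        rss = float(
            np.sum(_residuals(np.log(full[i]), d.expression, d.growth_rate, None) ** 2)
        )
        out[d.condition or str(i)] = FitResult(
            kg0=float(kg0), J=float(J), m=float(m), rss=rss, n_obs=len(d),
            converged=bool(sol.success), condition=d.condition,
        )
    return out


def predict(fit: FitResult, expression) -> np.ndarray:
    """Fitted growth-rate curve at the requested expression levels."""
    if not fit.converged:
        raise ValueError("cannot predict from an unconverged fit")
    return growth_rate(fit.params, expression)


def ultrasensitivity_test(fit: FitResult) -> str:
    """Verdict on m > 1 (ultrasensitive burden) from the fitted interval.

    "supported" iff the lower 95% bound on m exceeds 1; "withheld" when the
    interval is unavailable or the fit is weakly identified.
    """
    if not fit.converged or "m" not in fit.ci or fit.weak_identifiability:
        return "withheld"
    return "supported" if fit.ci["m"][0] > 1.0 else "not_supported"
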