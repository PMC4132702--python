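"""Pre-steady-state kinetic analysis: STO fits, burst fits, titration.

Single-turnover (enzyme >> substrate) progress curves follow

    [P] = A0 * (1 - exp(-k_obs * t)),        k_obs ~ k_chem

and multiple-turnover (burst) curves follow

    [P] = A0 * (1 - exp(-k_obs * t)) + k_ss * t

where the burst amplitude A0 estimates the active-enzyme concentration and
the steady-state slope k_ss yields the product-dissociation (turnover) rate
k_pd = k_ss / A0 in min^-1. Active-site titration regresses fitted burst
amplitudes on total enzyme through the origin; the slope is the active
fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .types import ProgressCurve

__all__ = [
    "STOFitResult",
    "BurstFitResult",
    "TitrationResult",
    "GroupComparison",
    "fit_sto",
    "fit_burst",
    "active_site_titration",
    "fold_change",
    "compare_groups",
]


@dataclass(frozen=True)
class STOFitResult:
    A0_hat: float  # nM
    k_obs_hat: float  # min^-1 (~ k_chem)
    A0_se: float
    k_obs_se: float
    rss: float
    n_points: int
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            assert self.A0_hat >= 0 and self.k_obs_hat >= 0


@dataclass(frozen=True)
class BurstFitResult:
    A0_hat: float  # nM, burst amplitude ~ active enzyme
    k_obs_hat: float  # min^-1, burst constant
    k_ss_hat: float  # nM min^-1, steady-state slope
    A0_se: float
    k_obs_se: float
    k_ss_se: float
    rss: float
    n_points: int
    converged: bool = True
    degenerate: bool = False

    @property
    def k_pd_hat(self) -> float:
        """Product-dissociation (turnover) rate, min^-1 = k_ss / A0."""
        if self.A0_hat == 0:
            return 0.0 if self.k_ss_hat == 0 else math.nan
        return self.k_ss_hat / self.A0_hat

    @property
    def k_pd_se(self) -> float:
        """Delta-method SE of k_pd (correlation between k_ss, A0 ignored)."""
        if self.A0_hat == 0:
            return math.nan
        rel_ss = (self.k_ss_se / self.k_ss_hat) ** 2 if self.k_ss_hat else 0.0
        rel_a0 = (self.A0_se / self.A0_hat) ** 2
        return abs(self.k_pd_hat) * math.sqrt(rel_ss + rel_a0)


@dataclass(frozen=True)
class TitrationResult:
    fits: tuple[BurstFitResult, ...]
    enzyme_concs: tuple[float, ...]
    active_fraction_hat: float
    slope_se: float
    r_squared: float

    @property
    def active_percent(self) -> float:
        return 100.0 * self.active_fraction_hat


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-tailed Student's t-test (equal variances pooled).

    Sign convention: ``t`` is computed as mean(a) - mean(b) over the pooled
    standard error, with group a conventionally the non-hotspot set.
    """

    label_a: str
    label_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    t_statistic: float
    p_value: float
    df: int

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.values_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.values_b))


# ---------------------------------------------------------------------------


def _se_from_jacobian(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    """Local-linearization SEs: sqrt(diag((J'J)^-1 * RSS/(n-p)))."""
    if n <= p:
        return np.full(p, math.nan)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.pinv(jtj) * (rss / (n - p))
    except np.linalg.LinAlgError:
        return np.full(p, math.nan)
    d = np.diag(cov).copy()
    d[d < 0] = math.nan
    return np.sqrt(d)


def _half_max_time(times: np.ndarray, values: np.ndarray, half: float) -> float:
    """Earliest time at which values reach ``half`` (ties -> earliest index)."""
    idx = np.nonzero(values >= half)[0]
    if len(idx) == 0 or times[idx[0]] <= 0:
        return float(times[-1]) / 2 if times[-1] > 0 else 1.0
    return float(times[idx[0]])


def fit_sto(curve: ProgressCurve) -> STOFitResult:
    """Fit the single-turnover exponential to a progress curve.

    Bounded (non-negative) nonlinear least squares, initialized at
    A0 = max(product) and k_obs = ln2 / (time of half-max). An all-zero
    trace returns a degenerate result (A0=0, k_obs undefined).
    """
    if curve.n_points < 4:
        raise ValueError("STO fit requires >= 4 time points")
    if curve.regime != "STO":
        warnings.warn(
            f"fitting STO model to a {curve.regime}-regime curve", stacklevel=2
        )
    t, y = curve.times, curve.product
    if np.all(y == 0):
        return STOFitResult(
            A0_hat=0.0,
            k_obs_hat=math.nan,
            A0_se=0.0,
            k_obs_se=math.nan,
            rss=0.0,
            n_points=curve.n_points,
            degenerate=True,
        )
    a0_init = float(np.max(y))
    k_init = math.log(2.0) / _half_max_time(t, y, a0_init / 2.0)

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] * (1.0 - np.exp(-p[1] * t)) - y

    sol = optimize.least_squares(
        residuals,
        x0=[a0_init, k_init],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    rss = float(np.sum(sol.fun**2))
    se = _se_from_jacobian(sol.jac, rss, curve.n_points, 2)
    return STOFitResult(
        A0_hat=float(sol.x[0]),
        k_obs_hat=float(sol.x[1]),
        A0_se=float(se[0]),
        k_obs_se=float(se[1]),
        rss=rss,
        n_points=curve.n_points,
        converged=bool(sol.success),
    )


def _burst_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Initial (A0, k_obs, k_ss): line through the final third of points gives
    k_ss (slope) and A0 (intercept); k_obs from the early burst half-rise."""
    n = len(t)
    tail = slice(max(n - max(n // 3, 2), 0), n)
    slope, intercept = np.polyfit(t[tail], y[tail], 1)
    k_ss = max(float(slope), 0.0)
    a0 = max(float(intercept), float(np.max(y - k_ss * t)) * 0.5, 1e-12)
    burst = y - k_ss * t
    k_obs = math.log(2.0) / _half_max_time(t, burst, a0 / 2.0)
    return a0, k_obs, k_ss


def fit_burst(curve: ProgressCurve) -> BurstFitResult:
    """Fit the burst (biphasic) model to a multiple-turnover progress curve.

    Returns amplitude, burst constant and linear slope with
    k_pd = k_ss / A0 exposed on the result. The amplitude is bounded above
    by the curve's total enzyme (the burst cannot exceed active enzyme).
    A curve with no resolvable burst is flagged degenerate.
    """
    if curve.n_points < 6:
        raise ValueError("burst fit requires >= 6 time points spanning both phases")
    t, y = curve.times, curve.product
    if np.all(y == 0):
        return BurstFitResult(
            A0_hat=0.0,
            k_obs_hat=math.nan,
            k_ss_hat=0.0,
            A0_se=0.0,
            k_obs_se=math.nan,
            k_ss_se=0.0,
            rss=0.0,
            n_points=curve.n_points,
            degenerate=True,
        )
    a0_init, k_init, kss_init = _burst_init(t, y)
    if np.count_nonzero(t > 3.0 / k_init) < 2:
        warnings.warn(
            "fewer than 2 points beyond 3/k_obs: linear phase poorly constrained",
            stacklevel=2,
        )
    a0_upper = curve.enzyme_total if curve.enzyme_total > 0 else np.inf

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] * (1.0 - np.exp(-p[1] * t)) + p[2] * t - y

    sol = optimize.least_squares(
        residuals,
        x0=[min(a0_init, a0_upper * 0.999), k_init, kss_init],
        bounds=([0.0, 0.0, 0.0], [a0_upper, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        x_scale="jac",
    )
    rss = float(np.sum(sol.fun**2))
    se = _se_from_jacobian(sol.jac, rss, curve.n_points, 3)
    a0_hat = float(sol.x[0])
    scale = float(np.max(y))
    degenerate = a0_hat <= max(1e-9, 1e-6 * scale)
    return BurstFitResult(
        A0_hat=a0_hat,
        k_obs_hat=float(sol.x[1]),
        k_ss_hat=float(sol.x[2]),
        A0_se=float(se[0]),
        k_obs_se=float(se[1]),
        k_ss_se=float(se[2]),
        rss=rss,
        n_points=curve.n_points,
        converged=bool(sol.success),
        degenerate=degenerate,
    )


def active_site_titration(
    series: Sequence[ProgressCurve],
    enzyme_concs: Sequence[float] | None = None,
) -> TitrationResult:
    """Estimate the active-enzyme fraction from a burst titration series.

    Each curve is burst-fitted; the amplitudes are regressed on total enzyme
    through the origin, and the slope is the active fraction. Degenerate
    member fits are excluded with a warning; fewer than two usable fits is
    an error.
    """
    curves = list(series)
    if enzyme_concs is None:
        concs = [c.enzyme_total for c in curves]
    else:
        concs = list(enzyme_concs)
    if len(curves) != len(concs):
        raise ValueError("series and enzyme_concs must have equal length")
    if len(curves) < 2:
        raise ValueError("titration requires >= 2 enzyme concentrations")

    fits, used_concs = [], []
    for curve, conc in zip(curves, concs):
        fit = fit_burst(curve)
        if fit.degenerate or not fit.converged:
            warnings.warn(
                f"excluding degenerate/non-converged fit at {conc} nM", stacklevel=2
            )
            continue
        fits.append(fit)
        used_concs.append(float(conc))
    if len(fits) < 2:
        raise ValueError("fewer than 2 usable burst fits in titration series")

    e = np.array(used_concs)
    a0 = np.array([f.A0_hat for f in fits])
    # Through-origin OLS: slope = sum(E*A0)/sum(E^2).
    slope = float(np.dot(e, a0) / np.dot(e, e))
    resid = a0 - slope * e
    dof = len(e) - 1
    slope_se = (
        math.sqrt(float(np.sum(resid**2)) / dof / float(np.dot(e, e)))
        if dof > 0
        else math.nan
    )
    ss_tot = float(np.sum((a0 - a0.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    if not slope <= 1.05:  # soft tolerance for noise above 100% active
        warnings.warn(
            f"fitted active fraction {slope:.3f} exceeds 1.05", stacklevel=2
        )
    return TitrationResult(
        fits=tuple(fits),
        enzyme_concs=tuple(used_concs),
        active_fraction_hat=slope,
        slope_se=slope_se,
        r_squared=r2,
    )


def fold_change(numerator: float, denominator: float) -> float:
    """Plain ratio of two rate constants (e.g. non-hotspot / hotspot k_pd)."""
    if denominator <= 0:
        raise ZeroDivisionError("fold_change denominator must be > 0")
    return numerator / denominator


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "non-hotspot",
    label_b: str = "hotspot",
) -> GroupComparison:
    """Unpaired two-tailed Student's t-test (pooled equal-variance form).

    Closed-form t and p; the degenerate case of zero variance in both
    groups with equal means returns t=0, p=1 (identical data carry no
    evidence of a difference).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    df = na + nb - 2
    pooled_var = (
        (na - 1) * float(np.var(a, ddof=1)) + (nb - 1) * float(np.var(b, ddof=1))
    ) / df
    diff = float(a.mean() - b.mean())
    if pooled_var == 0.0:
        t_stat = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        se = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        t_stat = diff / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        values_a=tuple(float(x) for x in a),
        values_b=tuple(float(x) for x in b),
        t_statistic=t_stat,
        p_value=p,
        df=df,
    )
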