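"""1:1 Langmuir kinetic analysis of SPR concentration-series sensorgrams.

The association phase at analyte concentration C follows
R(t) = Req (1 - exp(-(ka C + kd) t)) with Req = Rmax ka C / (ka C + kd);
dissociation decays mono-exponentially at kd. The global fit shares
(ka, kd, Rmax) across concentrations; K_D = kd/ka. The per-concentration
pseudo-first-order rate kobs = ka C + kd provides an independent linear
diagnostic (slope ka, intercept kd).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .types import Sensorgram, SensorgramSet

__all__ = ["LangmuirFitResult", "KobsLinearity", "fit_langmuir", "kobs_linearity"]


@dataclass(frozen=True)
class LangmuirFitResult:
    ka_hat: float  # nM^-1 s^-1
    kd_hat: float  # s^-1
    Rmax_hat: float  # RU
    ka_se: float
    kd_se: float
    Rmax_se: float
    rss: float
    n_points: int
    converged: bool = True
    flagged: bool = False  # e.g. single-concentration: ka/Rmax confounded

    @property
    def KD_hat(self) -> float:
        """Equilibrium dissociation constant, nM = kd/ka."""
        if self.ka_hat == 0:
            return math.inf if self.kd_hat > 0 else 0.0
        return self.kd_hat / self.ka_hat


@dataclass(frozen=True)
class KobsLinearity:
    ka_hat: float  # slope of kobs on C
    kd_hat: float  # intercept
    ka_se: float
    kd_se: float
    r_squared: float
    concentrations: tuple[float, ...]
    kobs_values: tuple[float, ...]


def _fit_single_exponential_rise(
    t: np.ndarray, r: np.ndarray
) -> tuple[float, float]:
    """Fit R = Req (1 - exp(-kobs t)); returns (Req, kobs)."""
    req_init = max(float(np.max(r)), 1e-9)
    half = np.nonzero(r >= req_init / 2.0)[0]
    t_half = float(t[half[0]]) if len(half) and t[half[0]] > 0 else max(t[-1] / 2, 1e-6)
    k_init = math.log(2.0) / t_half

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * (1.0 - np.exp(-p[1] * t)) - r

    sol = optimize.least_squares(
        resid,
        x0=[req_init, k_init],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return float(sol.x[0]), float(sol.x[1])


def _dissociation_rate_estimate(s: Sensorgram) -> float:
    """Log-linear estimate of kd from the dissociation tail (init only)."""
    td, rd = s.dissociation
    mask = rd > 1e-12
    if np.count_nonzero(mask) < 2:
        return 0.0
    slope, _ = np.polyfit(td[mask], np.log(rd[mask]), 1)
    return max(-float(slope), 0.0)


def fit_langmuir(sset: SensorgramSet) -> LangmuirFitResult:
    """Global 1:1 Langmuir fit of (ka, kd, Rmax) across a concentration series.

    Requires >= 2 nonzero analyte concentrations for a well-posed global
    fit; with a single concentration ka and Rmax are confounded and the
    result is flagged (kd, and hence K_D = kd/ka, still reported from the
    composite fit).
    """
    active = sset.nonzero()
    if len(active) == 0:
        raise ValueError("sensorgram set has no nonzero analyte concentrations")
    flagged = len(active) < 2
    if flagged:
        warnings.warn(
            "single analyte concentration: ka and Rmax are confounded; "
            "result flagged",
            stacklevel=2,
        )

    # Initialization: kd from the dissociation tail of the highest
    # concentration, then per-concentration kobs for ka, Rmax from Req.
    top = max(active, key=lambda s: s.analyte_conc)
    kd0 = _dissociation_rate_estimate(top)
    ta, ra = top.association
    req0, kobs0 = _fit_single_exponential_rise(ta, ra)
    ka0 = max((kobs0 - kd0) / top.analyte_conc, 1e-12)
    rmax0 = max(req0 * kobs0 / max(ka0 * top.analyte_conc, 1e-12), req0)

    def residuals(p: np.ndarray) -> np.ndarray:
        ka, kd, rmax = p
        out = []
        for s in active:
            kobs = ka * s.analyte_conc + kd
            req = rmax * ka * s.analyte_conc / kobs if kobs > 0 else 0.0
            t_a, r_a = s.association
            model_a = req * (1.0 - np.exp(-kobs * t_a))
            out.append(model_a - r_a)
            t_d, r_d = s.dissociation
            r_end = req * (1.0 - math.exp(-kobs * s.assoc_end)) if kobs > 0 else 0.0
            model_d = r_end * np.exp(-kd * t_d)
            out.append(model_d - r_d)
        return np.concatenate(out)

    sol = optimize.least_squares(
        residuals,
        x0=[ka0, max(kd0, 0.0), rmax0],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    rss = float(np.sum(sol.fun**2))
    n = sol.fun.size
    se = np.full(3, math.nan)
    if n > 3:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (rss / (n - 3))
        d = np.diag(cov).copy()
        d[d < 0] = math.nan
        se = np.sqrt(d)
    return LangmuirFitResult(
        ka_hat=float(sol.x[0]),
        kd_hat=float(sol.x[1]),
        Rmax_hat=float(sol.x[2]),
        ka_se=float(se[0]),
        kd_se=float(se[1]),
        Rmax_se=float(se[2]),
        rss=rss,
        n_points=n,
        converged=bool(sol.success),
        flagged=flagged,
    )


def kobs_linearity(sset: SensorgramSet) -> KobsLinearity:
    """Per-concentration association rates regressed on concentration.

    Fits each association phase to a single exponential, then OLS of kobs
    on C: slope = ka, intercept = kd. Standard diagnostic for the 1:1
    model and an independent check on the global fit.
    """
    active = sset.nonzero()
    if len(active) < 3:
        raise ValueError("kobs linearity requires >= 3 nonzero concentrations")
    concs, kobs = [], []
    for s in sorted(active, key=lambda s: s.analyte_conc):
        t_a, r_a = s.association
        _, k = _fit_single_exponential_rise(t_a, r_a)
        concs.append(s.analyte_conc)
        kobs.append(k)
    res = stats.linregress(concs, kobs)
    r2 = float(res.rvalue) ** 2 if not math.isnan(res.rvalue) else 0.0
    return KobsLinearity(
        ka_hat=float(res.slope),
        kd_hat=float(res.intercept),
        ka_se=float(res.stderr),
        kd_se=float(res.intercept_stderr),
        r_squared=min(r2, 1.0),
        concentrations=tuple(concs),
        kobs_values=tuple(kobs),
    )
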