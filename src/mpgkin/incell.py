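"""In-cell repair quantification from the real-time-PCR assay.

The assay converts unrepaired lesions to nicked, non-amplifiable template,
so the amplifiable fraction measures repair: with amplification base E per
cycle, fraction = E^(Ct_ref - Ct_sample) against a fully-repaired
reference. Repair time courses are summarized by the half-life t1/2 (time
to 50% repair), by default from a single-exponential plateau fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .types import CtTable, MixingStandard, RepairTimeCourse

__all__ = [
    "HalfLifeResult",
    "LinearityResult",
    "SlopeResult",
    "percent_repair_from_ct",
    "estimate_half_life",
    "mixing_linearity",
    "excision_slope",
    "classify_codon",
    "median_by_group",
    "DEFAULT_CODON_CATALOG",
]

# Hotspot membership per the IARC TP53 adenine-mutation pattern.
DEFAULT_CODON_CATALOG: dict[str, bool] = {
    "246": False,
    "247": False,
    "249": True,
    "179": True,
    "255": True,
}


@dataclass(frozen=True)
class HalfLifeResult:
    """Repair half-life for one codon construct in one cell context.

    ``censored`` marks curves that never reach 50% repair; then
    ``t_half_hat`` is a lower bound at the last observed time.
    """

    codon: str
    lesion: str
    cell_context: str
    t_half_hat: float  # hours
    method: str  # exponential_fit | linear_interpolation
    se: float = math.nan
    censored: bool = False
    plateau_hat: float = math.nan
    hotspot: bool = False

    def __post_init__(self) -> None:
        if not (self.t_half_hat > 0):
            raise ValueError("t_half_hat must be > 0")
        if self.method not in ("exponential_fit", "linear_interpolation"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("linearity requires n >= 3")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 out of [0, 1]")


@dataclass(frozen=True)
class SlopeResult:
    label: str
    slope: float  # % product per minute
    se: float
    r_squared: float
    n: int


def percent_repair_from_ct(
    table: CtTable | Iterable[CtTable],
) -> float | list[float]:
    """Convert Ct readings to percent repair via the amplification-blocking
    model: fraction = efficiency^(ct_full_repair - ct_sample), clamped to
    [0, 1]. A sample amplifying earlier than the fully-repaired reference
    beyond half a cycle is clamped to 100% with a warning.
    """
    if isinstance(table, CtTable):
        return _percent_one(table)
    return [_percent_one(t) for t in table]


def _percent_one(t: CtTable) -> float:
    delta = t.ct_full_repair - t.ct_sample
    if delta > 0.5:
        warnings.warn(
            f"sample {t.sample_id!r} amplified {delta:.2f} cycles before the "
            "fully-repaired reference; clamping to 100%",
            stacklevel=3,
        )
    fraction = t.efficiency**delta
    return 100.0 * min(max(fraction, 0.0), 1.0)


def estimate_half_life(
    tc: RepairTimeCourse,
    method: str = "exponential_fit",
) -> HalfLifeResult:
    """Estimate the repair half-life of a percent-repair time course.

    ``exponential_fit`` (default) fits percent = plateau*(1 - exp(-k*t))
    with plateau in (0, 100] and reports t1/2 = ln2/k. ``linear_interpolation``
    takes the first crossing of 50% between adjacent points. A curve whose
    observations never reach 50% is censored with the last time point as a
    lower bound.
    """
    t, y = tc.times, tc.percent_repair
    if method == "exponential_fit" and len(t) < 3:
        raise ValueError("exponential_fit requires >= 3 time points")
    if method == "linear_interpolation" and len(t) < 2:
        raise ValueError("linear_interpolation requires >= 2 time points")

    if float(np.max(y)) < 50.0:
        return HalfLifeResult(
            codon=tc.codon,
            lesion=tc.lesion,
            cell_context=tc.cell_context,
            t_half_hat=float(t[-1]),
            method=method,
            censored=True,
            hotspot=tc.hotspot,
        )

    if method == "exponential_fit":
        t_half, se, plateau = _exponential_half_life(t, y)
    elif method == "linear_interpolation":
        t_half = _interpolated_half_life(t, y)
        se, plateau = math.nan, math.nan
    else:
        raise ValueError(f"unknown method {method!r}")
    return HalfLifeResult(
        codon=tc.codon,
        lesion=tc.lesion,
        cell_context=tc.cell_context,
        t_half_hat=t_half,
        method=method,
        se=se,
        plateau_hat=plateau,
        hotspot=tc.hotspot,
    )


def _exponential_half_life(
    t: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    plateau_init = min(float(np.max(y)), 100.0)
    half_idx = np.nonzero(y >= plateau_init / 2.0)[0]
    t_half_guess = (
        float(t[half_idx[0]]) if len(half_idx) and t[half_idx[0]] > 0 else 1.0
    )
    k_init = math.log(2.0) / t_half_guess

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] * (1.0 - np.exp(-p[1] * t)) - y

    sol = optimize.least_squares(
        residuals,
        x0=[max(plateau_init, 1e-6), k_init],
        bounds=([1e-9, 1e-9], [100.0, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    plateau, k = float(sol.x[0]), float(sol.x[1])
    t_half = math.log(2.0) / k
    # SE via delta method from the local linearization of k.
    n, p = len(t), 2
    rss = float(np.sum(sol.fun**2))
    se = math.nan
    if n > p:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * (rss / (n - p))
        var_k = cov[1, 1]
        if var_k >= 0:
            se = math.log(2.0) / k**2 * math.sqrt(var_k)
    return t_half, se, plateau


def _interpolated_half_life(t: np.ndarray, y: np.ndarray) -> float:
    for i in range(1, len(t)):
        if y[i] >= 50.0:
            if y[i] == y[i - 1]:
                return float(t[i])
            frac = (50.0 - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise RuntimeError("unreachable: max(y) >= 50 was checked upstream")


def mixing_linearity(standards: Sequence[MixingStandard]) -> LinearityResult:
    """OLS of observed on expected percent repair for mixing standards.

    Validates assay linearity; requires >= 3 standards at >= 3 distinct
    expected values.
    """
    if len(standards) < 3:
        raise ValueError("linearity needs >= 3 mixing standards")
    x = np.array([s.expected_percent for s in standards])
    y = np.array([s.observed_percent for s in standards])
    if len(np.unique(x)) < 3:
        raise ValueError("linearity needs >= 3 distinct expected values")
    res = stats.linregress(x, y)
    return LinearityResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue) ** 2, 1.0),
        n=len(standards),
    )


def excision_slope(
    times: Sequence[float],
    percent_product: Sequence[float],
    label: str = "",
) -> SlopeResult:
    """OLS slope (free intercept) of percent product formation over time,
    the extract-activity readout (% product per minute)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(percent_product, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("excision_slope needs >= 2 paired points")
    if len(t) == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        return SlopeResult(label=label, slope=float(slope), se=math.nan,
                           r_squared=1.0, n=2)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue) ** 2 if not math.isnan(res.rvalue) else 0.0
    return SlopeResult(
        label=label,
        slope=float(res.slope),
        se=float(res.stderr),
        r_squared=min(r2, 1.0),
        n=len(t),
    )


def classify_codon(
    codon: str, catalog: dict[str, bool] | None = None
) -> bool:
    """Hotspot membership of a p53 codon from the configured catalog
    (default: hotspots 249/179/255, non-hotspots 246/247)."""
    cat = DEFAULT_CODON_CATALOG if catalog is None else catalog
    if codon not in cat:
        raise KeyError(
            f"codon {codon!r} is not configured; known codons: "
            f"{sorted(cat)}"
        )
    return cat[codon]


def median_by_group(results: Sequence[HalfLifeResult]) -> dict[str, float]:
    """Group medians of fitted half-lives, keyed 'non-hotspot'/'hotspot'.

    Censored results are excluded with a warning; an empty (all-censored)
    group is an error.
    """
    groups: dict[str, list[float]] = {"non-hotspot": [], "hotspot": []}
    n_censored = 0
    for r in results:
        if r.censored:
            n_censored += 1
            continue
        groups["hotspot" if r.hotspot else "non-hotspot"].append(r.t_half_hat)
    if n_censored:
        warnings.warn(
            f"excluded {n_censored} censored half-life result(s) from medians",
            stacklevel=2,
        )
    out = {}
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"group {name!r} has no uncensored half-lives")
        out[name] = float(np.median(vals))
    return out
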