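"""Independent brute-force oracles used to cross-check the fitters.

These deliberately avoid scipy's optimizers: coarse log-grid searches
refined by per-coordinate golden-section bisection. Slow but transparent.
"""

from __future__ import annotations

import math

import numpy as np

GOLDEN = (math.sqrt(5) - 1) / 2


def _rss_sto(t: np.ndarray, y: np.ndarray, a0: float, k: float) -> float:
    return float(np.sum((a0 * (1.0 - np.exp(-k * t)) - y) ** 2))


def _golden_min(f, lo: float, hi: float, iters: int = 80) -> float:
    """Golden-section bisection of a 1-D unimodal function on [lo, hi]."""
    a, b = lo, hi
    c = b - GOLDEN * (b - a)
    d = a + GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2


def sto_grid_oracle(
    t: np.ndarray, y: np.ndarray, refine_rounds: int = 6
) -> tuple[float, float, float]:
    """20x20 log-grid search over (A0, k_obs), refined by coordinate
    bisection. Returns (A0, k_obs, RSS)."""
    ymax = max(float(np.max(y)), 1e-12)
    a_grid = np.geomspace(ymax / 4, ymax * 4, 20)
    k_grid = np.geomspace(1e-3, 1e2, 20)
    best = (a_grid[0], k_grid[0], math.inf)
    for a in a_grid:
        for k in k_grid:
            rss = _rss_sto(t, y, a, k)
            if rss < best[2]:
                best = (a, k, rss)
    a0, k0, _ = best
    for _ in range(refine_rounds):
        a0 = _golden_min(lambda a: _rss_sto(t, y, a, k0), a0 / 2, a0 * 2)
        k0 = _golden_min(lambda k: _rss_sto(t, y, a0, k), k0 / 2, k0 * 2)
    return a0, k0, _rss_sto(t, y, a0, k0)


def _rss_burst(
    t: np.ndarray, y: np.ndarray, a0: float, k: float, kss: float
) -> float:
    return float(np.sum((a0 * (1.0 - np.exp(-k * t)) + kss * t - y) ** 2))


def burst_grid_oracle(
    t: np.ndarray, y: np.ndarray, refine_rounds: int = 8
) -> tuple[float, float, float, float]:
    """Coarse 12^3 log-grid over (A0, k_obs, k_ss) plus coordinate
    bisection. Returns (A0, k_obs, k_ss, RSS)."""
    ymax = max(float(np.max(y)), 1e-12)
    tmax = float(t[-1])
    a_grid = np.geomspace(ymax / 10, ymax * 2, 12)
    k_grid = np.geomspace(1e-2, 50, 12)
    s_grid = np.geomspace(ymax / tmax / 100, ymax / tmax * 2, 12)
    best = (a_grid[0], k_grid[0], s_grid[0], math.inf)
    for a in a_grid:
        for k in k_grid:
            for s in s_grid:
                rss = _rss_burst(t, y, a, k, s)
                if rss < best[3]:
                    best = (a, k, s, rss)
    a0, k0, s0, _ = best
    for _ in range(refine_rounds):
        a0 = _golden_min(lambda a: _rss_burst(t, y, a, k0, s0), a0 / 2, a0 * 2)
        k0 = _golden_min(lambda k: _rss_burst(t, y, a0, k, s0), k0 / 2, k0 * 2)
        s0 = _golden_min(lambda s: _rss_burst(t, y, a0, k0, s), s0 / 2, s0 * 2)
    return a0, k0, s0, _rss_burst(t, y, a0, k0, s0)


def pooled_t_test(a, b) -> tuple[float, float, int]:
    """Textbook pooled-variance unpaired two-tailed t-test, written out
    by hand; p via the regularized incomplete beta function identity."""
    from scipy.special import betainc

    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    # two-sided p for Student's t: I_{df/(df+t^2)}(df/2, 1/2)
    p = float(betainc(df / 2, 0.5, df / (df + t * t)))
    return t, p, df
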