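"""Synthetic-data generators for every assay the pipeline consumes.

All generators are exact evaluations of their stated models when noise is
off, and bit-reproducible for a fixed :class:`~mpgkin.types.NoiseSpec` seed.
Noisy product/percent traces are clamped to their physical bounds.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .types import (
    CtTable,
    MechanismParams,
    MixingStandard,
    NoiseSpec,
    ProgressCurve,
    RepairTimeCourse,
    Sensorgram,
    SensorgramSet,
)

__all__ = [
    "simulate_mechanism_ode",
    "generate_sto_curve",
    "generate_mto_curve",
    "generate_titration_series",
    "generate_repair_timecourse",
    "generate_ct_table",
    "generate_mixing_standards",
    "generate_sensorgram_set",
]

DEFAULT_MIXING_FRACTIONS = (0.0, 10.0, 30.0, 50.0, 70.0, 90.0, 100.0)


def simulate_mechanism_ode(
    params: MechanismParams,
    enzyme_total: float,
    substrate_total: float,
    times: Sequence[float],
    *,
    regime: str | None = None,
    full_output: bool = False,
):
    """Numerically integrate the excision mechanism E+S <=> ES -> EP -> E+P.

    Mass-action kinetics with ``k_on``, ``k_off = K_D*k_on``, ``k_chem`` and
    an irreversible release step at ``k_pd`` (product rebinding off). Only
    ``active_fraction * enzyme_total`` participates. The returned noise-free
    "product" trace is cleaved substrate, [EP] + [P] — what the gel assay
    counts after AP-site cleavage — so the single-turnover rate reflects
    k_chem rather than the release step.

    Raises ``ArithmeticError`` naming the parameter set if the integrator
    fails or returns non-finite values.
    """
    if enzyme_total <= 0 or substrate_total <= 0:
        raise ValueError("enzyme_total and substrate_total must be > 0")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0 or t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be ascending and start at >= 0")

    e_act = params.active_fraction * enzyme_total
    k_on, k_off = params.k_on, params.k_off
    k_chem, k_pd = params.k_chem, params.k_pd

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        s, es, ep, p = y
        e_free = e_act - es - ep
        bind = k_on * e_free * s - k_off * es
        chem = k_chem * es
        rel = k_pd * ep
        return [-bind, bind - chem, chem - rel, rel]

    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1e-9)
    t_eval = t if t[0] == 0 else np.concatenate(([0.0], t))
    sol = solve_ivp(
        rhs,
        t_span,
        y0=[substrate_total, 0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise ArithmeticError(
            f"mechanism integration failed for {params.label!r} "
            f"(K_D={params.K_D}, k_on={params.k_on}, k_chem={params.k_chem}, "
            f"k_pd={params.k_pd}): {sol.message}"
        )
    y = sol.y if t[0] == 0 else sol.y[:, 1:]
    cleaved = y[2] + y[3]  # [EP] + [P]
    cleaved = np.clip(cleaved, 0.0, substrate_total)
    if regime is None:
        regime = "STO" if enzyme_total >= substrate_total else "MTO"
    curve = ProgressCurve(
        label=params.label,
        enzyme_total=enzyme_total,
        substrate_total=substrate_total,
        times=t,
        product=cleaved,
        regime=regime,
    )
    if full_output:
        states = {"S": y[0], "ES": y[1], "EP": y[2], "P": y[3]}
        return curve, states
    return curve


def _finish_curve(
    label: str,
    enzyme_total: float,
    substrate_total: float,
    times: np.ndarray,
    clean: np.ndarray,
    noise: NoiseSpec,
    regime: str,
    replicate: int,
) -> ProgressCurve:
    product = noise.apply(clean)
    product = np.clip(product, 0.0, substrate_total)
    return ProgressCurve(
        label=label,
        enzyme_total=enzyme_total,
        substrate_total=substrate_total,
        times=times,
        product=product,
        replicate=replicate,
        regime=regime,
    )


def generate_sto_curve(
    A0: float,
    k_obs: float,
    times: Sequence[float],
    noise: NoiseSpec = NoiseSpec.off(),
    *,
    label: str = "STO",
    enzyme_total: float | None = None,
    substrate_total: float | None = None,
    replicate: int = 1,
) -> ProgressCurve:
    """Closed-form single-turnover curve [P] = A0 * (1 - exp(-k_obs t))."""
    if A0 < 0 or k_obs < 0:
        raise ValueError("A0 and k_obs must be >= 0")
    t = np.asarray(times, dtype=float)
    clean = A0 * (1.0 - np.exp(-k_obs * t))
    # STO default: enzyme in large excess over the (A0-sized) substrate pool.
    e_tot = enzyme_total if enzyme_total is not None else max(500.0, 10 * A0)
    s_tot = substrate_total if substrate_total is not None else max(A0, 1e-12)
    return _finish_curve(label, e_tot, s_tot, t, clean, noise, "STO", replicate)


def generate_mto_curve(
    A0: float,
    k_obs: float,
    k_ss: float,
    times: Sequence[float],
    noise: NoiseSpec = NoiseSpec.off(),
    *,
    label: str = "MTO",
    enzyme_total: float | None = None,
    substrate_total: float | None = None,
    replicate: int = 1,
) -> ProgressCurve:
    """Closed-form burst curve [P] = A0 * (1 - exp(-k_obs t)) + k_ss * t.

    ``A0`` (nM) is the burst amplitude, approximately the active enzyme
    concentration; ``k_ss`` (nM min^-1) is the linear steady-state slope, so
    the turnover number k_pd = k_ss / A0.
    """
    if A0 < 0 or k_obs < 0 or k_ss < 0:
        raise ValueError("A0, k_obs and k_ss must be >= 0")
    t = np.asarray(times, dtype=float)
    clean = A0 * (1.0 - np.exp(-k_obs * t)) + k_ss * t
    # default: total enzyme at twice the burst amplitude (partially active
    # preparations are the norm); fixtures pass the true total explicitly
    e_tot = enzyme_total if enzyme_total is not None else max(2 * A0, 1e-12)
    s_tot = (
        substrate_total
        if substrate_total is not None
        else max(float(clean.max(initial=0.0)) * 2, 75.0)
    )
    return _finish_curve(label, e_tot, s_tot, t, clean, noise, "MTO", replicate)


def generate_titration_series(
    enzyme_concs: Sequence[float],
    active_fraction: float,
    k_obs: float,
    k_pd: float,
    times: Sequence[float],
    noise: NoiseSpec = NoiseSpec.off(),
    *,
    label: str = "titration",
    substrate_total: float = 75.0,
) -> list[ProgressCurve]:
    """Burst curves at several total-enzyme concentrations.

    Each concentration E yields an MTO curve with burst amplitude
    A0 = active_fraction * E and steady-state slope k_ss = k_pd * A0.
    Noise seeds are decorrelated across the series (seed + index).
    """
    concs = list(enzyme_concs)
    if not concs or any(c <= 0 for c in concs):
        raise ValueError("enzyme_concs must be non-empty and positive")
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    curves = []
    for i, conc in enumerate(concs):
        a0 = active_fraction * conc
        per_curve = noise
        if noise.enabled:
            per_curve = NoiseSpec(noise.cv, noise.floor_sd, noise.seed + i)
        curves.append(
            generate_mto_curve(
                a0,
                k_obs,
                k_pd * a0,
                times,
                per_curve,
                label=f"{label}_{conc:g}nM",
                enzyme_total=conc,
                substrate_total=substrate_total,
            )
        )
    return curves


def generate_repair_timecourse(
    t_half: float,
    times: Sequence[float],
    plateau: float = 100.0,
    noise: NoiseSpec = NoiseSpec.off(),
    *,
    codon: str = "246",
    lesion: str = "eA",
    cell_context: str = "HepG2",
    hotspot: bool = False,
) -> RepairTimeCourse:
    """Single-exponential approach to a repair plateau.

    percent(t) = plateau * (1 - exp(-ln2 * t / t_half)); ``t_half = inf``
    models no detectable repair (identically zero, e.g. Mpg-null cells).
    """
    if not (t_half > 0):  # rejects 0, negatives and NaN; inf allowed
        raise ValueError("t_half must be > 0 (or inf for no repair)")
    if not 0.0 < plateau <= 100.0:
        raise ValueError("plateau must lie in (0, 100]")
    t = np.asarray(times, dtype=float)
    if math.isinf(t_half):
        clean = np.zeros_like(t)
    else:
        clean = plateau * (1.0 - np.exp(-math.log(2.0) * t / t_half))
    pct = np.clip(noise.apply(clean), 0.0, 100.0)
    return RepairTimeCourse(
        codon=codon,
        lesion=lesion,
        cell_context=cell_context,
        times=t,
        percent_repair=pct,
        hotspot=hotspot,
    )


def generate_ct_table(
    true_repair_fraction: float,
    ct_full_repair: float,
    efficiency: float = 2.0,
    noise: NoiseSpec = NoiseSpec.off(),
    *,
    sample_id: str = "sample",
) -> CtTable:
    """Invert the amplification-blocking model to a Ct reading.

    ct_sample = ct_full_repair - log(fraction)/log(efficiency); a fully
    repaired sample amplifies like the reference, an unrepairable one never
    crosses threshold (fraction 0 is rejected as censored).
    """
    if not 0.0 < true_repair_fraction <= 1.0:
        raise ValueError(
            "true_repair_fraction must lie in (0, 1]; 0 gives an undefined Ct "
            "(censored sample)"
        )
    ct = ct_full_repair - math.log(true_repair_fraction) / math.log(efficiency)
    ct = float(noise.apply(np.array([ct]))[0])
    return CtTable(
        sample_id=sample_id,
        ct_sample=ct,
        ct_full_repair=ct_full_repair,
        efficiency=efficiency,
    )


def generate_mixing_standards(
    fractions: Sequence[float] = DEFAULT_MIXING_FRACTIONS,
    noise: NoiseSpec = NoiseSpec.off(),
) -> list[MixingStandard]:
    """Mixing-experiment standards: observed = expected + seeded noise.

    Emulates blends of damaged and undamaged plasmid spanning 0-100%
    repaired-equivalent; observations are clamped to [0, 100].
    """
    expected = np.asarray(list(fractions), dtype=float)
    if np.any(expected < 0) or np.any(expected > 100):
        raise ValueError("fractions must lie within [0, 100]")
    observed = np.clip(noise.apply(expected), 0.0, 100.0)
    return [
        MixingStandard(expected_percent=float(e), observed_percent=float(o))
        for e, o in zip(expected, observed)
    ]


def generate_sensorgram_set(
    ka: float,
    kd: float,
    Rmax: float,
    concs: Sequence[float],
    t_assoc: float = 120.0,
    t_dissoc: float = 180.0,
    noise: NoiseSpec = NoiseSpec.off(),
    *,
    label: str = "SPR",
    dt: float = 1.0,
) -> SensorgramSet:
    """1:1 Langmuir sensorgrams for a concentration series.

    Association: R(t) = Req * (1 - exp(-(ka*C + kd) t)) with
    Req = Rmax * ka * C / (ka*C + kd); dissociation: mono-exponential decay
    from the end-of-injection response at rate kd.
    """
    if ka < 0 or kd < 0 or Rmax < 0:
        raise ValueError("ka, kd and Rmax must be >= 0")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be >= 0")
    sensorgrams = []
    for i, conc in enumerate(concs):
        t_a = np.arange(0.0, t_assoc + dt / 2, dt)
        t_d = np.arange(dt, t_dissoc + dt / 2, dt) + t_assoc
        kobs = ka * conc + kd
        if conc == 0 or ka == 0 or Rmax == 0:
            r_a = np.zeros_like(t_a)
        elif kobs == 0:
            r_a = np.zeros_like(t_a)
        else:
            req = Rmax * ka * conc / kobs
            r_a = req * (1.0 - np.exp(-kobs * t_a))
        r_end = r_a[-1] if len(r_a) else 0.0
        r_d = r_end * np.exp(-kd * (t_d - t_assoc))
        times = np.concatenate([t_a, t_d])
        resp = np.concatenate([r_a, r_d])
        per_curve = noise
        if noise.enabled:
            per_curve = NoiseSpec(noise.cv, noise.floor_sd, noise.seed + i)
        resp = per_curve.apply(resp)
        sensorgrams.append(
            Sensorgram(
                analyte_conc=float(conc),
                times=times,
                response=resp,
                assoc_end=float(t_assoc),
            )
        )
    return SensorgramSet(label=label, sensorgrams=tuple(sensorgrams))
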