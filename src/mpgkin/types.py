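"""Shared domain containers for glycosylase kinetics and in-cell repair assays.

Units are fixed package-wide: concentrations in nM, enzymology time in
minutes, in-cell repair time in hours, SPR time in seconds, qPCR thresholds
in cycles. Containers validate their invariants at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MechanismParams",
    "NoiseSpec",
    "ProgressCurve",
    "RepairTimeCourse",
    "MixingStandard",
    "CtTable",
    "Sensorgram",
    "SensorgramSet",
]


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class MechanismParams:
    """Ground-truth kinetic constants for one substrate/sequence context.

    The minimal excision mechanism is

        E + S <=> ES -> EP -> E + P
              K_D    k_chem   k_pd

    with K_D the equilibrium dissociation constant of enzyme-substrate
    binding (nM), k_chem the glycosidic-bond cleavage rate (min^-1) and
    k_pd the product (AP-site) dissociation rate (min^-1), the turnover
    number. ``k_off`` is implied as ``K_D * k_on``.
    """

    label: str
    K_D: float  # nM
    k_on: float  # nM^-1 min^-1
    k_chem: float  # min^-1
    k_pd: float  # min^-1
    active_fraction: float = 1.0
    hotspot: bool = False

    def __post_init__(self) -> None:
        for name in ("K_D", "k_on", "k_chem", "k_pd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError(
                f"active_fraction must lie in [0, 1], got {self.active_fraction}"
            )

    @property
    def k_off(self) -> float:
        """Dissociation rate of the ES complex, min^-1 (= K_D * k_on)."""
        return self.K_D * self.k_on


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: proportional Gaussian (CV) plus additive floor.

    A noisy reading of true value y is ``y * (1 + cv*z1) + floor_sd*z2`` with
    z1, z2 standard normal. ``seed`` is mandatory whenever cv or floor_sd is
    nonzero; identical (parameters, seed) gives bit-identical output.
    """

    cv: float = 0.0
    floor_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor_sd < 0:
            raise ValueError("cv and floor_sd must be >= 0")
        if (self.cv > 0 or self.floor_sd > 0) and self.seed is None:
            raise ValueError("a seed is required when noise is enabled")

    @property
    def enabled(self) -> bool:
        return self.cv > 0 or self.floor_sd > 0

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(cv=0.0, floor_sd=0.0, seed=None)

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Return a noisy copy of ``values`` (exact copy when noise is off)."""
        values = np.asarray(values, dtype=float)
        if not self.enabled:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        z1 = rng.standard_normal(values.shape)
        z2 = rng.standard_normal(values.shape)
        return values * (1.0 + self.cv * z1) + self.floor_sd * z2


@dataclass(frozen=True)
class ProgressCurve:
    """A timed product-formation trace from a glycosylase excision reaction.

    ``product`` is cleaved substrate in nM (everything converted past the
    chemistry step, i.e. what the gel assay counts after AP-site cleavage).
    ``regime`` is "STO" (enzyme >> substrate, single turnover) or "MTO"
    (substrate >> enzyme, burst/multiple turnover).
    """

    label: str
    enzyme_total: float  # nM
    substrate_total: float  # nM
    times: np.ndarray  # minutes
    product: np.ndarray  # nM
    replicate: int = 1
    regime: str = "MTO"

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        product = _as_float_array(self.product, "product")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "product", product)
        if len(times) != len(product):
            raise ValueError("times and product must have equal length")
        if len(times) and times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.regime not in ("STO", "MTO"):
            raise ValueError(f"regime must be 'STO' or 'MTO', got {self.regime!r}")
        if np.any(product < 0) or np.any(product > self.substrate_total * (1 + 1e-9)):
            raise ValueError("product must lie within [0, substrate_total]")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RepairTimeCourse:
    """Percent repair versus time for one lesion-bearing codon construct."""

    codon: str
    lesion: str  # "eA" or "AP"
    cell_context: str  # e.g. "HepG2", "HUVEC", "MEF_wt", "MEF_ko"
    times: np.ndarray  # hours
    percent_repair: np.ndarray  # [0, 100]
    hotspot: bool = False

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        pct = _as_float_array(self.percent_repair, "percent_repair")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "percent_repair", pct)
        if len(times) != len(pct):
            raise ValueError("times and percent_repair must have equal length")
        if len(times) == 0 or times[0] != 0:
            raise ValueError("times must start at 0 h")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(pct < 0) or np.any(pct > 100):
            raise ValueError("percent_repair must lie in [0, 100]")
        if self.lesion not in ("eA", "AP"):
            raise ValueError(f"lesion must be 'eA' or 'AP', got {self.lesion!r}")


@dataclass(frozen=True)
class MixingStandard:
    """One defined blend of damaged and undamaged plasmid (assay linearity)."""

    expected_percent: float
    observed_percent: float

    def __post_init__(self) -> None:
        for name in ("expected_percent", "observed_percent"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class CtTable:
    """qPCR cycle thresholds for one sample against a fully-repaired reference.

    ``efficiency`` is the per-cycle amplification base in (1, 2]; 2.0 means
    perfect doubling every cycle.
    """

    sample_id: str
    ct_sample: float
    ct_full_repair: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")
        for name in ("ct_sample", "ct_full_repair"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass(frozen=True)
class Sensorgram:
    """One SPR response-vs-time trace at a single analyte concentration."""

    analyte_conc: float  # nM
    times: np.ndarray  # seconds
    response: np.ndarray  # response units
    assoc_end: float  # seconds; boundary between association and dissociation

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        resp = _as_float_array(self.response, "response")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "response", resp)
        if len(times) != len(resp):
            raise ValueError("times and response must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.analyte_conc < 0:
            raise ValueError("analyte_conc must be >= 0")

    @property
    def association(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.times <= self.assoc_end
        return self.times[mask], self.response[mask]

    @property
    def dissociation(self) -> tuple[np.ndarray, np.ndarray]:
        """Dissociation phase with time measured from the injection stop."""
        mask = self.times > self.assoc_end
        return self.times[mask] - self.assoc_end, self.response[mask]


@dataclass(frozen=True)
class SensorgramSet:
    """A concentration series of sensorgrams sharing one immobilized ligand."""

    label: str
    sensorgrams: tuple[Sensorgram, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensorgrams", tuple(self.sensorgrams))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.analyte_conc for s in self.sensorgrams])

    def nonzero(self) -> tuple[Sensorgram, ...]:
        return tuple(s for s in self.sensorgrams if s.analyte_conc > 0)
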