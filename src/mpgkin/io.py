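"""Long-format CSV readers/writers for curves, repair courses, sensorgrams.

Progress curves and repair time courses share one layout
(label, replicate, regime, time, value); sensorgrams add analyte_conc and
phase. Units travel in a sidecar JSON next to each CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import MixingStandard, ProgressCurve, RepairTimeCourse, Sensorgram, SensorgramSet

__all__ = [
    "write_progress_curves",
    "read_progress_curves",
    "write_repair_timecourses",
    "read_repair_timecourses",
    "write_sensorgram_set",
    "read_sensorgram_set",
    "write_mixing_standards",
    "read_mixing_standards",
]


def _write_sidecar(path: Path, units: dict) -> None:
    path.with_suffix(path.suffix + ".units.json").write_text(
        json.dumps(units, indent=2) + "\n"
    )


def write_progress_curves(curves: Sequence[ProgressCurve], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for c in curves:
        for t, p in zip(c.times, c.product):
            rows.append(
                {
                    "label": c.label,
                    "replicate": c.replicate,
                    "regime": c.regime,
                    "enzyme_total": c.enzyme_total,
                    "substrate_total": c.substrate_total,
                    "time": t,
                    "value": p,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_sidecar(
        path,
        {"time": "min", "value": "nM", "enzyme_total": "nM", "substrate_total": "nM"},
    )


def read_progress_curves(path: str | Path) -> list[ProgressCurve]:
    df = pd.read_csv(path)
    curves = []
    for (label, rep), grp in df.groupby(["label", "replicate"], sort=False):
        grp = grp.sort_values("time")
        curves.append(
            ProgressCurve(
                label=str(label),
                enzyme_total=float(grp["enzyme_total"].iloc[0]),
                substrate_total=float(grp["substrate_total"].iloc[0]),
                times=grp["time"].to_numpy(float),
                product=grp["value"].to_numpy(float),
                replicate=int(rep),
                regime=str(grp["regime"].iloc[0]),
            )
        )
    return curves


def write_repair_timecourses(
    courses: Sequence[RepairTimeCourse], path: str | Path
) -> None:
    path = Path(path)
    rows = []
    for tc in courses:
        for t, p in zip(tc.times, tc.percent_repair):
            rows.append(
                {
                    "codon": tc.codon,
                    "lesion": tc.lesion,
                    "cell_context": tc.cell_context,
                    "hotspot": tc.hotspot,
                    "time": t,
                    "value": p,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_sidecar(path, {"time": "h", "value": "% repair"})


def read_repair_timecourses(path: str | Path) -> list[RepairTimeCourse]:
    df = pd.read_csv(path)
    out = []
    keys = ["codon", "lesion", "cell_context"]
    for (codon, lesion, ctx), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time")
        out.append(
            RepairTimeCourse(
                codon=str(codon),
                lesion=str(lesion),
                cell_context=str(ctx),
                times=grp["time"].to_numpy(float),
                percent_repair=grp["value"].to_numpy(float),
                hotspot=bool(grp["hotspot"].iloc[0]),
            )
        )
    return out


def write_sensorgram_set(sset: SensorgramSet, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for s in sset.sensorgrams:
        phases = np.where(s.times <= s.assoc_end, "association", "dissociation")
        for t, r, ph in zip(s.times, s.response, phases):
            rows.append(
                {
                    "label": sset.label,
                    "analyte_conc": s.analyte_conc,
                    "phase": ph,
                    "assoc_end": s.assoc_end,
                    "time": t,
                    "response": r,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_sidecar(path, {"time": "s", "response": "RU", "analyte_conc": "nM"})


def read_sensorgram_set(path: str | Path) -> SensorgramSet:
    df = pd.read_csv(path)
    label = str(df["label"].iloc[0]) if len(df) else "SPR"
    sensorgrams = []
    for conc, grp in df.groupby("analyte_conc", sort=True):
        grp = grp.sort_values("time")
        sensorgrams.append(
            Sensorgram(
                analyte_conc=float(conc),
                times=grp["time"].to_numpy(float),
                response=grp["response"].to_numpy(float),
                assoc_end=float(grp["assoc_end"].iloc[0]),
            )
        )
    return SensorgramSet(label=label, sensorgrams=tuple(sensorgrams))


def write_mixing_standards(
    standards: Sequence[MixingStandard], path: str | Path
) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "expected_percent": [s.expected_percent for s in standards],
            "observed_percent": [s.observed_percent for s in standards],
        }
    ).to_csv(path, index=False)
    _write_sidecar(path, {"expected_percent": "%", "observed_percent": "%"})


def read_mixing_standards(path: str | Path) -> list[MixingStandard]:
    df = pd.read_csv(path)
    return [
        MixingStandard(float(r.expected_percent), float(r.observed_percent))
        for r in df.itertuples()
    ]
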