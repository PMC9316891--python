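"""Diurnal sensitivity of model output to forcing quantization.

For each 15-min time-of-day step t the sensitivity of a quantized scenario is
the RMSE across simulation days between the full-forcing and quantized-forcing
model output,

    SM_t = sqrt( sum_d (F(d,t) - Q(d,t))**2 / D ),        t = 1..96,

in the flux's own units.  It measures how far quantizing the forcing moves the
model, not an error against observations.  Windowed variants restrict d to
20-day blocks of the growing season; time-of-day aggregation averages SM_t
over 3-h clock blocks; and the comparison table joins these aggregates with
the forcing complexity Cm of every scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forcing import FluxSeries, ForcingSet, day_of_year_labels, diurnal_index
from .information import complexity_cm, full_resolution_histograms
from .quantize import Quantizer
from .scenarios import ExperimentResult

__all__ = [
    "SensitivityCurve",
    "smt",
    "windowed_smt",
    "aggregate_tod",
    "complexity_sensitivity_table",
    "DEFAULT_WINDOWS",
    "DEFAULT_BLOCKS",
]

#: five 20-day growing-season windows (DOY, inclusive ends) tiling 150-250
DEFAULT_WINDOWS = ((150, 170), (171, 190), (191, 210), (211, 230), (231, 250))

#: 3-h clock blocks used for time-of-day aggregation, half-open [start, end)
DEFAULT_BLOCKS = (("03:00", "06:00"), ("09:00", "12:00"),
                  ("12:00", "15:00"), ("18:00", "21:00"))


@dataclass(frozen=True)
class SensitivityCurve:
    """SM_t by time of day for one flux and one scenario."""

    flux: str
    scenario_id: str
    values: np.ndarray        # length steps_per_day; NaN where no usable days
    days_used: np.ndarray     # effective D per time step
    window: str = "full"
    steps_per_day: int = 96

    def __post_init__(self):
        self.values.setflags(write=False)
        self.days_used.setflags(write=False)


def smt(
    full: FluxSeries,
    quantized: FluxSeries,
    scenario_id: str = "",
    window: str = "full",
    day_mask: np.ndarray | None = None,
) -> SensitivityCurve:
    """Diurnal RMSE between full-model and quantized-model output.

    Days with a missing value at a given t (in either series) are dropped
    pairwise at that t and the effective day count recorded.  ``day_mask``
    optionally restricts which days enter (used by the windowed variant).
    """
    if not full.timestamps.equals(quantized.timestamps):
        raise ValueError("full and quantized series are not on the same grid")
    f = diurnal_index(full)
    q = diurnal_index(quantized)
    if day_mask is not None:
        day_mask = np.asarray(day_mask, bool)
        if day_mask.sum() == 0:
            raise ValueError("empty day selection")
        f, q = f[day_mask], q[day_mask]
    diff = f - q
    usable = ~np.isnan(diff)
    days_used = usable.sum(axis=0)
    with np.errstate(invalid="ignore"):
        msq = np.nansum(diff * diff, axis=0) / np.where(days_used > 0, days_used, 1)
    values = np.sqrt(msq)
    values[days_used == 0] = np.nan
    return SensitivityCurve(full.name, scenario_id, values, days_used,
                            window, f.shape[1])


def windowed_smt(
    full: FluxSeries,
    quantized: FluxSeries,
    windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
    scenario_id: str = "",
) -> dict[str, SensitivityCurve]:
    """SM_t restricted to days within each DOY window (inclusive ends)."""
    doy = day_of_year_labels(full)
    out: dict[str, SensitivityCurve] = {}
    for lo, hi in windows:
        mask = (doy >= lo) & (doy <= hi)
        if not mask.any():
            raise ValueError(f"window DOY {lo}-{hi} contains no simulated days")
        label = f"DOY {lo}-{hi}"
        out[label] = smt(full, quantized, scenario_id, label, day_mask=mask)
    return out


def _clock_to_step(clock: str | float, steps_per_day: int) -> int:
    """Map a clock time to a time-of-day step index; must land on the grid."""
    if isinstance(clock, str):
        parts = clock.split(":")
        hours = int(parts[0]) + (int(parts[1]) / 60.0 if len(parts) > 1 else 0.0)
    else:
        hours = float(clock)
    step = hours * steps_per_day / 24.0
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"clock time {clock!r} is off the {steps_per_day}-step grid")
    return int(round(step))


def aggregate_tod(
    curve: SensitivityCurve,
    block: tuple[str | float, str | float],
) -> float:
    """Mean SM_t over a clock block, half-open [start, end)."""
    start = _clock_to_step(block[0], curve.steps_per_day)
    end = _clock_to_step(block[1], curve.steps_per_day)
    if end <= start:
        end += curve.steps_per_day  # block wrapping midnight
    idx = np.arange(start, end) % curve.steps_per_day
    return float(np.nanmean(curve.values[idx]))


def complexity_sensitivity_table(
    result: ExperimentResult,
    base: ForcingSet,
    blocks: Sequence[tuple[str, str]] = DEFAULT_BLOCKS,
    fluxes: Sequence[str] = ("Fc", "LE", "SH"),
    variables: Sequence[str] = ("Ta", "U", "VPD"),
    full_discs=None,
) -> pd.DataFrame:
    """One row per scenario joining forcing complexity Cm with aggregated SM_t.

    The full model anchors the table with (Cm, SM_t) = (1, 0).  Scenarios
    quantizing variables outside ``variables`` (the Rg case) carry Cm = NaN,
    since forcing complexity is defined on the meteorological triple.
    Incomplete (failed) scenarios are flagged rather than dropped.
    """
    if full_discs is None:
        full_discs = full_resolution_histograms(base, variables)

    def block_label(flux: str, block: tuple[str, str]) -> str:
        return f"SMt_{flux}_{block[0]}-{block[1]}"

    rows: list[dict] = []
    anchor: dict = {"scenario": "full", "case": "full", "cm": 1.0, "complete": True}
    for v in variables:
        anchor[f"N_{v}"] = "full"
    for flux in fluxes:
        for block in blocks:
            anchor[block_label(flux, block)] = 0.0
    rows.append(anchor)

    for run in result.runs:
        sc = run.scenario
        row: dict = {"scenario": sc.scenario_id, "case": f"case{sc.case}",
                     "complete": not run.failed}
        lv = sc.level_map
        for v in variables:
            row[f"N_{v}"] = lv.get(v, "full")
        q_map: dict[str, Quantizer] = {
            v: result.quantizers[(v, n)] for v, n in sc.levels if v in variables
        }
        if set(lv) <= set(variables):
            row["cm"] = complexity_cm(base, q_map, variables, full_discs).cm
        else:
            row["cm"] = np.nan
        if run.failed or run.fluxes is None:
            for flux in fluxes:
                for block in blocks:
                    row[block_label(flux, block)] = np.nan
        else:
            for flux in fluxes:
                curve = smt(result.full[flux], run.fluxes[flux], sc.scenario_id)
                for block in blocks:
                    row[block_label(flux, block)] = aggregate_tod(curve, block)
        rows.append(row)
    return pd.DataFrame(rows)
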