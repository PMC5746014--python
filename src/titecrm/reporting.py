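"""Operating-characteristics aggregation and drug-supply forecasting.

An operating-characteristics table has one row per scenario x design
cell: the percentage of replicates selecting each schedule as the MTD
(plus a stopped-for-safety category — together a partition of the
replicates, summing to 100%), the mean number of patients treated on each
schedule, the mean sample size, the mean trial duration, and the
safety-stop percentage.  Percentages are reported to one decimal in the
CSV rendering; full precision is kept in memory and in JSON.

The drug-supply forecaster implements the two requirement forecasts a
supplier can be given before a dose-finding trial starts: a worst case in
which the maximum number of patients all need the most drug-hungry
schedule, and an expected case weighted by the simulated mean allocation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import TrialResult
from .design import StopReason, DesignConfig
from .model import ScheduleGrid


@dataclass
class OCCell:
    """Aggregated operating characteristics of one scenario x design cell."""

    selection_pct: np.ndarray       # per schedule, % of replicates
    stopped_toxic_pct: float        # % of replicates ending with no safe schedule
    mean_alloc: np.ndarray          # mean patients per schedule
    mean_n: float
    mean_duration: float
    safety_stop_pct: float
    n_rep: int
    scenario: str = ""
    design: str = ""

    def __post_init__(self) -> None:
        total = float(np.sum(self.selection_pct)) + self.stopped_toxic_pct
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"selection percentages must sum to 100, got {total}")
        if np.any(self.selection_pct < 0) or not (0.0 <= self.stopped_toxic_pct <= 100.0):
            raise ValidationError("percentages must lie in [0,100]")
        if self.mean_n < 0 or self.mean_duration < 0 or np.any(self.mean_alloc < 0):
            raise ValidationError("means must be non-negative")


def aggregate_results(results: Sequence[TrialResult]) -> OCCell:
    """Empirical operating characteristics of a list of trial replicates."""
    if not results:
        raise ValidationError("cannot aggregate an empty replicate list")
    n_sched = len(results[0].alloc)
    if any(len(r.alloc) != n_sched for r in results):
        raise ValidationError("replicates have inconsistent schedule counts")
    n_rep = len(results)
    sel = np.zeros(n_sched)
    none_sel = 0
    for r in results:
        if r.selected is None:
            none_sel += 1
        else:
            sel[r.selected - 1] += 1
    alloc = np.array([r.alloc for r in results], dtype=float)
    return OCCell(
        selection_pct=100.0 * sel / n_rep,
        stopped_toxic_pct=100.0 * none_sel / n_rep,
        mean_alloc=alloc.mean(axis=0),
        mean_n=float(np.mean([r.n for r in results])),
        mean_duration=float(np.mean([r.duration for r in results])),
        safety_stop_pct=100.0 * sum(r.stop_reason is StopReason.SAFETY for r in results) / n_rep,
        n_rep=n_rep,
    )


@dataclass
class OCTable:
    """Cross-cell operating-characteristics table with run metadata."""

    cells: List[OCCell]
    n_rep: int
    master_seed: int
    n_schedules: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {"scenario": c.scenario, "design": c.design}
            for s in range(self.n_schedules):
                row[f"sel_pct_s{s + 1}"] = c.selection_pct[s]
            row["stopped_toxic_pct"] = c.stopped_toxic_pct
            for s in range(self.n_schedules):
                row[f"mean_alloc_s{s + 1}"] = c.mean_alloc[s]
            row.update(
                mean_n=c.mean_n,
                mean_duration_weeks=c.mean_duration,
                safety_stop_pct=c.safety_stop_pct,
                n_rep=c.n_rep,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "n_rep": self.n_rep,
            "master_seed": self.master_seed,
            "n_schedules": self.n_schedules,
            "cells": [
                {
                    "scenario": c.scenario,
                    "design": c.design,
                    "selection_pct": list(map(float, c.selection_pct)),
                    "stopped_toxic_pct": c.stopped_toxic_pct,
                    "mean_alloc": list(map(float, c.mean_alloc)),
                    "mean_n": c.mean_n,
                    "mean_duration_weeks": c.mean_duration,
                    "safety_stop_pct": c.safety_stop_pct,
                    "n_rep": c.n_rep,
                }
                for c in self.cells
            ],
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    @classmethod
    def from_csv(cls, path, n_rep: Optional[int] = None, master_seed: int = 0) -> "OCTable":
        df = pd.read_csv(path)
        sel_cols = sorted([c for c in df.columns if c.startswith("sel_pct_s")],
                          key=lambda c: int(c.split("sel_pct_s")[1]))
        alloc_cols = sorted([c for c in df.columns if c.startswith("mean_alloc_s")],
                            key=lambda c: int(c.split("mean_alloc_s")[1]))
        cells = [
            OCCell(
                selection_pct=row[sel_cols].to_numpy(dtype=float),
                stopped_toxic_pct=float(row["stopped_toxic_pct"]),
                mean_alloc=row[alloc_cols].to_numpy(dtype=float),
                mean_n=float(row["mean_n"]),
                mean_duration=float(row["mean_duration_weeks"]),
                safety_stop_pct=float(row["safety_stop_pct"]),
                n_rep=int(row["n_rep"]),
                scenario=str(row["scenario"]),
                design=str(row["design"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(cells=cells, n_rep=n_rep or (cells[0].n_rep if cells else 0),
                   master_seed=master_seed, n_schedules=len(sel_cols))

    @classmethod
    def from_json(cls, path) -> "OCTable":
        with open(path) as fh:
            d = json.load(fh)
        cells = [
            OCCell(
                selection_pct=np.asarray(c["selection_pct"], dtype=float),
                stopped_toxic_pct=c["stopped_toxic_pct"],
                mean_alloc=np.asarray(c["mean_alloc"], dtype=float),
                mean_n=c["mean_n"],
                mean_duration=c["mean_duration_weeks"],
                safety_stop_pct=c["safety_stop_pct"],
                n_rep=c["n_rep"],
                scenario=c["scenario"],
                design=c["design"],
            )
            for c in d["cells"]
        ]
        return cls(cells=cells, n_rep=d["n_rep"], master_seed=d["master_seed"],
                   n_schedules=d["n_schedules"])


@dataclass(frozen=True)
class DrugForecast:
    """Drug-requirement forecast in administration units."""

    worst_case_units: float
    expected_units: Optional[float]
    admin_per_patient: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.worst_case_units < 0:
            raise ValidationError("worst_case_units must be non-negative")
        if self.expected_units is not None:
            if self.expected_units < 0:
                raise ValidationError("expected_units must be non-negative")
            if self.expected_units > self.worst_case_units + 1e-9:
                raise ValidationError("expected units cannot exceed the worst case")


def forecast_drug_supply(
    design: DesignConfig,
    grid: ScheduleGrid,
    admin_per_patient: Sequence[float],
    oc_cell: Optional[OCCell] = None,
) -> DrugForecast:
    """The two supplier forecasts: all-maximal worst case and simulation-based expectation.

    Worst case: the maximum sample size of patients all treated on the
    schedule needing the most administrations.  Expected case (requires an
    operating-characteristics cell): mean patients per schedule dotted
    with the per-schedule administrations.
    """
    admin = np.asarray(list(admin_per_patient), dtype=float)
    if admin.size != grid.n_schedules:
        raise ValidationError("admin_per_patient length must match the schedule grid")
    if np.any(admin < 0):
        raise ValidationError("admin_per_patient must be non-negative")
    worst = float(design.max_n * admin.max())
    expected = None
    if oc_cell is not None:
        if oc_cell.mean_alloc.size != admin.size:
            raise ValidationError("OC cell and admin_per_patient dimensions differ")
        expected = float(np.dot(oc_cell.mean_alloc, admin))
    return DrugForecast(
        worst_case_units=worst,
        expected_units=expected,
        admin_per_patient=tuple(map(float, admin)),
    )
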