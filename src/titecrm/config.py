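"""Configuration files and seeded fixture generation.

A configuration file (YAML or JSON) has up to three sections::

    grid:
      skeleton: [0.05, 0.10, 0.15, 0.25, 0.35, 0.45]
      labels:   [S1, S2, S3, S4, S5, S6]        # optional
    design:
      ttl: 0.25
      max_n: 25
      window: 12
      ...                                        # any DesignConfig field
    scenarios:
      - name: skeleton-true
        true_p: [0.05, 0.10, 0.15, 0.25, 0.35, 0.45]
        dlt_time_dist: uniform
        accrual_rate: 0.25
        window: 12

Unknown keys raise a named validation error; omitted design fields take
their documented defaults; save-then-load is the identity.

The fixture generator emits self-consistent stage presets: the dose-
finding stages of a three-stage schedule-finding trial (a palliative-
radiotherapy stage with six nested schedules, a chemotherapy-only stage
with four, and a radical stage with six schedules and a 6-week delay
between enrolment and schedule assignment), each with a scenario set —
skeleton-true, shifted up, shifted down, and a steepened curve — built
by monotone transforms of the skeleton.  The numbers are explicit
package choices, fully configurable, not reproductions of any real trial.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .design import DesignConfig
from .errors import ValidationError
from .model import PatientRecord, ScheduleGrid
from .simulate import Scenario

_DESIGN_FIELDS = {f.name for f in dataclasses.fields(DesignConfig)}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(Scenario)}
_GRID_FIELDS = {"skeleton", "labels"}

FIXTURE_KINDS = ("stage-A1", "stage-A2", "stage-B", "custom")


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValidationError(f"unknown keys in '{section}' section: {sorted(unknown)}")


def load_config(path) -> Tuple[DesignConfig, ScheduleGrid, List[Scenario]]:
    """Load and validate a design + grid + scenarios configuration file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError("configuration root must be a mapping")
    _check_keys("root", data, {"grid", "design", "scenarios"})
    if "grid" not in data or "design" not in data:
        raise ValidationError("configuration needs 'grid' and 'design' sections")

    gsec = dict(data["grid"])
    _check_keys("grid", gsec, _GRID_FIELDS)
    grid = ScheduleGrid(
        skeleton=tuple(gsec["skeleton"]), labels=tuple(gsec.get("labels", ()))
    )

    dsec = dict(data["design"])
    _check_keys("design", dsec, _DESIGN_FIELDS)
    design = DesignConfig(**dsec)

    scenarios: List[Scenario] = []
    for i, ssec in enumerate(data.get("scenarios", []) or []):
        ssec = dict(ssec)
        _check_keys(f"scenarios[{i}]", ssec, _SCENARIO_FIELDS)
        ssec["true_p"] = tuple(ssec["true_p"])
        scenarios.append(Scenario(**ssec))
        if len(scenarios[-1].true_p) != grid.n_schedules:
            raise ValidationError(
                f"scenario '{scenarios[-1].name}' has {len(scenarios[-1].true_p)} "
                f"schedules, grid has {grid.n_schedules}"
            )
    return design, grid, scenarios


def save_config(
    design: DesignConfig,
    grid: ScheduleGrid,
    scenarios: Sequence[Scenario],
    path,
) -> None:
    """Serialise a configuration; round-trips through :func:`load_config`."""
    data = {
        "grid": {"skeleton": list(grid.skeleton), "labels": list(grid.labels)},
        "design": dataclasses.asdict(design),
        "scenarios": [
            {**dataclasses.asdict(s), "true_p": list(s.true_p)} for s in scenarios
        ],
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# --------------------------------------------------------------------------
# scenario transforms: monotone maps of the skeleton used to build
# realistic and extreme ground-truth curves around a design's TTL

def _shift_up(p: np.ndarray) -> np.ndarray:
    return 1.0 - (1.0 - p) ** 1.8


def _shift_down(p: np.ndarray) -> np.ndarray:
    return p ** 1.8


def _steepen(p: np.ndarray, ttl: float, power: float = 2.5) -> np.ndarray:
    lo = p <= ttl
    out = np.empty_like(p)
    out[lo] = ttl * (p[lo] / ttl) ** power
    out[~lo] = 1.0 - (1.0 - ttl) * ((1.0 - p[~lo]) / (1.0 - ttl)) ** power
    return out


def scenario_set(grid: ScheduleGrid, design: DesignConfig,
                 accrual_rate: float = 0.25, dlt_time_dist: str = "uniform") -> List[Scenario]:
    """Skeleton-true, shifted-up, shifted-down and steep scenarios for a stage."""
    skel = np.asarray(grid.skeleton)
    common = dict(accrual_rate=accrual_rate, window=design.window,
                  dlt_time_dist=dlt_time_dist)
    return [
        Scenario(true_p=tuple(skel), name="skeleton-true", **common),
        Scenario(true_p=tuple(_shift_up(skel)), name="shifted-up", **common),
        Scenario(true_p=tuple(_shift_down(skel)), name="shifted-down", **common),
        Scenario(true_p=tuple(_steepen(skel, design.ttl)), name="steep", **common),
    ]


_STAGE_PRESETS = {
    # 6 nested schedules, no assignment delay
    "stage-A1": dict(
        skeleton=(0.05, 0.10, 0.15, 0.25, 0.35, 0.45),
        ttl=0.25, max_n=25, window=12.0, assignment_delay=0.0,
    ),
    # 4 schedules (two doses at two frequencies)
    "stage-A2": dict(
        skeleton=(0.10, 0.18, 0.25, 0.35),
        ttl=0.25, max_n=20, window=12.0, assignment_delay=0.0,
    ),
    # 6 schedules; every patient on the common backbone for the first 6 weeks
    "stage-B": dict(
        skeleton=(0.05, 0.10, 0.15, 0.25, 0.35, 0.45),
        ttl=0.25, max_n=25, window=12.0, assignment_delay=6.0,
    ),
}


def generate_fixtures(
    kind: str = "stage-A1",
    seed: int = 0,
    out_dir: Optional[Path] = None,
    skeleton: Optional[Sequence[float]] = None,
    ttl: Optional[float] = None,
) -> Tuple[DesignConfig, ScheduleGrid, List[Scenario], List[PatientRecord]]:
    """Build a stage preset: design, grid, scenario set and an example patient stream.

    The example patient records are one partially-run virtual trial under
    the skeleton-true scenario, deterministic given ``seed``.  When
    ``out_dir`` is given, ``design.yaml`` and ``patients.csv`` are written
    there (byte-identical for identical seeds).
    """
    if kind not in FIXTURE_KINDS:
        raise ValidationError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if kind == "custom":
        if skeleton is None or ttl is None:
            raise ValidationError("custom fixtures need an explicit skeleton and ttl")
        preset = dict(skeleton=tuple(skeleton), ttl=float(ttl), max_n=25,
                      window=12.0, assignment_delay=0.0)
    else:
        preset = dict(_STAGE_PRESETS[kind])

    grid = ScheduleGrid(skeleton=tuple(preset.pop("skeleton")))
    design = DesignConfig(**preset)
    scenarios = scenario_set(grid, design)

    # Example patient stream: simulate the skeleton-true scenario, then
    # truncate follow-up to mid-trial so some patients are partial.
    result_records = _example_patients(scenarios[0], design, grid, seed)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_config(design, grid, scenarios, out_dir / "design.yaml")
        from .io import write_patients

        write_patients(result_records, out_dir / "patients.csv")
    return design, grid, scenarios, result_records


def _example_patients(
    scenario: Scenario, design: DesignConfig, grid: ScheduleGrid, seed: int
) -> List[PatientRecord]:
    """A small, deterministic mid-trial patient stream for demos and the CLI.

    Run-in patients at the lowest schedule fully observed in sequence, then
    gradually escalating assignments; follow-up is truncated at a mid-trial
    analysis time so recent enrollees are only partially observed.
    """
    rng = np.random.default_rng(seed)
    n = min(design.max_n, 8)
    entries: List[tuple] = []
    t = 0.0
    schedule = 1
    for i in range(n):
        if 0 < i <= design.run_in_n:
            t += design.window if i < design.run_in_n else design.window + design.slot_gap
        elif i > 0:
            t += design.slot_gap + float(rng.exponential(1.0 / scenario.accrual_rate))
        if i >= design.run_in_n:
            schedule = min(schedule + int(rng.random() < 0.6), grid.n_schedules)
        dlt = int(rng.random() < scenario.true_p[schedule - 1])
        t_dlt = float(rng.uniform(0, design.window)) if dlt else None
        entries.append((t, schedule, dlt, t_dlt))
    now = entries[-1][0] + design.window / 2.0
    records: List[PatientRecord] = []
    for i, (start, sched, dlt, t_dlt) in enumerate(entries):
        fu = min(max(now - start, 0.0), design.window)
        observed = int(bool(dlt) and t_dlt is not None and t_dlt <= fu)
        records.append(
            PatientRecord(
                id=f"P{i + 1:03d}", enrol_time=round(start, 2), schedule=sched,
                window=design.window, follow_up=round(fu, 2), dlt=observed,
                t_dlt=round(min(t_dlt, fu), 2) if observed else None,
            )
        )
    return records
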