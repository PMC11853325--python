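"""Revised NIOSH lifting equation (RNLE).

Computes the recommended weight limit

    RWL = LC * HM * VM * DM * AM * FM * CM

and the lifting index LI = load / RWL for a single lifting task, then
classifies the task as acceptable (LI <= 1), increased risk
(1 < LI <= 3) or high risk (LI > 3).  The binary label used downstream
by the risk classifiers is 0 for acceptable tasks and 1 otherwise.

VM is evaluated at both the origin and the destination of the lift; the
smaller of the two RWLs governs the task.  All multipliers follow the
NIOSH Applications Manual; the frequency multiplier is a table lookup
shipped as versioned package data (``data/fm_table.yaml``).

Units: ``unit_system="US"`` expects pounds and inches,
``unit_system="metric"`` kilograms and centimetres.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

import yaml

IN_PER_CM = 1.0 / 2.54
LB_PER_KG = 1.0 / 0.45359237

UNIT_SYSTEMS = ("US", "metric")
DURATIONS = ("le1h", "le2h", "le8h")
COUPLINGS = ("good", "fair", "poor")
RISK_CATEGORIES = ("acceptable", "increased", "high")

#: Unit-system dependent constants of the equation:
#: (LC, H optimum, H max, V optimum, VM slope, V max, DM numerator,
#:  D short-travel floor, D max, knuckle-height band edge for FM/CM)
_CONST = {
    "US": dict(LC=51.0, H_OPT=10.0, H_MAX=25.0, V_OPT=30.0, VM_SLOPE=0.0075,
               V_MAX=70.0, DM_NUM=1.8, D_MIN=10.0, D_MAX=70.0, V_KNUCKLE=30.0),
    "metric": dict(LC=23.0, H_OPT=25.0, H_MAX=63.0, V_OPT=75.0, VM_SLOPE=0.003,
                   V_MAX=175.0, DM_NUM=4.5, D_MIN=25.0, D_MAX=175.0, V_KNUCKLE=75.0),
}

#: Demographic load constants (kg) by (sex, older-than-45 band).
_DEMOGRAPHIC_LC_KG = {("M", False): 25.0, ("M", True): 20.0,
                      ("F", False): 20.0, ("F", True): 15.0}


class RnleError(ValueError):
    """Invalid task geometry or lookup input."""


@dataclass(frozen=True)
class Demographics:
    sex: str  # "M" | "F"
    age: float  # years

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise RnleError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.age > 0:
            raise RnleError("age must be positive")


@dataclass
class LiftingTask:
    """One single-task lift description in a fixed unit system."""

    load_weight: float
    horizontal_distance: float
    vertical_origin: float
    vertical_destination: float
    frequency: float
    travel_distance: Optional[float] = None
    asymmetry_angle: float = 0.0
    duration_category: str = "le1h"
    coupling: str = "good"
    unit_system: str = "US"
    demographics: Optional[Demographics] = None

    def __post_init__(self):
        if self.unit_system not in UNIT_SYSTEMS:
            raise RnleError(f"unknown unit system {self.unit_system!r}")
        if self.duration_category not in DURATIONS:
            raise RnleError(f"unknown duration category {self.duration_category!r}")
        if self.coupling not in COUPLINGS:
            raise RnleError(f"unknown coupling {self.coupling!r}")
        if not self.load_weight > 0:
            raise RnleError("load_weight must be positive")
        if not self.frequency > 0:
            raise RnleError("frequency must be positive")
        for name in ("horizontal_distance", "vertical_origin", "vertical_destination"):
            if getattr(self, name) < 0:
                raise RnleError(f"{name} must be non-negative")
        if self.asymmetry_angle < 0:
            raise RnleError("asymmetry_angle must be non-negative")
        if self.travel_distance is None:
            self.travel_distance = abs(self.vertical_destination - self.vertical_origin)
        elif self.travel_distance < 0:
            raise RnleError("travel_distance must be non-negative")


@dataclass
class RnleAssessment:
    """Multipliers, recommended weight limits and lifting index of a task."""

    LC: float
    HM: float
    VM_origin: float
    VM_destination: float
    DM: float
    AM: float
    FM: float
    CM: float
    RWL_origin: float
    RWL_destination: float
    LI: float
    risk_category: str
    binary_label: int

    @property
    def GM(self) -> float:
        """Alias: some sources call the coupling factor the 'grab multiplier'."""
        return self.CM

    def rounded(self, ndigits: int = 2) -> "RnleAssessment":
        """Presentation copy with RWL and LI rounded (multipliers untouched)."""
        out = RnleAssessment(**asdict(self))
        out.RWL_origin = round(out.RWL_origin, ndigits)
        out.RWL_destination = round(out.RWL_destination, ndigits)
        if math.isfinite(out.LI):
            out.LI = round(out.LI, ndigits)
        return out


def load_constant(mode: str = "standard",
                  demographics: Optional[Demographics] = None,
                  unit_system: str = "US") -> float:
    """Baseline liftable weight under ideal conditions.

    ``standard`` is the Applications Manual constant (51 lb / 23 kg).
    ``demographic`` uses sex/age bands (men: 25 kg under 45, 20 kg from 45;
    women: 20 kg under 45, 15 kg from 45), converted to lb for US tasks.
    """
    if unit_system not in UNIT_SYSTEMS:
        raise RnleError(f"unknown unit system {unit_system!r}")
    if mode == "standard":
        return _CONST[unit_system]["LC"]
    if mode == "demographic":
        if demographics is None:
            raise RnleError("demographic load constant requires demographics")
        lc_kg = _DEMOGRAPHIC_LC_KG[(demographics.sex, demographics.age >= 45)]
        return lc_kg if unit_system == "metric" else lc_kg * LB_PER_KG
    raise RnleError(f"unknown load-constant mode {mode!r}")


def horizontal_multiplier(h: float, unit_system: str = "US") -> float:
    """HM = 10/H (in) or 25/H (cm); 1 below the optimum, 0 beyond the maximum."""
    c = _CONST[unit_system]
    if h < 0:
        raise RnleError("horizontal distance must be non-negative")
    if h <= c["H_OPT"]:
        return 1.0
    if h > c["H_MAX"]:
        return 0.0
    return c["H_OPT"] / h


def vertical_multiplier(v: float, unit_system: str = "US") -> float:
    """VM = 1 - slope*|V - optimum|, clamped to [0, 1]; 0 above the ceiling."""
    c = _CONST[unit_system]
    if v < 0:
        raise RnleError("vertical location must be non-negative")
    if v > c["V_MAX"]:
        return 0.0
    return min(1.0, max(0.0, 1.0 - c["VM_SLOPE"] * abs(v - c["V_OPT"])))


def distance_multiplier(d: float, unit_system: str = "US") -> float:
    """DM = 0.82 + 1.8/D (in) or 0.82 + 4.5/D (cm); 1 for short travel."""
    c = _CONST[unit_system]
    if d < 0:
        raise RnleError("travel distance must be non-negative")
    if d <= c["D_MIN"]:
        return 1.0
    if d > c["D_MAX"]:
        return 0.0
    return min(1.0, 0.82 + c["DM_NUM"] / d)


def asymmetric_multiplier(a: float) -> float:
    """AM = 1 - 0.0032*A (degrees), clamped to [0, 1]; 0 beyond 135 degrees."""
    if a < 0:
        raise RnleError("asymmetry angle must be non-negative")
    if a > 135.0:
        return 0.0
    return min(1.0, max(0.0, 1.0 - 0.0032 * a))


def _fm_table() -> dict:
    with resources.files("liftrisk.data").joinpath("fm_table.yaml").open() as fh:
        return yaml.safe_load(fh)


_FM_CACHE: Optional[dict] = None


def frequency_multiplier(f: float, duration_category: str = "le1h",
                         v: float = 0.0, unit_system: str = "US") -> float:
    """FM table lookup by lifting rate, work duration and vertical band.

    Rates between tabulated rows are rounded *up* to the next row (the
    conservative direction: more frequent lifting, smaller multiplier);
    rates below 0.2/min use the 0.2 row, above 15/min FM = 0.
    """
    global _FM_CACHE
    if not f > 0:
        raise RnleError("frequency must be positive")
    if duration_category not in DURATIONS:
        raise RnleError(f"unknown duration category {duration_category!r}")
    if _FM_CACHE is None:
        _FM_CACHE = _fm_table()
    table = _FM_CACHE
    freqs = table["frequencies"]
    if f > freqs[-1]:
        return 0.0
    band = "v_low" if v < _CONST[unit_system]["V_KNUCKLE"] else "v_high"
    column = table[duration_category][band]
    for rate, fm in zip(freqs, column):
        if f <= rate + 1e-12:
            return float(fm)
    return 0.0  # pragma: no cover - unreachable


def coupling_multiplier(coupling: str, v: float = 0.0,
                        unit_system: str = "US") -> float:
    """CM: good 1.00; fair 0.95 below knuckle height else 1.00; poor 0.90."""
    if coupling not in COUPLINGS:
        raise RnleError(f"unknown coupling {coupling!r}")
    if coupling == "good":
        return 1.00
    if coupling == "poor":
        return 0.90
    return 0.95 if v < _CONST[unit_system]["V_KNUCKLE"] else 1.00


#: accepted alias — the coupling factor is also called the grab multiplier
grab_multiplier = coupling_multiplier


def assess_task(task: LiftingTask, lc_mode: str = "standard") -> RnleAssessment:
    """Evaluate the full equation at origin and destination and classify.

    The destination and origin share every multiplier except VM; the
    smaller RWL governs LI.  A zero multiplier gives RWL = 0 and an
    infinite LI (reported as high risk).
    """
    us = task.unit_system
    lc = load_constant(lc_mode, task.demographics, us)
    hm = horizontal_multiplier(task.horizontal_distance, us)
    vm_o = vertical_multiplier(task.vertical_origin, us)
    vm_d = vertical_multiplier(task.vertical_destination, us)
    dm = distance_multiplier(task.travel_distance, us)
    am = asymmetric_multiplier(task.asymmetry_angle)
    fm = frequency_multiplier(task.frequency, task.duration_category,
                              task.vertical_origin, us)
    cm = coupling_multiplier(task.coupling, task.vertical_origin, us)
    shared = lc * hm * dm * am * fm * cm
    rwl_o = shared * vm_o
    rwl_d = shared * vm_d
    rwl = min(rwl_o, rwl_d)
    li = task.load_weight / rwl if rwl > 0 else math.inf
    if li <= 1.0:
        category = "acceptable"
    elif li <= 3.0:
        category = "increased"
    else:
        category = "high"
    return RnleAssessment(
        LC=lc, HM=hm, VM_origin=vm_o, VM_destination=vm_d, DM=dm, AM=am,
        FM=fm, CM=cm, RWL_origin=rwl_o, RWL_destination=rwl_d, LI=li,
        risk_category=category, binary_label=0 if category == "acceptable" else 1,
    )


_TASK_FIELDS = ("load_weight", "horizontal_distance", "vertical_origin",
                "vertical_destination", "travel_distance", "asymmetry_angle",
                "frequency", "duration_category", "coupling", "unit_system")


def assess_tasks_csv(in_path, out_path, lc_mode: str = "standard") -> int:
    """Batch mode: read one task per row, write multipliers/RWL/LI per row.

    Returns the number of tasks assessed.  Numeric columns are parsed as
    floats; ``travel_distance`` may be empty (defaults to |Vd - Vo|).
    """
    n = 0
    with open(in_path, newline="") as fin, open(out_path, "w", newline="") as fout:
        reader = csv.DictReader(fin)
        writer = None
        for row in reader:
            kwargs = {}
            for name in _TASK_FIELDS:
                if name not in row or row[name] in ("", None):
                    continue
                if name in ("duration_category", "coupling", "unit_system"):
                    kwargs[name] = row[name]
                else:
                    kwargs[name] = float(row[name])
            assessment = assess_task(LiftingTask(**kwargs), lc_mode=lc_mode)
            record = {**{k: kwargs.get(k, "") for k in _TASK_FIELDS},
                      **asdict(assessment.rounded())}
            if writer is None:
                writer = csv.DictWriter(fout, fieldnames=list(record))
                writer.writeheader()
            writer.writerow(record)
            n += 1
    return n
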