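"""Virtual screw placement: configuration grid, axis geometry, injury rule.

Every simulated screw is one cell of a Cartesian grid per ankle: a placement
level (cm above the tibiotalar joint), a trajectory rule (20 degrees,
30 degrees, or the ankle's individual syndesmosis angle) and a shaft diameter
(3.5 / 4.0 / 4.5 mm).  The axis is the infinite in-plane line through the
lateral fibular entry point, rotated counter-clockwise from the epicondylar
reference axis (posterior-to-anterior opening).  The injury-potential rule is
purely geometric: the perpendicular distance from the peroneal artery point
to the axis, flagged when it is at or below the screw's outer shaft radius
(1.75 mm for a 3.5 mm screw, 2.0 mm for 4.0, 2.25 mm for 4.5; the boundary
counts as injury potential).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anatomy import AnkleAnatomy, _point_line_distance, _rotate

#: Trajectory rules in canonical order.
ANGLE_RULES: tuple[str, ...] = ("fixed_20", "fixed_30", "individual")

#: Shaft diameters (mm) considered by default; the flag threshold is D/2.
DEFAULT_DIAMETERS_MM: tuple[float, ...] = (3.5, 4.0, 4.5)

_FIXED_ANGLES = {"fixed_20": 20.0, "fixed_30": 30.0}


class GeometryError(ValueError):
    """Invalid screw-axis geometry (angle out of range, degenerate direction)."""


@dataclass(frozen=True)
class ScrewSpec:
    """One (level, trajectory rule, diameter) placement option."""

    level_cm: float
    angle_rule: str
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.angle_rule not in ANGLE_RULES:
            raise GeometryError(
                f"unknown angle rule {self.angle_rule!r}; expected one of {ANGLE_RULES}"
            )
        if self.diameter_mm <= 0:
            raise GeometryError(f"diameter must be positive, got {self.diameter_mm}")


@dataclass(frozen=True)
class ScrewAxis:
    """A resolved in-plane screw axis: anchored line with unit direction."""

    level_cm: float
    angle_deg: float
    anchor_point: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class SimulationRecord:
    """Outcome of one simulated screw against one ankle."""

    ankle_id: str
    level_cm: float
    angle_rule: str
    resolved_angle_deg: float
    diameter_mm: float
    distance_mm: float
    injury_flag: bool


def make_screw_grid(
    levels: Sequence[float],
    angle_rules: Sequence[str] = ANGLE_RULES,
    diameters: Sequence[float] = DEFAULT_DIAMETERS_MM,
) -> list[ScrewSpec]:
    """Cartesian product of placement options in deterministic order.

    Order: level ascending, then rule (20, 30, individual), then diameter
    ascending.  Duplicate entries in any argument are rejected.
    """
    for name, seq in (("levels", levels), ("angle_rules", angle_rules), ("diameters", diameters)):
        if len(seq) == 0:
            raise GeometryError(f"{name} must be non-empty")
        if len(set(seq)) != len(seq):
            raise GeometryError(f"duplicate entries in {name}: {list(seq)}")
    unknown = set(angle_rules) - set(ANGLE_RULES)
    if unknown:
        raise GeometryError(f"unknown angle rules {sorted(unknown)}")
    rule_order = {r: i for i, r in enumerate(ANGLE_RULES)}
    return [
        ScrewSpec(level_cm=lv, angle_rule=rule, diameter_mm=d)
        for lv, rule, d in product(
            sorted(levels),
            sorted(angle_rules, key=rule_order.__getitem__),
            sorted(diameters),
        )
    ]


def resolve_angle(spec: ScrewSpec, anatomy: AnkleAnatomy) -> float:
    """Trajectory angle (degrees from the epicondylar axis) for one spec.

    Fixed rules return their nominal angle; the individual rule reads the
    angle sampled into the anatomy at that level (perpendicular to the
    incisura when visible, parallel to the interosseous ligament above 3 cm
    -- both reduce to the stored direction).
    """
    if spec.angle_rule in _FIXED_ANGLES:
        anatomy.level(spec.level_cm)  # raises KeyError if the level is absent
        return _FIXED_ANGLES[spec.angle_rule]
    return anatomy.level(spec.level_cm).individual_angle_deg


def axis_line(anatomy: AnkleAnatomy, level_cm: float, angle_deg: float) -> ScrewAxis:
    """Resolve the screw axis at a level: the entry-point line rotated
    ``angle_deg`` counter-clockwise from the epicondylar axis."""
    if not 0.0 < angle_deg < 90.0:
        raise GeometryError(f"screw angle must lie strictly in (0, 90) degrees, got {angle_deg}")
    rec = anatomy.level(level_cm)
    direction = _rotate(rec.epicondylar_axis_direction, angle_deg)
    return ScrewAxis(
        level_cm=level_cm,
        angle_deg=angle_deg,
        anchor_point=rec.fibula_entry_point.copy(),
        direction=direction / np.linalg.norm(direction),
    )


def closest_distance(axis: ScrewAxis, artery_position: np.ndarray) -> float:
    """Perpendicular distance (mm) from the artery point to the infinite axis."""
    norm = np.linalg.norm(axis.direction)
    if norm < 1e-12:
        raise GeometryError("screw axis direction has zero norm")
    return _point_line_distance(np.asarray(artery_position, dtype=float),
                                axis.anchor_point, axis.direction / norm)


def classify_injury(
    distance_mm: float,
    diameter_mm: float,
    allowed_diameters: Sequence[float] = DEFAULT_DIAMETERS_MM,
) -> bool:
    """Injury potential iff the artery lies within the outer shaft radius.

    ``distance <= diameter / 2``, boundary inclusive.  The diameter whitelist
    is configurable for non-standard hardware.
    """
    if distance_mm < 0:
        raise GeometryError(f"distance must be >= 0, got {distance_mm}")
    if diameter_mm not in allowed_diameters:
        raise GeometryError(
            f"diameter {diameter_mm} mm not in allowed set {tuple(allowed_diameters)}"
        )
    return distance_mm <= diameter_mm / 2.0


def run_cohort(
    cohort: Iterable[AnkleAnatomy],
    grid: Sequence[ScrewSpec],
    allowed_diameters: Sequence[float] = DEFAULT_DIAMETERS_MM,
) -> list[SimulationRecord]:
    """Simulate every grid spec against every ankle.

    A pure function of its inputs: |records| = |cohort| x |grid|, in cohort
    order then grid order.  Distances are resolved once per distinct
    (ankle, level, rule) axis and shared across diameters, so the threshold
    nesting flag(3.5) => flag(4.0) => flag(4.5) is structural.
    """
    records: list[SimulationRecord] = []
    for ankle in cohort:
        axis_cache: dict[tuple[float, str], tuple[float, float]] = {}
        for spec in grid:
            key = (spec.level_cm, spec.angle_rule)
            if key not in axis_cache:
                angle = resolve_angle(spec, ankle)
                axis = axis_line(ankle, spec.level_cm, angle)
                dist = closest_distance(axis, ankle.level(spec.level_cm).artery_position)
                axis_cache[key] = (angle, dist)
            angle, dist = axis_cache[key]
            records.append(
                SimulationRecord(
                    ankle_id=ankle.ankle_id,
                    level_cm=spec.level_cm,
                    angle_rule=spec.angle_rule,
                    resolved_angle_deg=angle,
                    diameter_mm=spec.diameter_mm,
                    distance_mm=dist,
                    injury_flag=classify_injury(dist, spec.diameter_mm, allowed_diameters),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Records CSV round-trip
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "ankle_id",
    "level_cm",
    "angle_rule",
    "resolved_angle_deg",
    "diameter_mm",
    "distance_mm",
    "injury_flag",
]


def records_to_frame(records: Iterable[SimulationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ankle_id": r.ankle_id,
                "level_cm": r.level_cm,
                "angle_rule": r.angle_rule,
                "resolved_angle_deg": r.resolved_angle_deg,
                "diameter_mm": r.diameter_mm,
                "distance_mm": r.distance_mm,
                "injury_flag": r.injury_flag,
            }
            for r in records
        ],
        columns=_RECORD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[SimulationRecord]:
    missing = set(_RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"records table missing columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        rec = SimulationRecord(
            ankle_id=str(row["ankle_id"]),
            level_cm=float(row["level_cm"]),
            angle_rule=str(row["angle_rule"]),
            resolved_angle_deg=float(row["resolved_angle_deg"]),
            diameter_mm=float(row["diameter_mm"]),
            distance_mm=float(row["distance_mm"]),
            injury_flag=bool(row["injury_flag"]),
        )
        if rec.injury_flag != (rec.distance_mm <= rec.diameter_mm / 2.0):
            raise ValueError(
                f"inconsistent injury flag for ankle {rec.ankle_id}, "
                f"level {rec.level_cm} cm, diameter {rec.diameter_mm} mm"
            )
        out.append(rec)
    return out


def write_records_csv(records: Iterable[SimulationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[SimulationRecord]:
    # round_trip parsing: CSVs must reproduce stored floats bit-for-bit
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))
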