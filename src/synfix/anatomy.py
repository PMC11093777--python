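"""Synthetic ankle anatomy for syndesmosis-screw simulation.

The simulation consumes, per ankle and per axial level above the tibiotalar
joint, only a handful of sufficient statistics of the real cross-sectional
anatomy: the in-plane position of the peroneal artery (centerline point), the
lateral fibular entry point of the screw corridor, the femoral-epicondylar
reference direction (the 0 degree axis), and the "individual" screw direction
(perpendicular to the incisura fibularis when visible, parallel to the
interosseous ligament above 3 cm).  This module generates cohorts of such
anatomies with a configurable statistical structure:

* the individual screw angle at level ``h`` is Normal(mean_h, sd_h) truncated
  to (0, 90) degrees, with the means increasing proximally;
* the artery sits at a signed perpendicular offset from a 20-degree reference
  corridor through the entry point, the offset Normal(mean_h, sd_h) in mm,
  truncated so the artery keeps a minimum clearance from every screw corridor
  (20 degrees, 30 degrees, and the ankle's own individual axis) at that level.

Distal levels of the packaged default configuration carry a hard clearance
larger than the largest screw radius, so no screw there can flag an injury;
proximal mean offsets are calibrated so flag rates rise with level.

All geometry is 2-D within the axial slice; coordinates are millimetres,
levels are centimetres above the joint line, angles are degrees.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Reference angle (degrees from the epicondylar axis) of the corridor along
#: which the artery offset is defined.  The 20-degree trajectory is the
#: calibration arm.
REFERENCE_CORRIDOR_DEG = 20.0

#: Levels at or below this height (cm) have a visible incisura fibularis; the
#: individual angle is read perpendicular to it.  Above, it is read parallel
#: to the interosseous ligament.
INCISURA_VISIBLE_MAX_CM = 3.0

#: Default simulated levels: every 0.5 cm from 0.5 to 5 cm above the joint.
DEFAULT_LEVELS_CM: tuple[float, ...] = tuple(round(0.5 * k, 1) for k in range(1, 11))

#: Individual-angle mean and SD (degrees) per level, distal to proximal.
DEFAULT_ANGLE_PARAMS: tuple[tuple[float, float], ...] = (
    (29.420, 6.61),  # 0.5 cm
    (31.120, 6.72),  # 1.0 cm
    (32.990, 6.84),  # 1.5 cm
    (34.480, 6.37),  # 2.0 cm
    (35.910, 6.32),  # 2.5 cm
    (36.930, 6.42),  # 3.0 cm
    (38.450, 6.67),  # 3.5 cm
    (39.490, 7.00),  # 4.0 cm
    (40.790, 7.07),  # 4.5 cm
    (41.970, 7.25),  # 5.0 cm
)

_MAX_REJECT_TRIES = 100_000


class ConfigError(ValueError):
    """A cohort configuration violates its invariants."""


class CalibrationError(RuntimeError):
    """A target flag rate cannot be reached within the offset bounds."""


def _unit_from_deg(angle_deg: float) -> np.ndarray:
    rad = math.radians(angle_deg)
    return np.array([math.cos(rad), math.sin(rad)])


def _rotate(vec: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a 2-vector counter-clockwise by ``angle_deg``."""
    rad = math.radians(angle_deg)
    c, s = math.cos(rad), math.sin(rad)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _point_line_distance(point: np.ndarray, anchor: np.ndarray, direction: np.ndarray) -> float:
    v = point - anchor
    return abs(direction[0] * v[1] - direction[1] * v[0])


@dataclass(frozen=True)
class LevelParams:
    """Distribution parameters for one axial level.

    ``artery_mean_offset_mm`` is the mean signed perpendicular offset of the
    artery from the 20-degree reference corridor (positive toward the side the
    corridor fan sweeps across as the trajectory angle grows).
    """

    level_cm: float
    angle_mean_deg: float
    angle_sd_deg: float
    artery_mean_offset_mm: float
    artery_sd_mm: float
    min_clearance_mm: float


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    Invariants are enforced by :meth:`validate` (called on construction):
    levels strictly increasing and positive, individual-angle means strictly
    increasing with level, positive SDs, non-negative clearances.
    """

    n_ankles: int
    seed: int
    levels: tuple[LevelParams, ...]
    artery_along_mm: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_ankles < 0:
            raise ConfigError(f"n_ankles must be >= 0, got {self.n_ankles}")
        if not self.levels:
            raise ConfigError("at least one level is required")
        heights = [lp.level_cm for lp in self.levels]
        if any(h <= 0 for h in heights):
            raise ConfigError(f"levels must be > 0 cm, got {heights}")
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise ConfigError(f"levels must be strictly increasing, got {heights}")
        means = [lp.angle_mean_deg for lp in self.levels]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ConfigError(
                "individual-angle means must be strictly increasing with level, "
                f"got {means}"
            )
        for lp in self.levels:
            if lp.angle_sd_deg <= 0 or lp.artery_sd_mm <= 0:
                raise ConfigError(f"standard deviations must be > 0 at level {lp.level_cm}")
            if lp.min_clearance_mm < 0:
                raise ConfigError(f"min_clearance_mm must be >= 0 at level {lp.level_cm}")
            if not 0 < lp.angle_mean_deg < 90:
                raise ConfigError(f"angle mean out of (0, 90) at level {lp.level_cm}")

    @property
    def level_heights(self) -> tuple[float, ...]:
        return tuple(lp.level_cm for lp in self.levels)

    def level_params(self, level_cm: float) -> LevelParams:
        for lp in self.levels:
            if lp.level_cm == level_cm:
                return lp
        raise KeyError(f"level {level_cm} cm not in configuration")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_ankles": self.n_ankles,
            "seed": self.seed,
            "artery_along_mm": self.artery_along_mm,
            "levels": [
                {
                    "level_cm": lp.level_cm,
                    "angle_mean_deg": lp.angle_mean_deg,
                    "angle_sd_deg": lp.angle_sd_deg,
                    "artery_mean_offset_mm": lp.artery_mean_offset_mm,
                    "artery_sd_mm": lp.artery_sd_mm,
                    "min_clearance_mm": lp.min_clearance_mm,
                }
                for lp in self.levels
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        try:
            levels = tuple(
                LevelParams(
                    level_cm=float(row["level_cm"]),
                    angle_mean_deg=float(row["angle_mean_deg"]),
                    angle_sd_deg=float(row["angle_sd_deg"]),
                    artery_mean_offset_mm=float(row["artery_mean_offset_mm"]),
                    artery_sd_mm=float(row["artery_sd_mm"]),
                    min_clearance_mm=float(row["min_clearance_mm"]),
                )
                for row in data["levels"]
            )
            return cls(
                n_ankles=int(data["n_ankles"]),
                seed=int(data["seed"]),
                artery_along_mm=float(data.get("artery_along_mm", 4.0)),
                levels=levels,
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed cohort configuration: {exc}") from exc

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a configuration from JSON (or YAML, which is a superset)."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"configuration file {path} does not hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass(frozen=True)
class LevelRecord:
    """Resolved geometry of one ankle at one axial level (mm / degrees)."""

    level_cm: float
    epicondylar_axis_direction: np.ndarray
    fibula_entry_point: np.ndarray
    artery_position: np.ndarray
    individual_angle_direction: np.ndarray
    individual_angle_deg: float
    incisura_visible: bool


@dataclass
class AnkleAnatomy:
    ankle_id: str
    records: dict[float, LevelRecord]

    def level(self, level_cm: float) -> LevelRecord:
        try:
            return self.records[level_cm]
        except KeyError:
            raise KeyError(f"level {level_cm} cm not present in ankle {self.ankle_id}") from None

    @property
    def level_heights(self) -> tuple[float, ...]:
        return tuple(self.records)


@dataclass
class TruncationStats:
    """Rejection bookkeeping for the truncated samplers."""

    angle_draws: int = 0
    angle_rejected: int = 0
    artery_draws: int = 0
    artery_rejected: int = 0

    @property
    def angle_reject_fraction(self) -> float:
        return self.angle_rejected / self.angle_draws if self.angle_draws else 0.0

    @property
    def artery_reject_fraction(self) -> float:
        return self.artery_rejected / self.artery_draws if self.artery_draws else 0.0


class Cohort(Sequence):
    """An ordered collection of :class:`AnkleAnatomy` with generation stats."""

    def __init__(self, anatomies: Sequence[AnkleAnatomy], stats: TruncationStats | None = None):
        self._anatomies = list(anatomies)
        self.truncation_stats = stats or TruncationStats()

    def __len__(self) -> int:
        return len(self._anatomies)

    def __getitem__(self, idx):
        return self._anatomies[idx]

    def __iter__(self) -> Iterator[AnkleAnatomy]:
        return iter(self._anatomies)


def _sample_truncated_angle(
    rng: np.random.Generator, mean: float, sd: float, stats: TruncationStats
) -> float:
    for _ in range(_MAX_REJECT_TRIES):
        stats.angle_draws += 1
        x = rng.normal(mean, sd)
        if 0.0 < x < 90.0:
            return x
        stats.angle_rejected += 1
    raise RuntimeError("angle sampler failed to produce a draw in (0, 90) degrees")


def _corridor_directions(epi_axis: np.ndarray, individual_angle_deg: float) -> list[np.ndarray]:
    return [
        _rotate(epi_axis, 20.0),
        _rotate(epi_axis, 30.0),
        _rotate(epi_axis, individual_angle_deg),
    ]


def _sample_artery(
    rng: np.random.Generator,
    lp: LevelParams,
    entry: np.ndarray,
    epi_axis: np.ndarray,
    individual_angle_deg: float,
    along_mm: float,
    stats: TruncationStats,
) -> np.ndarray:
    """Draw an artery position respecting the corridor-fan clearance."""
    ref_dir = _rotate(epi_axis, REFERENCE_CORRIDOR_DEG)
    ref_normal = np.array([-ref_dir[1], ref_dir[0]])
    corridors = _corridor_directions(epi_axis, individual_angle_deg)
    for _ in range(_MAX_REJECT_TRIES):
        stats.artery_draws += 1
        offset = rng.normal(lp.artery_mean_offset_mm, lp.artery_sd_mm)
        pos = entry + along_mm * ref_dir + offset * ref_normal
        if all(
            _point_line_distance(pos, entry, d) >= lp.min_clearance_mm for d in corridors
        ):
            return pos
        stats.artery_rejected += 1
    raise RuntimeError(
        f"artery sampler at level {lp.level_cm} cm cannot satisfy "
        f"min_clearance {lp.min_clearance_mm} mm; check offset parameters"
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``config.n_ankles`` synthetic ankles, one record per level.

    Deterministic given ``config.seed``: each ankle draws from an independent
    substream spawned from the root seed, so any prefix of the cohort is
    reproducible regardless of cohort size downstream.
    """
    config.validate()
    stats = TruncationStats()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_ankles)
    anatomies = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        records: dict[float, LevelRecord] = {}
        for lp in config.levels:
            epi_axis = np.array([1.0, 0.0])
            entry = np.array([0.0, 0.0])
            angle = _sample_truncated_angle(rng, lp.angle_mean_deg, lp.angle_sd_deg, stats)
            artery = _sample_artery(
                rng, lp, entry, epi_axis, angle, config.artery_along_mm, stats
            )
            records[lp.level_cm] = LevelRecord(
                level_cm=lp.level_cm,
                epicondylar_axis_direction=epi_axis,
                fibula_entry_point=entry,
                artery_position=artery,
                individual_angle_direction=_rotate(epi_axis, angle),
                individual_angle_deg=angle,
                incisura_visible=lp.level_cm <= INCISURA_VISIBLE_MAX_CM,
            )
        anatomies.append(AnkleAnatomy(ankle_id=f"A{i:04d}", records=records))
    if stats.artery_draws:
        logger.info(
            "generated %d ankles: angle rejection %.4f, artery rejection %.4f",
            len(anatomies),
            stats.angle_reject_fraction,
            stats.artery_reject_fraction,
        )
    return Cohort(anatomies, stats)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def simulated_flag_rate(
    lp: LevelParams,
    *,
    angle_deg: float = REFERENCE_CORRIDOR_DEG,
    diameter_mm: float = 3.5,
    along_mm: float = 4.0,
    n: int = 5000,
    seed: int = 0,
) -> float:
    """Monte-Carlo flag rate at one level for a single (angle, diameter) arm.

    Mirrors the generator's conditional law: draws rejected by the clearance
    fan are discarded, the rate is taken over accepted draws.  Vectorised for
    calibration use.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, int(lp.level_cm * 10))))
    angles = rng.normal(lp.angle_mean_deg, lp.angle_sd_deg, size=n)
    bad = (angles <= 0) | (angles >= 90)
    while bad.any():
        angles[bad] = rng.normal(lp.angle_mean_deg, lp.angle_sd_deg, size=int(bad.sum()))
        bad = (angles <= 0) | (angles >= 90)
    offsets = rng.normal(lp.artery_mean_offset_mm, lp.artery_sd_mm, size=n)

    ref = math.radians(REFERENCE_CORRIDOR_DEG)
    along, off = along_mm, offsets
    px = along * math.cos(ref) - off * math.sin(ref)
    py = along * math.sin(ref) + off * math.cos(ref)

    def dist_to(theta_deg):
        t = np.radians(theta_deg)
        return np.abs(np.cos(t) * py - np.sin(t) * px)

    d_fan = np.minimum(np.minimum(dist_to(20.0), dist_to(30.0)), dist_to(angles))
    accepted = d_fan >= lp.min_clearance_mm
    if not accepted.any():
        raise CalibrationError(
            f"level {lp.level_cm} cm: clearance {lp.min_clearance_mm} mm rejects every draw"
        )
    d_screw = dist_to(angle_deg)[accepted]
    return float(np.mean(d_screw <= diameter_mm / 2.0))


def calibrate_artery_means(
    target_rates: Mapping[float, float] | Sequence[float],
    config: CohortConfig,
    diameter_mm: float = 3.5,
    angle_deg: float = REFERENCE_CORRIDOR_DEG,
    *,
    n: int = 5000,
    tol: float = 0.03,
    seed: int = 20_240_316,
) -> CohortConfig:
    """Adjust per-level artery mean offsets so the simulated flag rate for the
    given (angle, diameter) arm hits each target.

    ``target_rates`` maps level (cm) to a proportion in [0, 1], or is a
    sequence aligned with ``config.levels``.  Levels with target 0 are given a
    hard clearance above the screw radius instead of a bisection solve.
    Raises :class:`CalibrationError` naming the level when a target cannot be
    reached within the offset bounds.
    """
    if not isinstance(target_rates, Mapping):
        if len(target_rates) != len(config.levels):
            raise ConfigError(
                f"{len(target_rates)} targets for {len(config.levels)} levels"
            )
        target_rates = {
            lp.level_cm: float(t) for lp, t in zip(config.levels, target_rates)
        }
    for lv, t in target_rates.items():
        if not 0.0 <= t <= 1.0:
            raise ConfigError(f"target rate {t} at level {lv} cm outside [0, 1]")
    missing = set(config.level_heights) - set(target_rates)
    if missing:
        raise ConfigError(f"no target rate for levels {sorted(missing)}")

    radius = diameter_mm / 2.0
    new_levels = []
    for lp in config.levels:
        target = target_rates[lp.level_cm]
        if target == 0.0:
            clearance = max(lp.min_clearance_mm, radius + 0.75)
            new_levels.append(
                replace(
                    lp,
                    min_clearance_mm=clearance,
                    artery_mean_offset_mm=clearance + 4.0 * lp.artery_sd_mm,
                )
            )
            continue

        def rate(mean: float) -> float:
            return simulated_flag_rate(
                replace(lp, artery_mean_offset_mm=mean),
                angle_deg=angle_deg,
                diameter_mm=diameter_mm,
                along_mm=config.artery_along_mm,
                n=n,
                seed=seed,
            )

        lo, hi = 0.0, 30.0
        if rate(lo) < target - tol:
            raise CalibrationError(
                f"level {lp.level_cm} cm: target {target} unreachable "
                f"(rate at zero offset is {rate(lo):.3f})"
            )
        if rate(hi) > target + tol:
            raise CalibrationError(
                f"level {lp.level_cm} cm: target {target} unreachable "
                f"(rate at offset {hi} mm is {rate(hi):.3f})"
            )
        for _ in range(45):
            mid = 0.5 * (lo + hi)
            if rate(mid) > target:
                lo = mid
            else:
                hi = mid
        mean = 0.5 * (lo + hi)
        achieved = rate(mean)
        if abs(achieved - target) > tol:
            raise CalibrationError(
                f"level {lp.level_cm} cm: achieved rate {achieved:.3f} misses "
                f"target {target:.3f} by more than {tol}"
            )
        new_levels.append(replace(lp, artery_mean_offset_mm=mean))
    return replace(config, levels=tuple(new_levels))


# ---------------------------------------------------------------------------
# Cohort CSV round-trip
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "ankle_id",
    "level_cm",
    "epi_axis_x",
    "epi_axis_y",
    "entry_x_mm",
    "entry_y_mm",
    "artery_x_mm",
    "artery_y_mm",
    "indiv_dir_x",
    "indiv_dir_y",
    "indiv_angle_deg",
    "incisura_visible",
]


def cohort_to_frame(cohort: Iterable[AnkleAnatomy]) -> pd.DataFrame:
    rows = []
    for ankle in cohort:
        for rec in ankle.records.values():
            rows.append(
                {
                    "ankle_id": ankle.ankle_id,
                    "level_cm": rec.level_cm,
                    "epi_axis_x": rec.epicondylar_axis_direction[0],
                    "epi_axis_y": rec.epicondylar_axis_direction[1],
                    "entry_x_mm": rec.fibula_entry_point[0],
                    "entry_y_mm": rec.fibula_entry_point[1],
                    "artery_x_mm": rec.artery_position[0],
                    "artery_y_mm": rec.artery_position[1],
                    "indiv_dir_x": rec.individual_angle_direction[0],
                    "indiv_dir_y": rec.individual_angle_direction[1],
                    "indiv_angle_deg": rec.individual_angle_deg,
                    "incisura_visible": rec.incisura_visible,
                }
            )
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> Cohort:
    missing = set(_COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"cohort table missing columns {sorted(missing)}")
    anatomies = []
    for ankle_id, group in frame.groupby("ankle_id", sort=False):
        records: dict[float, LevelRecord] = {}
        for _, row in group.iterrows():
            for pref in ("epi_axis", "indiv_dir"):
                v = np.array([row[f"{pref}_x"], row[f"{pref}_y"]])
                if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{pref} not unit-norm for ankle {ankle_id} level {row['level_cm']}"
                    )
            records[float(row["level_cm"])] = LevelRecord(
                level_cm=float(row["level_cm"]),
                epicondylar_axis_direction=np.array([row["epi_axis_x"], row["epi_axis_y"]]),
                fibula_entry_point=np.array([row["entry_x_mm"], row["entry_y_mm"]]),
                artery_position=np.array([row["artery_x_mm"], row["artery_y_mm"]]),
                individual_angle_direction=np.array([row["indiv_dir_x"], row["indiv_dir_y"]]),
                individual_angle_deg=float(row["indiv_angle_deg"]),
                incisura_visible=bool(row["incisura_visible"]),
            )
        anatomies.append(AnkleAnatomy(ankle_id=str(ankle_id), records=records))
    return Cohort(anatomies)


def write_cohort_csv(cohort: Iterable[AnkleAnatomy], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    # round_trip parsing: CSVs must reproduce stored floats bit-for-bit
    return frame_to_cohort(pd.read_csv(path, float_precision="round_trip"))
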