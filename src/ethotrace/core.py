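"""Domain types and configuration for the behavior-monitoring pipeline.

The system records individually caged flies with a stereo camera pair,
reduces each video frame to a single 3D position inside the cage, and
classifies every frame into one of six behaviors (resting, micro-movement,
walking, flying, feeding, drinking).  The types here carry the geometry of
one cage, the acquisition settings of the nine-cage round-robin recorder,
and the distance thresholds of the rule-based classifier.

Coordinate convention: right-handed cage frame, origin at the
front-bottom-left corner, x across the front face, y into the cage
(depth), z up.  All lengths are millimetres, all times seconds.
"""

from __future__ import annotations

import enum
import math
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterator

import numpy as np

__all__ = [
    "BehaviorLabel",
    "Position3D",
    "FrameRecord",
    "Bout",
    "CageGeometry",
    "ClassifierConfig",
    "ExperimentConfig",
    "ValidationError",
    "load_config",
    "UNSET",
]


class ValidationError(ValueError):
    """A configuration or data object violates one of its invariants."""


class BehaviorLabel(enum.IntEnum):
    """The six classifiable behaviors plus bookkeeping sentinels.

    ``NO_DATA`` and ``DEAD`` appear only in summary tables, never inside a
    classified bout; ``UNSET`` marks frames not yet classified.
    """

    RESTING = 0
    MICRO_MOVEMENT = 1
    WALKING = 2
    FLYING = 3
    FEEDING = 4
    DRINKING = 5
    NO_DATA = -1
    DEAD = -2
    UNSET = -3


UNSET = int(BehaviorLabel.UNSET)

#: Single-letter codes used in bout log files.
LABEL_LETTERS = {
    BehaviorLabel.RESTING: "R",
    BehaviorLabel.MICRO_MOVEMENT: "M",
    BehaviorLabel.WALKING: "W",
    BehaviorLabel.FLYING: "F",
    BehaviorLabel.FEEDING: "E",
    BehaviorLabel.DRINKING: "D",
}
LETTER_LABELS = {v: k for k, v in LABEL_LETTERS.items()}

#: The six classifiable behaviors in canonical order (profile vector order).
CLASSIFIABLE = (
    BehaviorLabel.RESTING,
    BehaviorLabel.MICRO_MOVEMENT,
    BehaviorLabel.WALKING,
    BehaviorLabel.FLYING,
    BehaviorLabel.FEEDING,
    BehaviorLabel.DRINKING,
)


@dataclass(frozen=True)
class Position3D:
    """A point in the cage frame (mm)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a) -> "Position3D":
        return Position3D(float(a[0]), float(a[1]), float(a[2]))

    def distance_to(self, other: "Position3D") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass(frozen=True)
class FrameRecord:
    """One sampled video frame: time offset within the bout, 3D position, label."""

    time: float
    position: Position3D
    label: BehaviorLabel | None = None


@dataclass
class CageGeometry:
    """Dimensions of one cage and the fixed food/water stations on its floor."""

    width: float = 150.0
    depth: float = 150.0
    height: float = 150.0
    food_center: Position3D = field(default_factory=lambda: Position3D(40.0, 20.0, 0.0))
    water_center: Position3D = field(default_factory=lambda: Position3D(110.0, 130.0, 0.0))
    top_fraction: float = 0.25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("width", "depth", "height"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"cage.{name} must be positive")
        if not 0.0 < self.top_fraction < 1.0:
            raise ValidationError("cage.top_fraction must be in (0, 1)")
        for name, p in (("food_center", self.food_center), ("water_center", self.water_center)):
            if p.z != 0.0:
                raise ValidationError(f"cage.{name} must lie on the cage floor (z = 0)")
            if not self.contains(p):
                raise ValidationError(f"cage.{name} lies outside the cage")
        if self.food_center == self.water_center:
            raise ValidationError("cage.food_center and cage.water_center must differ")

    @property
    def top_z(self) -> float:
        """Lower boundary of the top region of the cage."""
        return (1.0 - self.top_fraction) * self.height

    def contains(self, p: Position3D, tol: float = 1e-9) -> bool:
        return (
            -tol <= p.x <= self.width + tol
            and -tol <= p.y <= self.depth + tol
            and -tol <= p.z <= self.height + tol
        )

    def bounds(self) -> np.ndarray:
        return np.array([self.width, self.depth, self.height])


@dataclass
class ClassifierConfig:
    """Distance thresholds and counts for the rule-based behavior classifier.

    delta_rest / delta_walk / delta_fly are millimetre thresholds on
    inter-frame (0.2 s) Euclidean displacement; window_n is the frame count
    of the net-displacement window that separates micro-movement from
    walking; feeding/drinking require at least feed_min_points consecutive
    resting frames inside a circle of the given radius around the station;
    a fly resting uninterruptedly for death_hours is flagged dead.
    """

    delta_rest: float = 1.0
    delta_walk: float = 5.0
    delta_fly: float = 20.0
    window_n: int = 5
    feed_min_points: int = 25
    feed_radius: float = 10.0
    drink_radius: float = 10.0
    death_hours: float = 5.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.delta_rest < self.delta_walk < self.delta_fly:
            raise ValidationError(
                "classifier thresholds must satisfy 0 < delta_rest < delta_walk < delta_fly "
                f"(got {self.delta_rest}, {self.delta_walk}, {self.delta_fly})"
            )
        if self.window_n < 2:
            raise ValidationError("classifier.window_n must be >= 2")
        if self.feed_min_points < 1:
            raise ValidationError("classifier.feed_min_points must be >= 1")
        if self.feed_radius <= 0 or self.drink_radius <= 0:
            raise ValidationError("classifier station radii must be positive")
        if self.death_hours <= 0:
            raise ValidationError("classifier.death_hours must be positive")

    def check_stations(self, geometry: CageGeometry) -> None:
        """Food and water circles must be disjoint so a resting run is never
        simultaneously a feeding and a drinking candidate."""
        sep = geometry.food_center.distance_to(geometry.water_center)
        if sep <= self.feed_radius + self.drink_radius:
            raise ValidationError(
                "food and water stations are closer than feed_radius + drink_radius "
                f"({sep:.1f} mm <= {self.feed_radius + self.drink_radius:.1f} mm)"
            )


@dataclass
class ExperimentConfig:
    """Acquisition settings of the round-robin recorder.

    Nine cages are visited sequentially; each visit records one
    bout_duration_s bout at rate_hz and is followed by process_s of on-line
    processing, so each fly is revisited every
    cages * (bout_duration_s + process_s) seconds (18 min at defaults).
    """

    cages: int = 9
    rate_hz: float = 5.0
    bout_duration_s: float = 60.0
    process_s: float = 60.0
    lights_on_hour: int = 7
    lights_off_hour: int = 19
    start: datetime = field(default_factory=lambda: datetime(2020, 1, 1, 0, 0, 0))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cages < 1:
            raise ValidationError("experiment.cages must be >= 1")
        if self.rate_hz <= 0 or self.bout_duration_s <= 0 or self.process_s < 0:
            raise ValidationError("experiment timing values must be positive")
        if not 0 <= self.lights_on_hour < self.lights_off_hour <= 24:
            raise ValidationError(
                "experiment light schedule must satisfy 0 <= lights_on_hour < lights_off_hour <= 24"
            )

    @property
    def frames_per_bout(self) -> int:
        return int(round(self.rate_hz * self.bout_duration_s))

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def cycle_s(self) -> float:
        """Full round-robin period, equal to the per-fly inter-bout interval."""
        return self.cages * (self.bout_duration_s + self.process_s)

    def daytime_hours(self) -> range:
        return range(self.lights_on_hour, self.lights_off_hour)


class Bout:
    """One continuous recording of a single fly.

    Positions are stored as an (n, 3) float array in cage coordinates;
    labels as int8 behavior codes (``UNSET`` until classified).
    """

    def __init__(
        self,
        fly_id: str,
        cage_id: int,
        start: datetime,
        rate_hz: float,
        duration_s: float,
        positions: np.ndarray,
        labels: np.ndarray | None = None,
        geometry: CageGeometry | None = None,
    ) -> None:
        self.fly_id = fly_id
        self.cage_id = int(cage_id)
        self.start = start
        self.rate_hz = float(rate_hz)
        self.duration_s = float(duration_s)
        self.positions = np.asarray(positions, dtype=float)
        if labels is None:
            labels = np.full(len(self.positions), UNSET, dtype=np.int8)
        self.labels = np.asarray(labels, dtype=np.int8)
        self.geometry = geometry if geometry is not None else CageGeometry()
        self.validate()

    def validate(self) -> None:
        n_expected = int(round(self.rate_hz * self.duration_s))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("bout positions must be an (n, 3) array")
        if len(self.positions) != n_expected:
            raise ValidationError(
                f"bout has {len(self.positions)} frames, expected "
                f"round(rate_hz * duration_s) = {n_expected}"
            )
        if len(self.labels) != len(self.positions):
            raise ValidationError("bout labels length differs from frame count")
        bounds = self.geometry.bounds()
        if (self.positions < -1e-6).any() or (self.positions > bounds + 1e-6).any():
            raise ValidationError("bout positions fall outside the cage")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Frame time offsets (s) from bout start."""
        return np.arange(self.n_frames) / self.rate_hz

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s)

    @property
    def frames(self) -> Iterator[FrameRecord]:
        for i in range(self.n_frames):
            code = int(self.labels[i])
            yield FrameRecord(
                time=i / self.rate_hz,
                position=Position3D.from_array(self.positions[i]),
                label=None if code == UNSET else BehaviorLabel(code),
            )

    def with_labels(self, labels: np.ndarray) -> "Bout":
        return Bout(
            self.fly_id,
            self.cage_id,
            self.start,
            self.rate_hz,
            self.duration_s,
            self.positions,
            np.asarray(labels, dtype=np.int8),
            self.geometry,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bout):
            return NotImplemented
        return (
            self.fly_id == other.fly_id
            and self.cage_id == other.cage_id
            and self.start == other.start
            and self.rate_hz == other.rate_hz
            and self.duration_s == other.duration_s
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.labels, other.labels)
            and self.geometry == other.geometry
        )

    def __repr__(self) -> str:
        return (
            f"Bout(fly={self.fly_id!r}, cage={self.cage_id}, start={self.start.isoformat()}, "
            f"{self.n_frames} frames @ {self.rate_hz:g} Hz)"
        )


# ---------------------------------------------------------------------------
# Configuration file loading
# ---------------------------------------------------------------------------

def _apply(cls, section: dict, prefix: str, transform=None):
    known = set(cls.__dataclass_fields__)
    kwargs = {}
    for key, value in section.items():
        if key not in known:
            raise ValidationError(f"unknown config key [{prefix}] {key}")
        if transform and key in transform:
            value = transform[key](value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> tuple[ExperimentConfig, ClassifierConfig, CageGeometry]:
    """Load a TOML config with ``[experiment]``, ``[classifier]`` and ``[cage]``
    sections; any field left out takes the documented default.

    Raises :class:`ValidationError` naming the offending field if any
    invariant is violated.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    point = lambda v: Position3D(*map(float, v))
    exp = _apply(
        ExperimentConfig,
        dict(raw.get("experiment", {})),
        "experiment",
        transform={"start": lambda v: v if isinstance(v, datetime) else datetime.fromisoformat(v)},
    )
    cfg = _apply(ClassifierConfig, dict(raw.get("classifier", {})), "classifier")
    cage = _apply(
        CageGeometry,
        dict(raw.get("cage", {})),
        "cage",
        transform={"food_center": point, "water_center": point},
    )
    cfg.check_stations(cage)
    return exp, cfg, cage
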