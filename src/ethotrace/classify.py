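"""Rule-based behavior classification from 3D displacements.

Every frame of a bout is labeled with one of the six behaviors by
deterministic distance rules applied to the fly's 3D path:

* a consecutive-frame displacement at or below ``delta_rest`` is resting;
* a displacement at or above ``delta_fly`` is flying;
* remaining ("pending") transitions are adjudicated in tumbling windows of
  ``window_n`` frames: if the net displacement between the window's first
  and last frame is at most ``delta_walk`` the pending transitions are
  micro-movement (large steps, little net motion — grooming-like), else
  walking;
* a maximal run of at least ``feed_min_points`` consecutive resting frames
  whose positions all lie within ``feed_radius`` of the food station is
  relabeled feeding; likewise ``drink_radius`` around water gives drinking;
* a fly resting without interruption for ``death_hours`` (5 h by default)
  is flagged dead.

Transition labels are assigned to the later of the two frames; frame 0
inherits the first transition's label.  Ties: resting uses <=, flying >=,
and the walking window uses <= on the net displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .core import (
    Bout,
    BehaviorLabel,
    CageGeometry,
    ClassifierConfig,
    ValidationError,
)

__all__ = [
    "Ethogram",
    "DeathRecord",
    "RestSpan",
    "pair_displacements",
    "classify_bout",
    "resting_spans",
    "detect_death",
]

_REST = int(BehaviorLabel.RESTING)
_MICRO = int(BehaviorLabel.MICRO_MOVEMENT)
_WALK = int(BehaviorLabel.WALKING)
_FLY = int(BehaviorLabel.FLYING)
_FEED = int(BehaviorLabel.FEEDING)
_DRINK = int(BehaviorLabel.DRINKING)
_PENDING = -128


@dataclass
class Ethogram:
    """Per-frame behavior labels aligned to one bout."""

    bout: Bout
    labels: np.ndarray  # int8 codes, one per frame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != self.bout.n_frames:
            raise ValidationError("ethogram length differs from bout frame count")
        if not np.isin(self.labels, [_REST, _MICRO, _WALK, _FLY, _FEED, _DRINK]).all():
            raise ValidationError("ethogram contains non-behavior codes")

    def counts(self) -> np.ndarray:
        """Frame counts for the six behaviors, in canonical label order."""
        return np.bincount(self.labels, minlength=6)[:6]

    @property
    def all_resting(self) -> bool:
        return bool((self.labels == _REST).all())


@dataclass
class DeathRecord:
    """Onset of the terminal (>= death_hours) resting run, if any."""

    fly_id: str
    onset: datetime | None

    @property
    def is_dead(self) -> bool:
        return self.onset is not None


def pair_displacements(bout: Bout) -> np.ndarray:
    """Euclidean distances (mm) between consecutive frame positions."""
    if bout.n_frames < 2:
        raise ValidationError("pair_displacements needs at least 2 frames")
    return np.linalg.norm(np.diff(bout.positions, axis=0), axis=1)


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of True runs."""
    edges = np.flatnonzero(np.diff(np.r_[False, mask, False]))
    return edges[::2], edges[1::2]


def classify_bout(
    bout: Bout,
    cfg: ClassifierConfig | None = None,
    geometry: CageGeometry | None = None,
) -> Ethogram:
    """Label every frame of *bout* using the distance rules above."""
    cfg = cfg if cfg is not None else ClassifierConfig()
    geometry = geometry if geometry is not None else bout.geometry
    cfg.check_stations(geometry)
    P = bout.positions
    n = bout.n_frames
    if n < 2:
        raise ValidationError("cannot classify a bout with fewer than 2 frames")

    # Stage 1: per-transition thresholds.
    d = np.linalg.norm(np.diff(P, axis=0), axis=1)
    trans = np.full(n - 1, _PENDING, dtype=np.int16)
    trans[d <= cfg.delta_rest] = _REST
    trans[d >= cfg.delta_fly] = _FLY

    # Stage 2: tumbling windows over frames, aligned to the bout start; a
    # transition belongs to the window holding its later frame.  The final
    # (possibly short) window is judged over its actual span.
    pending = trans == _PENDING
    if pending.any():
        N = cfg.window_n
        first = np.arange(0, n, N)
        last = np.minimum(first + N - 1, n - 1)
        net = np.linalg.norm(P[last] - P[first], axis=1)
        window_of_transition = np.arange(1, n) // N
        is_micro = net[window_of_transition] <= cfg.delta_walk
        trans[pending] = np.where(is_micro[pending], _MICRO, _WALK)

    labels = np.empty(n, dtype=np.int8)
    labels[1:] = trans
    labels[0] = trans[0]

    # Stage 3: feeding/drinking relabeling of resting runs near a station.
    rest = labels == _REST
    if rest.any():
        for station, radius, code in (
            (geometry.food_center, cfg.feed_radius, _FEED),
            (geometry.water_center, cfg.drink_radius, _DRINK),
        ):
            near = np.linalg.norm(P - station.as_array(), axis=1) <= radius
            starts, ends = _runs(rest)
            for s, e in zip(starts, ends):
                if e - s >= cfg.feed_min_points and near[s:e].all():
                    labels[s:e] = code
        # runs already relabeled feeding are no longer resting candidates
        # for drinking; recomputing `rest` is unnecessary because the
        # station circles are disjoint (check_stations).
    return Ethogram(bout, labels)


# ---------------------------------------------------------------------------
# Resting runs across a bout timeline, and death detection
# ---------------------------------------------------------------------------

@dataclass
class RestSpan:
    """A maximal resting run on a fly's timeline.

    ``duration_s`` counts covered frame time (each frame spans one sampling
    period) plus any bridged inter-bout gaps.
    """

    onset: datetime
    end: datetime

    @property
    def duration_s(self) -> float:
        return (self.end - self.onset).total_seconds()

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


def resting_spans(
    ethograms: list[Ethogram],
    cfg: ClassifierConfig | None = None,
) -> list[RestSpan]:
    """Maximal resting runs of one fly across its time-ordered ethograms.

    Within a bout a run is a maximal stretch of resting frames.  Runs in
    contiguous bouts (gap of at most one frame period) join if resting
    continues across the boundary.  A genuine inter-bout gap (the recorder
    is visiting other cages) is bridged only when it is bracketed by two
    all-resting bouts whose boundary positions agree within ``delta_rest``
    — no frames exist inside a gap, so motion there can only be excluded
    by the flanking evidence.
    """
    cfg = cfg if cfg is not None else ClassifierConfig()
    if not ethograms:
        raise ValidationError("resting_spans needs at least one ethogram")
    ethograms = sorted(ethograms, key=lambda e: e.bout.start)
    spans: list[RestSpan] = []
    open_span: RestSpan | None = None
    prev: Ethogram | None = None

    for eth in ethograms:
        bout = eth.bout
        period = bout.frame_period_s
        rest = eth.labels == _REST
        starts, ends = _runs(rest)
        run_iter = list(zip(starts, ends))

        if open_span is not None:
            bridged = False
            if run_iter and run_iter[0][0] == 0 and prev is not None:
                gap = (bout.start - prev.bout.end).total_seconds()
                if gap <= period + 1e-9:
                    bridged = True  # contiguous recording
                elif prev.all_resting and eth.all_resting:
                    agree = (
                        np.linalg.norm(bout.positions[0] - prev.bout.positions[-1])
                        <= cfg.delta_rest
                    )
                    bridged = bool(agree)
            if bridged:
                s, e = run_iter.pop(0)
                open_span.end = bout.start + timedelta(seconds=e * period)
                if e < bout.n_frames:  # resting ended inside this bout
                    spans.append(open_span)
                    open_span = None
            else:
                spans.append(open_span)
                open_span = None

        for s, e in run_iter:
            if open_span is not None:
                spans.append(open_span)
            open_span = RestSpan(
                onset=bout.start + timedelta(seconds=s * period),
                end=bout.start + timedelta(seconds=e * period),
            )
            if e < bout.n_frames:
                spans.append(open_span)
                open_span = None
        prev = eth

    if open_span is not None:
        spans.append(open_span)
    return spans


def detect_death(
    ethograms: list[Ethogram],
    cfg: ClassifierConfig | None = None,
) -> DeathRecord:
    """Flag the fly dead at the onset of the earliest resting run lasting at
    least ``death_hours``; returns an empty record otherwise."""
    cfg = cfg if cfg is not None else ClassifierConfig()
    spans = resting_spans(ethograms, cfg)
    fly_id = ethograms[0].bout.fly_id
    threshold = cfg.death_hours * 3600.0
    for span in spans:  # spans are in onset order
        if span.duration_s >= threshold - 1e-6:
            return DeathRecord(fly_id, span.onset)
    return DeathRecord(fly_id, None)
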