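"""Synthetic ground truth: a six-state behavioral simulator plus the
round-robin acquisition scheduler and bout sampler.

The fly is modeled as a semi-Markov process over the six behaviors.  It
rests most of the time; the propensity to leave resting is modulated by an
hour-of-day weight profile (diurnal rhythm, lights on 07:00-19:00 with a
strong late-afternoon peak) and by an age multiplier that rises to a peak
around day 15-20 of life and then declines.  On leaving rest the fly
starts a micro-movement, walking or flying episode with exponential dwell
time, or makes a feeding/drinking excursion: it walks to the station,
dwells there nearly motionless, then walks off.  Per-state displacement
kernels are scaled so the behaviors are separable by the classifier's
distance thresholds (resting jitter far below delta_rest, flying steps far
above delta_fly, and so on).

Internally a lifetime is an episode table on a fixed 0.2 s grid: dense
per-step positions are stored only for moving episodes, while stationary
episodes keep an anchor point plus a deterministic hash-derived jitter
stream, so a 40-day lifetime stays small in memory yet reconstructs the
full-resolution path exactly and reproducibly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .core import (
    BehaviorLabel,
    Bout,
    CageGeometry,
    ExperimentConfig,
    ValidationError,
)
from .io import write_bout_log

__all__ = [
    "SimConfig",
    "TrueTrajectory",
    "BoutSchedule",
    "FlyData",
    "default_hourly_weights",
    "simulate_lifetime",
    "schedule_bouts",
    "sample_bout",
    "iter_cohort",
    "generate_cohort",
    "validation_sim_config",
    "simulate_validation_bouts",
    "planted_archetype_sim",
]

_REST = int(BehaviorLabel.RESTING)
_MICRO = int(BehaviorLabel.MICRO_MOVEMENT)
_WALK = int(BehaviorLabel.WALKING)
_FLY = int(BehaviorLabel.FLYING)
_FEED = int(BehaviorLabel.FEEDING)
_DRINK = int(BehaviorLabel.DRINKING)


def default_hourly_weights() -> np.ndarray:
    """Relative propensity to leave resting, by clock hour.

    Calibrated so the *realized* distance distribution shows the diurnal
    structure the recorder is meant to resolve: lights-on hours
    (07:00-19:00) carry ~90% of daily distance, the late afternoon
    (15:00-19:00) ~50%, with the single peak at 18:00 and night hours
    sharing the small remainder evenly.  Nominal weights are slightly
    sharper than the realized shares because busy hours saturate (time
    spent moving is unavailable for further rest exits).
    """
    w = np.empty(24)
    w[:7] = 0.085 / 12
    w[19:] = 0.085 / 12
    w[7:15] = 0.395 / 8
    w[15:19] = [0.105, 0.115, 0.135, 0.165]
    return w


@dataclass
class SimConfig:
    """Parameters of the lifetime behavior simulator.

    Dwell means are in seconds, displacement scales in mm per 0.2 s step.
    ``activity_mix`` is the (micro, walk, fly) episode-type distribution on
    leaving rest; station visits are drawn separately with per-exit
    probabilities ``p_feed``/``p_drink``.  ``phase_profiles`` optionally
    overrides (rest_mean_s, activity_mix) by age phase — used to plant
    age-specific behavioral archetypes; each entry is
    (end_day, rest_mean_s, activity_mix).
    """

    step_s: float = 0.2
    lifespan_days: float | None = None  # None: drawn per fly, N(60, 15) clipped >= 5
    rest_mean_s: float = 600.0
    micro_mean_s: float = 12.0
    walk_mean_s: float = 10.0
    fly_mean_s: float = 2.0
    activity_mix: tuple[float, float, float] = (0.55, 0.35, 0.10)
    p_feed: float = 0.02
    p_drink: float = 0.02
    feed_dwell_s: float = 60.0
    drink_dwell_s: float = 40.0
    station_stop_mm: float = 4.5
    rest_jitter_mm: float = 0.0
    micro_amp_mm: tuple[float, float] = (1.2, 1.6)
    micro_noise_mm: float = 0.1
    walk_step_mm: float = 6.0
    walk_step_sd: float = 0.5
    walk_step_clip: tuple[float, float] = (5.2, 8.0)
    walk_turn_sd: float = 0.3
    fly_step_mm: float = 65.0
    fly_step_clip: tuple[float, float] = (60.0, 130.0)
    hourly_weights: np.ndarray = field(default_factory=default_hourly_weights)
    age_peak_day: float = 18.0
    age_floor: float = 0.25
    age_power: float = 6.0
    age_decline_tau_days: float = 12.0
    age_modulation: bool = True
    phase_profiles: tuple | None = None

    def __post_init__(self) -> None:
        self.hourly_weights = np.asarray(self.hourly_weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.step_s <= 0:
            raise ValidationError("sim.step_s must be positive")
        for name in ("rest_mean_s", "micro_mean_s", "walk_mean_s", "fly_mean_s",
                     "feed_dwell_s", "drink_dwell_s", "walk_step_mm", "fly_step_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"sim.{name} must be positive")
        if self.hourly_weights.shape != (24,) or (self.hourly_weights < 0).any():
            raise ValidationError("sim.hourly_weights must be 24 non-negative values")
        if len(self.activity_mix) != 3 or min(self.activity_mix) < 0:
            raise ValidationError("sim.activity_mix must be 3 non-negative weights")
        if self.p_feed < 0 or self.p_drink < 0 or self.p_feed + self.p_drink >= 1:
            raise ValidationError("sim.p_feed + sim.p_drink must lie in [0, 1)")

    def age_multiplier(self, day: float) -> float:
        """Activity multiplier a(day): rises to 1 at ``age_peak_day``, then
        declines exponentially with time constant ``age_decline_tau_days``
        (senescence is faster than the juvenile rise)."""
        if not self.age_modulation:
            return 1.0
        day = max(day, 0.0)
        if day <= self.age_peak_day:
            r = day / self.age_peak_day
            shape = (r * math.exp(1.0 - r)) ** self.age_power
        else:
            shape = math.exp(-(day - self.age_peak_day) / self.age_decline_tau_days)
        return self.age_floor + (1.0 - self.age_floor) * shape

    def phase_params(self, day: float) -> tuple[float, tuple[float, float, float]]:
        if self.phase_profiles:
            for end_day, rest_mean, mix in self.phase_profiles:
                if day < end_day:
                    return rest_mean, mix
            return self.phase_profiles[-1][1], self.phase_profiles[-1][2]
        return self.rest_mean_s, self.activity_mix


# ---------------------------------------------------------------------------
# Deterministic jitter for stationary episodes (splitmix64-style hash)
# ---------------------------------------------------------------------------

_U = np.uint64


def _hash_u64(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        z = x + _U(0x9E3779B97F4A7C15)
        z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
        return z ^ (z >> _U(31))


def _jitter(seed: int, ep: np.ndarray, k: np.ndarray, sigma: float) -> np.ndarray:
    """Reproducible per-(episode, step) jitter, uniform in +-sigma per axis."""
    out = np.empty((len(ep), 3))
    with np.errstate(over="ignore"):
        base = (_U(seed & 0xFFFFFFFF) << _U(40)) ^ (ep.astype(_U) << _U(24)) ^ k.astype(_U)
        for axis, salt in enumerate((0x1234, 0xABCD, 0x7F0F)):
            h = _hash_u64(base + _U(salt) * _U(0x10000000000000))
            out[:, axis] = (h >> _U(11)).astype(float) * 2.0 ** -53
    return (out * 2.0 - 1.0) * sigma


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

class TrueTrajectory:
    """A fly's lifetime ground truth as a grid-aligned episode table.

    Episode i occupies times ``(t0[i], t1[i]]`` on the ``step_s`` grid (the
    position at an episode's start instant still belongs to the previous
    episode: a state change takes effect with the first step into it).
    Moving episodes store the dense per-step path; stationary ones an
    anchor plus deterministic jitter.  After ``death_time`` the position is
    frozen.
    """

    def __init__(self, geometry, sim, seed, t0, t1, states, anchors, offsets,
                 counts, path_store, death_time, horizon_s, frozen_ep):
        self.geometry = geometry
        self.sim = sim
        self.seed = int(seed)
        self.t0 = t0
        self.t1 = t1
        # integer step-grid episode boundaries: exact attribution of sample
        # times to episodes (float comparison at boundaries is off-by-one)
        self._k1 = np.rint(t1 / sim.step_s).astype(np.int64)
        self._k0 = np.rint(t0 / sim.step_s).astype(np.int64)
        self.states = states
        self.anchors = anchors
        self.offsets = offsets
        self.counts = counts
        self.path_store = path_store
        self.death_time = death_time
        self.horizon_s = float(horizon_s)
        self._frozen_ep = frozen_ep
        self.step_s = sim.step_s

    @property
    def n_episodes(self) -> int:
        return len(self.t0)

    def _episode_of(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        kg = np.rint(t / self.step_s).astype(np.int64)
        ep = np.searchsorted(self._k1, kg, side="left")
        return np.minimum(ep, self.n_episodes - 1), kg

    def positions_at(self, times) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if (t < -1e-9).any() or (t > self.horizon_s + 1e-9).any():
            raise ValidationError("requested times fall outside the trajectory span")
        ep, kg = self._episode_of(t)
        k = np.clip(kg - self._k0[ep], 0, self.counts[ep])
        out = np.empty((len(t), 3))
        moving = self.offsets[ep] >= 0
        if moving.any():
            out[moving] = self.path_store[self.offsets[ep[moving]] + k[moving]]
        stat = ~moving
        if stat.any():
            jit = _jitter(self.seed, ep[stat], k[stat], self.sim.rest_jitter_mm)
            if self._frozen_ep is not None:
                jit[ep[stat] == self._frozen_ep] = 0.0
            out[stat] = self.anchors[ep[stat]] + jit
        return out

    def labels_at(self, times) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        ep, _ = self._episode_of(t)
        return self.states[ep].astype(np.int8)

    def dense(self, t_start: float, t_end: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, positions, labels) at every grid step in [t_start, t_end)."""
        times = np.arange(t_start, t_end - 1e-9, self.step_s)
        return times, self.positions_at(times), self.labels_at(times)


# ---------------------------------------------------------------------------
# Lifetime simulation
# ---------------------------------------------------------------------------

def _rand_unit(rng, n: int | None = None) -> np.ndarray:
    v = rng.normal(size=(n or 1, 3))
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    return v if n else v[0]


def _fold(points: np.ndarray, lo: float, hi: np.ndarray) -> np.ndarray:
    """Reflect positions into the box [lo, hi] per axis (billiard walls)."""
    span = hi - lo
    m = np.mod(points - lo, 2.0 * span)
    return lo + np.minimum(m, 2.0 * span - m)


class _Builder:
    def __init__(self) -> None:
        self.t0: list[float] = []
        self.states: list[int] = []
        self.anchors: list[np.ndarray] = []
        self.counts: list[int] = []
        self.paths: list[np.ndarray | None] = []

    def add_stationary(self, t: float, state: int, anchor: np.ndarray, counts: int) -> float:
        self.t0.append(t)
        self.states.append(state)
        self.anchors.append(anchor.copy())
        self.counts.append(counts)
        self.paths.append(None)
        return anchor

    def add_moving(self, t: float, state: int, path: np.ndarray) -> np.ndarray:
        self.t0.append(t)
        self.states.append(state)
        self.anchors.append(path[0].copy())
        self.counts.append(len(path) - 1)
        self.paths.append(path)
        return path[-1]


def simulate_lifetime(
    sim: SimConfig,
    geometry: CageGeometry,
    seed: int,
    horizon_s: float,
    start_hour: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TrueTrajectory:
    """Simulate one fly's ground-truth trajectory over ``horizon_s`` seconds.

    ``start_hour`` is the clock hour at experiment time zero (the diurnal
    weight profile is indexed by wall-clock hour).  Identical seeds produce
    identical trajectories.
    """
    sim.validate()
    rng = rng if rng is not None else np.random.default_rng(seed)
    step = sim.step_s
    horizon = round(horizon_s / step) * step
    bounds = geometry.bounds()
    lo, hi = 0.5, bounds - 0.5
    total_w = sim.hourly_weights.sum()
    # an all-zero profile is legal: the fly never leaves resting
    wrel = sim.hourly_weights / (total_w / 24.0) if total_w > 0 else np.zeros(24)

    lifespan = sim.lifespan_days
    if lifespan is None:
        lifespan = max(5.0, rng.normal(60.0, 15.0))
    death_time: float | None = lifespan * 86400.0
    if death_time >= horizon:
        death_time = None
    sim_end = round((death_time if death_time is not None else horizon) / step) * step

    def rate_at(tt: float) -> float:
        hour = int((start_hour + tt / 3600.0) % 24)
        day = tt / 86400.0
        rest_mean, _ = sim.phase_params(day)
        return wrel[hour] * sim.age_multiplier(day) / rest_mean

    def sample_rest_exit(t: float) -> float:
        target = rng.exponential()
        tt = t
        while tt < sim_end:
            lam = rate_at(tt)
            hour_end = (math.floor((start_hour * 3600.0 + tt) / 3600.0) + 1) * 3600.0 - start_hour * 3600.0
            bound = min(sim_end, hour_end)
            cap = lam * (bound - tt)
            if cap >= target and lam > 0:
                return tt + target / lam
            target -= cap
            tt = bound
        return sim_end

    def walk_path(start: np.ndarray, n: int) -> np.ndarray:
        steps = np.clip(rng.normal(sim.walk_step_mm, sim.walk_step_sd, n), *sim.walk_step_clip)
        drift = _rand_unit(rng) + np.cumsum(rng.normal(0.0, sim.walk_turn_sd, (n, 3)), axis=0)
        drift /= np.maximum(np.linalg.norm(drift, axis=1, keepdims=True), 1e-12)
        pts = np.vstack([start, start + np.cumsum(drift * steps[:, None], axis=0)])
        return _fold(pts, lo, hi)

    def fly_path(start: np.ndarray, n: int) -> np.ndarray:
        # darting flight: each frame the fly repositions anywhere in the cage
        # within the configured jump band, so no wall bounce can shrink a
        # flight step below the jump minimum
        jump_lo, jump_hi = sim.fly_step_clip
        pts = np.empty((n + 1, 3))
        pts[0] = start
        cur = start
        for j in range(1, n + 1):
            while True:
                cand = rng.uniform(lo, hi)
                if jump_lo <= np.linalg.norm(cand - cur) <= jump_hi:
                    break
            pts[j] = cand
            cur = cand
        return pts

    def micro_path(start: np.ndarray, n: int) -> np.ndarray:
        anchor = np.clip(start, lo + 2.0, hi - 2.0)
        u = _rand_unit(rng)
        amp = rng.uniform(*sim.micro_amp_mm, size=n)
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        offs = signs[:, None] * amp[:, None] * u + rng.normal(0.0, sim.micro_noise_mm, (n, 3))
        return np.vstack([start, anchor + offs])

    def station_path(start: np.ndarray, target: np.ndarray) -> np.ndarray | None:
        """Straight directed walk toward a station, stopping station_stop_mm short."""
        delta = target - start
        dist = float(np.linalg.norm(delta)) - sim.station_stop_mm
        if dist < sim.walk_step_mm:
            return None  # already at the station
        n = max(1, int(math.ceil(dist / sim.walk_step_mm)))
        u = delta / np.linalg.norm(delta)
        along = np.linspace(dist / n, dist, n)
        noise = rng.normal(0.0, 0.3, (n, 3))
        noise -= np.outer(noise @ u, u)  # keep noise perpendicular to the approach
        pts = np.vstack([start, start + np.outer(along, u) + noise])
        return np.clip(pts, lo, hi)

    b = _Builder()
    pos = rng.uniform(np.full(3, 10.0), bounds - 10.0)
    t = 0.0

    def steps_left(tt: float) -> int:
        return int(round((sim_end - tt) / step))

    while t < sim_end - 1e-9:
        # --- resting ---
        exit_t = sample_rest_exit(t)
        counts = max(1, int(round((exit_t - t) / step)))
        counts = min(counts, steps_left(t))
        if counts <= 0:
            break
        b.add_stationary(t, _REST, pos, counts)
        t += counts * step
        if steps_left(t) <= 0:
            break

        # --- activity episode ---
        day = t / 86400.0
        _, mix = sim.phase_params(day)
        u01 = rng.random()
        if u01 < sim.p_feed + sim.p_drink:
            station = geometry.food_center if u01 < sim.p_feed else geometry.water_center
            dwell_mean = sim.feed_dwell_s if u01 < sim.p_feed else sim.drink_dwell_s
            state = _FEED if u01 < sim.p_feed else _DRINK
            path = station_path(pos, station.as_array())
            if path is not None:
                n = min(len(path) - 1, steps_left(t))
                if n <= 0:
                    continue
                pos = b.add_moving(t, _WALK, path[: n + 1])
                t += n * step
            n = min(max(5, int(round(rng.exponential(dwell_mean) / step))), steps_left(t))
            if n <= 0:
                continue
            pos = b.add_stationary(t, state, pos, n)
            t += n * step
            # walk off the station so the next rest does not sit inside it
            n = min(max(1, int(round(rng.exponential(sim.walk_mean_s) / step))), steps_left(t))
            if n <= 0:
                continue
            pos = b.add_moving(t, _WALK, walk_path(pos, n))
            t += n * step
        else:
            mix_p = np.asarray(mix, dtype=float)
            mix_p = mix_p / mix_p.sum()
            state = [_MICRO, _WALK, _FLY][rng.choice(3, p=mix_p)]
            mean = {_MICRO: sim.micro_mean_s, _WALK: sim.walk_mean_s, _FLY: sim.fly_mean_s}[state]
            n = min(max(1, int(round(rng.exponential(mean) / step))), steps_left(t))
            if n <= 0:
                continue
            gen = {_MICRO: micro_path, _WALK: walk_path, _FLY: fly_path}[state]
            pos = b.add_moving(t, state, gen(pos, n))
            t += n * step

    frozen_ep = None
    if death_time is not None and t < horizon - 1e-9:
        frozen_ep = len(b.t0)
        b.add_stationary(t, _REST, pos, int(round((horizon - t) / step)))

    t0 = np.asarray(b.t0)
    counts_arr = np.asarray(b.counts, dtype=np.int64)
    t1 = t0 + counts_arr * step
    offsets = np.full(len(t0), -1, dtype=np.int64)
    store_parts = []
    cursor = 0
    for i, p in enumerate(b.paths):
        if p is not None:
            offsets[i] = cursor
            store_parts.append(p)
            cursor += len(p)
    path_store = np.concatenate(store_parts) if store_parts else np.empty((0, 3))
    return TrueTrajectory(
        geometry, sim, seed, t0, t1,
        np.asarray(b.states, dtype=np.int8),
        np.asarray(b.anchors), offsets, counts_arr, path_store,
        death_time, horizon, frozen_ep,
    )


# ---------------------------------------------------------------------------
# Acquisition schedule and bout sampling
# ---------------------------------------------------------------------------

@dataclass
class BoutSchedule:
    """Round-robin recording schedule: ordered (cage_id, start_s) entries."""

    entries: list[tuple[int, float]]
    cycle_s: float

    def for_cage(self, cage_id: int) -> np.ndarray:
        return np.array([s for c, s in self.entries if c == cage_id])

    def per_fly_interval_s(self) -> float:
        return self.cycle_s


def schedule_bouts(exp: ExperimentConfig, horizon_s: float) -> BoutSchedule:
    """Each cage is recorded for bout_duration_s, then processed for
    process_s, before the recorder moves to the next cage; the pattern is
    exactly periodic with period cages * (bout + process)."""
    if exp.cages < 1:
        raise ValidationError("schedule requires at least one cage")
    slot = exp.bout_duration_s + exp.process_s
    entries: list[tuple[int, float]] = []
    k = 0
    while True:
        cycle_start = k * exp.cycle_s
        if cycle_start + exp.bout_duration_s > horizon_s:
            break
        for c in range(exp.cages):
            start = cycle_start + c * slot
            if start + exp.bout_duration_s <= horizon_s:
                entries.append((c, start))
        k += 1
    return BoutSchedule(entries, exp.cycle_s)


def sample_bout(
    truth: TrueTrajectory,
    start_s: float,
    exp: ExperimentConfig,
    fly_id: str,
    cage_id: int,
) -> tuple[Bout, np.ndarray]:
    """Sample one bout from the ground truth at the camera rate.

    Returns the bout with *unset* labels plus the parallel ground-truth
    label sequence (retained separately for validation).
    """
    if start_s < 0 or start_s + exp.bout_duration_s > truth.horizon_s + 1e-9:
        raise ValidationError("bout sampling window falls outside the trajectory span")
    times = start_s + np.arange(exp.frames_per_bout) / exp.rate_hz
    positions = truth.positions_at(times)
    gt = truth.labels_at(times)
    bout = Bout(
        fly_id,
        cage_id,
        exp.start + timedelta(seconds=start_s),
        exp.rate_hz,
        exp.bout_duration_s,
        positions,
        geometry=truth.geometry,
    )
    return bout, gt


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class FlyData:
    """All sampled data for one fly of a synthetic cohort."""

    fly_id: str
    tag: str
    cage_id: int
    death_day: int | None  # 1-based day of life containing the death, None if censored
    bouts: list[Bout]
    truth_labels: list[np.ndarray]
    death_time_s: float | None = None


def _fly_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def iter_cohort(
    n_flies: int,
    days: float,
    exp: ExperimentConfig | None = None,
    geometry: CageGeometry | None = None,
    sim: SimConfig | None = None,
    seed: int = 0,
    tags: Sequence[str] | None = None,
    sim_overrides: dict[str, SimConfig] | None = None,
) -> Iterator[FlyData]:
    """Generate a cohort fly by fly (streaming; ground-truth trajectories are
    discarded after sampling).

    Flies are assigned to cages round-robin; a fly's per-seed stream is
    derived deterministically from the master seed and its index.  No bout
    is recorded after the day a fly dies.
    """
    if n_flies < 1:
        raise ValidationError("cohort needs at least one fly")
    exp = exp if exp is not None else ExperimentConfig()
    geometry = geometry if geometry is not None else CageGeometry()
    sim = sim if sim is not None else SimConfig()
    horizon_s = days * 86400.0
    schedule = schedule_bouts(exp, horizon_s)
    start_hour = exp.start.hour + exp.start.minute / 60.0

    for i in range(n_flies):
        tag = tags[i] if tags is not None else "default"
        fly_sim = (sim_overrides or {}).get(tag, sim)
        ss = _fly_seed(seed, i)
        child_seed = int(ss.generate_state(1)[0]) & 0x7FFFFFFF
        rng = np.random.default_rng(ss)
        truth = simulate_lifetime(fly_sim, geometry, child_seed, horizon_s,
                                  start_hour=start_hour, rng=rng)
        cage = i % exp.cages
        death_day = None
        cutoff = horizon_s
        if truth.death_time is not None:
            death_day = int(truth.death_time // 86400.0) + 1
            cutoff = death_day * 86400.0  # bouts continue to the end of the death day
        fly_id = f"fly_{i:03d}"
        bouts: list[Bout] = []
        gts: list[np.ndarray] = []
        for start_s in schedule.for_cage(cage):
            if start_s + exp.bout_duration_s > cutoff:
                break
            bout, gt = sample_bout(truth, start_s, exp, fly_id, cage)
            bouts.append(bout)
            gts.append(gt)
        yield FlyData(fly_id, tag, cage, death_day, bouts, gts, truth.death_time)


def generate_cohort(
    n_flies: int,
    days: float,
    out_dir,
    exp: ExperimentConfig | None = None,
    geometry: CageGeometry | None = None,
    sim: SimConfig | None = None,
    seed: int = 0,
    tags: Sequence[str] | None = None,
    sim_overrides: dict[str, SimConfig] | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a synthetic cohort to disk: one directory per fly holding daily
    bout-log files plus ground-truth label files, and a cohort manifest CSV.
    Refuses to write into an existing non-empty directory unless *overwrite*.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ValidationError(f"output directory {out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    letters = "RMWFED"
    manifest_rows = []
    for fly in iter_cohort(n_flies, days, exp, geometry, sim, seed, tags, sim_overrides):
        fly_dir = out / fly.fly_id
        fly_dir.mkdir(exist_ok=True)
        exp_cfg = exp if exp is not None else ExperimentConfig()
        by_day: dict[int, list[int]] = {}
        for j, bout in enumerate(fly.bouts):
            day = int((bout.start - exp_cfg.start).total_seconds() // 86400) + 1
            by_day.setdefault(day, []).append(j)
        for day, idxs in sorted(by_day.items()):
            with open(fly_dir / f"day_{day:03d}.tsv", "w") as fh:
                for j in idxs:
                    write_bout_log(fly.bouts[j], fh)
            with open(fly_dir / f"day_{day:03d}.truth.tsv", "w") as fh:
                for j in idxs:
                    gt = "".join(letters[c] for c in fly.truth_labels[j])
                    fh.write(f"{fly.bouts[j].start.isoformat()}\t{gt}\n")
        manifest_rows.append(
            (fly.fly_id, fly.tag, fly.cage_id,
             "" if fly.death_day is None else fly.death_day)
        )
    with open(out / "cohort.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fly_id", "tag", "cage_id", "death_day"])
        writer.writerows(manifest_rows)
    return out


# ---------------------------------------------------------------------------
# Presets: classifier validation and planted archetypes
# ---------------------------------------------------------------------------

def validation_sim_config() -> SimConfig:
    """Balanced short-dwell preset for ground-truth classifier validation.

    Uniform diurnal weights, no station visits and comparable dwell times
    across the four locomotor behaviors, so a modest number of bouts
    contains ample resting, micro-movement, walking and flying frames.
    Displacement scales are the defaults (threshold-separated).
    """
    return SimConfig(
        rest_mean_s=8.0,
        micro_mean_s=10.0,
        walk_mean_s=10.0,
        fly_mean_s=2.4,
        activity_mix=(0.4, 0.4, 0.2),
        p_feed=0.0,
        p_drink=0.0,
        hourly_weights=np.full(24, 1.0 / 24.0),
        age_modulation=False,
        lifespan_days=1e6,
    )


def simulate_validation_bouts(
    n_bouts: int,
    seed: int,
    exp: ExperimentConfig | None = None,
    geometry: CageGeometry | None = None,
    sim: SimConfig | None = None,
) -> list[tuple[Bout, np.ndarray]]:
    """Contiguous bouts with retained ground truth for recall measurement."""
    exp = exp if exp is not None else ExperimentConfig()
    geometry = geometry if geometry is not None else CageGeometry()
    sim = sim if sim is not None else validation_sim_config()
    horizon = n_bouts * exp.bout_duration_s
    truth = simulate_lifetime(sim, geometry, seed, horizon)
    out = []
    for i in range(n_bouts):
        bout, gt = sample_bout(truth, i * exp.bout_duration_s, exp, "validation", 0)
        out.append((bout, gt))
    return out


def planted_archetype_sim(
    young_end_day: float = 20.0,
    middle_end_day: float = 40.0,
) -> SimConfig:
    """Three planted age-phase behavior archetypes.

    Mirrors the qualitative ordering seen in aged cohorts: middle age has
    the highest walking/flying load, old age the most resting and
    micro-movement, youth sits in between.  Phases are constant within
    themselves so 10-day age groups inside one phase are near-identical.
    """
    return SimConfig(
        age_modulation=False,
        lifespan_days=1e6,
        phase_profiles=(
            (young_end_day, 500.0, (0.60, 0.30, 0.10)),
            (middle_end_day, 150.0, (0.25, 0.55, 0.20)),
            (float("inf"), 1500.0, (0.75, 0.20, 0.05)),
        ),
    )
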