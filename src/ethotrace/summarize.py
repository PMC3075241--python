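"""Lifetime descriptive analytics.

All summaries are built from a fly's classified bouts.  Because the
recorder only samples 2-3 one-minute bouts per cage per hour, hourly
values are scaled to full-hour estimates: a cell of the day x hour matrix
is the sum over that hour's bouts multiplied by 3600 / seconds actually
recorded.  Hours with no recording carry a no-data marker (NaN).

Day 1 is the first day of the experiment clock; the clock hour of a bout
is taken from its absolute start time, so the light cycle (lights on
07:00, off 19:00 by default) indexes the circadian profiles directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BehaviorLabel,
    Bout,
    CageGeometry,
    ClassifierConfig,
    ExperimentConfig,
    ValidationError,
)
from .classify import Ethogram, resting_spans

__all__ = [
    "HourlyMatrix",
    "bout_distance",
    "hourly_activity",
    "circadian_profile",
    "age_profile",
    "top_occupancy",
    "rest_runs",
    "event_history",
    "behavior_frequencies",
    "survival_from_deaths",
    "peak_day",
    "distance_share",
]

REST_BINS = (0.0, 1.0, 2.0, 3.0, np.inf)
REST_BIN_LABELS = ("<1", "1-2", "2-3", ">3")


@dataclass
class HourlyMatrix:
    """Day-of-life x clock-hour matrix; NaN cells mark unrecorded hours."""

    values: pd.DataFrame  # index: day (1-based), columns: 0..23
    kind: str  # "distance" (mm, full-hour estimate) or a behavior name (count)

    @property
    def days(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def total(self) -> float:
        return float(np.nansum(self.values.to_numpy()))


def bout_distance(bout: Bout) -> float:
    """Total path length (mm) of one bout."""
    if bout.n_frames < 2:
        raise ValidationError("bout_distance needs at least 2 frames")
    return float(np.linalg.norm(np.diff(bout.positions, axis=0), axis=1).sum())


def _day_hour(bout: Bout, exp: ExperimentConfig) -> tuple[int, int]:
    day = int((bout.start - exp.start).total_seconds() // 86400) + 1
    return day, bout.start.hour


def _check_sorted_nonoverlapping(bouts: list[Bout]) -> None:
    for a, b in zip(bouts, bouts[1:]):
        if b.start < a.end:
            raise ValidationError(f"overlapping bouts at {b.start.isoformat()}")


def hourly_activity(
    pairs: list[tuple[Bout, Ethogram]],
    exp: ExperimentConfig | None = None,
    geometry: CageGeometry | None = None,
) -> tuple[HourlyMatrix, dict[BehaviorLabel, HourlyMatrix], HourlyMatrix]:
    """Hourly summaries for one fly.

    Returns the distance matrix (full-hour estimates, mm), one count matrix
    per behavior (full-hour estimated frame counts) and the top-of-cage
    occupancy fraction matrix.  A bout is attributed to the clock hour it
    starts in.
    """
    exp = exp if exp is not None else ExperimentConfig()
    if not pairs:
        raise ValidationError("hourly_activity needs at least one bout")
    pairs = sorted(pairs, key=lambda pe: pe[0].start)
    bouts = [b for b, _ in pairs]
    _check_sorted_nonoverlapping(bouts)
    geometry = geometry if geometry is not None else bouts[0].geometry
    n_days = max(_day_hour(b, exp)[0] for b in bouts)

    dist = np.zeros((n_days, 24))
    seconds = np.zeros((n_days, 24))
    counts = np.zeros((6, n_days, 24))
    top_frames = np.zeros((n_days, 24))
    frames = np.zeros((n_days, 24))
    for bout, eth in pairs:
        day, hour = _day_hour(bout, exp)
        r, c = day - 1, hour
        dist[r, c] += bout_distance(bout)
        seconds[r, c] += bout.duration_s
        counts[:, r, c] += eth.counts()
        top_frames[r, c] += (bout.positions[:, 2] >= geometry.top_z).sum()
        frames[r, c] += bout.n_frames

    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(seconds > 0, 3600.0 / np.where(seconds > 0, seconds, 1.0), np.nan)
        top_frac = np.where(frames > 0, top_frames / np.where(frames > 0, frames, 1.0), np.nan)
    days_idx = pd.RangeIndex(1, n_days + 1, name="day")
    cols = pd.RangeIndex(0, 24, name="hour")
    as_df = lambda a: pd.DataFrame(a, index=days_idx, columns=cols)
    dist_m = HourlyMatrix(as_df(dist * scale), "distance")
    count_ms = {
        lab: HourlyMatrix(as_df(counts[int(lab)] * scale), lab.name.lower())
        for lab in list(BehaviorLabel)[:6]
    }
    top_m = HourlyMatrix(as_df(top_frac), "top_occupancy")
    return dist_m, count_ms, top_m


def circadian_profile(matrices: list[HourlyMatrix], mode: str = "none") -> np.ndarray:
    """Average each clock hour over all fly-days with data.

    mode: "none" (raw hourly means), "peak" (max = 1) or "share" (sums to
    1 over hours with data).  All-missing hours stay NaN and are excluded
    from normalization.
    """
    if not matrices:
        raise ValidationError("circadian_profile needs at least one matrix")
    stacked = np.vstack([m.values.to_numpy() for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing hours
        prof = np.nanmean(stacked, axis=0)
    return _normalize(prof, mode)


def _normalize(values: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return values
    finite = np.isfinite(values)
    out = values.astype(float).copy()
    if mode == "peak":
        peak = np.nanmax(values)
        if peak > 0:
            out[finite] = values[finite] / peak
        return out
    if mode == "share":
        total = np.nansum(values)
        if total > 0:
            out[finite] = values[finite] / total
        return out
    raise ValidationError(f"unknown normalization mode {mode!r}")


def age_profile(matrices: list[HourlyMatrix], mode: str = "none") -> pd.Series:
    """Per-day activity series averaged across flies alive on each day.

    A fly-day's value is the mean over its recorded hours scaled to 24 h;
    flies contribute nothing after their last recorded day.
    """
    if not matrices:
        raise ValidationError("age_profile needs at least one matrix")
    per_fly = []
    for m in matrices:
        vals = m.values.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # unrecorded days
            daily = np.nanmean(vals, axis=1) * 24.0
        per_fly.append(pd.Series(daily, index=m.values.index))
    table = pd.concat(per_fly, axis=1)
    series = table.mean(axis=1, skipna=True)
    out = _normalize(series.to_numpy(), mode)
    return pd.Series(out, index=series.index, name="daily_activity")


def top_occupancy(
    pairs: list[tuple[Bout, Ethogram]],
    geometry: CageGeometry | None = None,
    exp: ExperimentConfig | None = None,
) -> np.ndarray:
    """Fraction of recorded frames spent in the top region of the cage, by
    clock hour (averaged over days) for one fly."""
    _, _, top_m = hourly_activity(pairs, exp, geometry)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing hours
        return np.nanmean(top_m.values.to_numpy(), axis=0)


def rest_runs(
    ethograms: list[Ethogram],
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Rest (sleep-like) bout table for one fly: onset, duration and
    duration bin (<1, 1-2, 2-3, >3 hours)."""
    spans = resting_spans(ethograms, cfg)
    durations = [s.duration_h for s in spans]
    return pd.DataFrame(
        {
            "onset": [s.onset for s in spans],
            "duration_h": durations,
            "bin": pd.cut(durations, REST_BINS, labels=REST_BIN_LABELS, right=False)
            if spans
            else pd.Categorical([], categories=REST_BIN_LABELS),
        }
    )


def event_history(
    pairs: list[tuple[Bout, Ethogram]],
    target: BehaviorLabel,
    exp: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Day x hour event-history matrix for one behavior.

    1 = behavior present in at least one frame that hour, 0 = recorded but
    absent, NaN = no data.  Rows run from the fly's first day to its last.
    """
    exp = exp if exp is not None else ExperimentConfig()
    if not pairs:
        raise ValidationError("event_history needs at least one bout")
    n_days = max(_day_hour(b, exp)[0] for b, _ in pairs)
    mat = np.full((n_days, 24), np.nan)
    for bout, eth in pairs:
        day, hour = _day_hour(bout, exp)
        present = (eth.labels == int(target)).any()
        cell = mat[day - 1, hour]
        mat[day - 1, hour] = max(cell, float(present)) if np.isfinite(cell) else float(present)
    return pd.DataFrame(
        mat, index=pd.RangeIndex(1, n_days + 1, name="day"), columns=pd.RangeIndex(0, 24, name="hour")
    )


def behavior_frequencies(
    pairs: list[tuple[Bout, Ethogram]],
    start_day: float,
    end_day: float,
    exp: ExperimentConfig | None = None,
) -> np.ndarray | None:
    """Six-behavior frame-share vector over the age interval
    [start_day, end_day) (days of life, 1-based); None if no frames."""
    exp = exp if exp is not None else ExperimentConfig()
    counts = np.zeros(6)
    for bout, eth in pairs:
        day, _ = _day_hour(bout, exp)
        if start_day <= day < end_day:
            counts += eth.counts()
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def survival_from_deaths(manifest: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival step curve from a cohort manifest.

    *manifest* needs columns ``day`` (death day, or last observed day for
    censored flies) and ``dead`` (bool).  Returns (day, fraction_alive),
    right-continuous, starting at 1.
    """
    from lifelines import KaplanMeierFitter

    if len(manifest) == 0:
        raise ValidationError("survival needs at least one fly")
    km = KaplanMeierFitter()
    km.fit(manifest["day"], event_observed=manifest["dead"].astype(bool))
    sf = km.survival_function_
    return pd.DataFrame({"day": sf.index.to_numpy(), "fraction_alive": sf.iloc[:, 0].to_numpy()})


def peak_day(series: pd.Series, smooth_days: int = 3) -> int:
    """Day of peak activity, estimated on a centered rolling mean.

    Daily totals from 2-3 bouts/hour are noisy; a short rolling mean keeps
    the peak-day estimate from latching onto single-day excursions.
    """
    s = series.rolling(smooth_days, center=True, min_periods=1).mean()
    return int(s.idxmax())


def distance_share(matrices: list[HourlyMatrix], hours: range) -> float:
    """Percentage of total distance falling in the given clock hours."""
    total = 0.0
    in_hours = 0.0
    for m in matrices:
        vals = m.values.to_numpy()
        total += np.nansum(vals)
        in_hours += np.nansum(vals[:, list(hours)])
    if total == 0:
        raise ValidationError("no recorded distance")
    return 100.0 * in_hours / total
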