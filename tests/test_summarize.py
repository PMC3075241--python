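"""Hourly matrices, circadian/age profiles, rest bouts, event history,
behavior frequencies and survival."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from ethotrace.classify import Ethogram
from ethotrace.core import BehaviorLabel, ValidationError
from ethotrace.summarize import (
    age_profile,
    behavior_frequencies,
    bout_distance,
    circadian_profile,
    distance_share,
    event_history,
    hourly_activity,
    rest_runs,
    survival_from_deaths,
    top_occupancy,
)

from conftest import labeled_bout, make_bout

R, M, W, F = 0, 1, 2, 3
WALK = BehaviorLabel.WALKING


def pair(bout):
    """Classified pair with an all-resting ethogram (labels irrelevant)."""
    return bout, Ethogram(bout, np.zeros(bout.n_frames, dtype=np.int8))


def distance_bout(total_mm, start, n=300, rate=5.0):
    """Bout of given total path length along x, parked at mid-cage."""
    step = total_mm / (n - 1)
    x = 40.0 + np.abs(np.arange(n) * step - 0.0)
    # keep inside the cage by zig-zagging
    x = 40.0 + (np.arange(n) * step) % 50.0
    pos = np.column_stack([x, np.full(n, 75.0), np.zeros(n)])
    b = make_bout(pos, rate_hz=rate, start=start)
    return b


class TestBoutDistance:
    def test_hand_computed_path(self):
        b = make_bout([(0, 0, 0), (3, 0, 0), (3, 4, 0)], rate_hz=1.0)
        assert bout_distance(b) == pytest.approx(7.0)

    def test_stationary_is_zero(self):
        assert bout_distance(make_bout(np.full((5, 3), 10.0), rate_hz=1.0)) == 0.0

    def test_at_least_net_displacement(self):
        rng = np.random.default_rng(0)
        pos = np.clip(np.cumsum(rng.normal(0, 2, (30, 3)), axis=0) + 75.0, 0, 150)
        b = make_bout(pos, rate_hz=1.0)
        assert bout_distance(b) >= np.linalg.norm(pos[-1] - pos[0]) - 1e-9


class TestHourlyActivity:
    def test_single_bout_scaled_to_full_hour(self, exp):
        start = exp.start + timedelta(hours=10)
        b = make_bout(
            np.column_stack([np.linspace(40, 50, 300), np.full(300, 75.0), np.zeros(300)]),
            start=start,
        )  # 10 mm over one 60 s bout
        dist_m, _, _ = hourly_activity([pair(b)], exp)
        assert dist_m.values.loc[1, 10] == pytest.approx(600.0)

    def test_two_bouts_share_the_hour_scale(self, exp):
        start = exp.start + timedelta(hours=10)
        mk = lambda t0, x1: make_bout(
            np.column_stack([np.linspace(40, 40 + x1, 300), np.full(300, 75.0), np.zeros(300)]),
            start=t0,
        )
        pairs = [pair(mk(start, 5.0)), pair(mk(start + timedelta(minutes=18), 5.0))]
        dist_m, _, _ = hourly_activity(pairs, exp)
        assert dist_m.values.loc[1, 10] == pytest.approx(300.0)

    def test_unrecorded_hours_are_nan(self, exp):
        b = make_bout(np.full((300, 3), 75.0), start=exp.start + timedelta(hours=10))
        dist_m, _, _ = hourly_activity([pair(b)], exp)
        row = dist_m.values.loc[1]
        assert np.isfinite(row[10]) and row.drop(10).isna().all()

    def test_distance_additivity_unscaled(self, exp):
        rng = np.random.default_rng(1)
        pairs = []
        total = 0.0
        for h in range(5):
            b = distance_bout(10.0, exp.start + timedelta(hours=h))
            total += bout_distance(b)
            pairs.append(pair(b))
        dist_m, _, _ = hourly_activity(pairs, exp)
        # each cell is dist * 3600/60; dividing back recovers the plain sum
        assert np.nansum(dist_m.values.to_numpy()) / 60.0 == pytest.approx(total)

    def test_overlapping_bouts_rejected(self, exp):
        b1 = make_bout(np.full((300, 3), 75.0), start=exp.start)
        b2 = make_bout(np.full((300, 3), 75.0), start=exp.start + timedelta(seconds=30))
        with pytest.raises(ValidationError):
            hourly_activity([pair(b1), pair(b2)], exp)


class TestProfiles:
    def _uniform_matrices(self, exp, value=10.0, days=3):
        pairs = []
        for d in range(days):
            for h in range(24):
                start = exp.start + timedelta(days=d, hours=h)
                pairs.append(pair(distance_bout(value, start)))
        dist_m, _, _ = hourly_activity(pairs, exp)
        return dist_m

    def test_uniform_activity_gives_flat_share(self, exp):
        m = self._uniform_matrices(exp)
        prof = circadian_profile([m], mode="share")
        assert np.allclose(prof, 1 / 24)
        assert np.nansum(prof) == pytest.approx(1.0)

    def test_constant_activity_gives_flat_age_series(self, exp):
        m = self._uniform_matrices(exp)
        series = age_profile([m])
        assert np.allclose(series, series.iloc[0])

    def test_peak_mode_max_is_one(self, exp):
        m = self._uniform_matrices(exp)
        assert np.nanmax(age_profile([m], mode="peak")) == pytest.approx(1.0)

    def test_dead_flies_drop_out_of_the_average(self, exp):
        long_lived = self._uniform_matrices(exp, value=10.0, days=4)
        short_lived = self._uniform_matrices(exp, value=30.0, days=2)
        series = age_profile([long_lived, short_lived])
        # hourly cells are 600 resp. 1800 mm/h; daily totals 24x that
        assert series.loc[1] == pytest.approx((600.0 + 1800.0) / 2 * 24, rel=1e-3)
        assert series.loc[3] == pytest.approx(600.0 * 24, rel=1e-3)  # only the survivor

    def test_distance_share_of_subset_hours(self, exp):
        m = self._uniform_matrices(exp)
        assert distance_share([m], range(0, 12)) == pytest.approx(50.0)


class TestTopOccupancy:
    def _bout_at_height(self, exp, z, hour):
        pos = np.column_stack([np.full(300, 75.0), np.full(300, 75.0), np.full(300, z)])
        return pair(make_bout(pos, start=exp.start + timedelta(hours=hour)))

    def test_ceiling_floor_and_mixture(self, exp, geometry):
        top = self._bout_at_height(exp, geometry.height, 8)
        bottom = self._bout_at_height(exp, 0.0, 9)
        prof = top_occupancy([top, bottom], geometry, exp)
        assert prof[8] == 1.0 and prof[9] == 0.0
        half = np.column_stack(
            [np.full(300, 75.0), np.full(300, 75.0),
             np.where(np.arange(300) % 2 == 0, geometry.height, 0.0)]
        )
        prof2 = top_occupancy([pair(make_bout(half, start=exp.start + timedelta(hours=10)))],
                              geometry, exp)
        assert prof2[10] == pytest.approx(0.5)


class TestRestRuns:
    def test_binning(self, cfg):
        rate = 5.0
        mk = lambda minutes, start: Ethogram(
            labeled_bout([R] * int(minutes * 60 * rate), rate_hz=rate, start=start),
            np.full(int(minutes * 60 * rate), R, dtype=np.int8),
        )
        t0 = datetime(2020, 1, 2)
        table = rest_runs([mk(90, t0)], cfg)
        assert list(table["bin"]) == ["1-2"]
        table2 = rest_runs([mk(30, t0)], cfg)
        assert list(table2["bin"]) == ["<1"]

    def test_interrupted_rest_gives_two_rows(self, cfg):
        labels = [R] * 100 + [W] + [R] * 100
        eth = Ethogram(labeled_bout(labels), np.asarray(labels, dtype=np.int8))
        assert len(rest_runs([eth], cfg)) == 2


class TestEventHistory:
    def test_present_absent_and_missing_codes(self, exp):
        walking_labels = [R] * 299 + [W]
        b1 = labeled_bout(walking_labels, start=exp.start + timedelta(hours=8))
        b2 = labeled_bout([R] * 300, start=exp.start + timedelta(hours=9))
        pairs = [
            (b1, Ethogram(b1, np.asarray(walking_labels, dtype=np.int8))),
            (b2, Ethogram(b2, np.full(300, R, dtype=np.int8))),
        ]
        hist = event_history(pairs, WALK, exp)
        assert hist.loc[1, 8] == 1.0
        assert hist.loc[1, 9] == 0.0
        assert hist.loc[1, 10] != hist.loc[1, 10]  # NaN: no data

    def test_row_count_equals_lifespan_days(self, exp):
        b = labeled_bout([R] * 300, start=exp.start + timedelta(days=6, hours=3))
        hist = event_history([(b, Ethogram(b, np.full(300, R, dtype=np.int8)))], WALK, exp)
        assert len(hist) == 7


class TestBehaviorFrequencies:
    def test_all_resting(self, exp):
        b = labeled_bout([R] * 300, start=exp.start + timedelta(hours=1))
        freq = behavior_frequencies([(b, Ethogram(b, np.full(300, R, dtype=np.int8)))], 1, 11, exp)
        assert np.allclose(freq, [1, 0, 0, 0, 0, 0])

    def test_uniform_mix_and_unit_sum(self, exp):
        labels = np.repeat(np.arange(6), 50).astype(np.int8)
        b = labeled_bout(labels, start=exp.start + timedelta(hours=1))
        freq = behavior_frequencies([(b, Ethogram(b, labels))], 1, 11, exp)
        assert np.allclose(freq, 1 / 6)
        assert freq.sum() == pytest.approx(1.0)

    def test_empty_interval_returns_none(self, exp):
        b = labeled_bout([R] * 300, start=exp.start + timedelta(hours=1))
        assert behavior_frequencies([(b, Ethogram(b, np.full(300, R, dtype=np.int8)))], 20, 30, exp) is None


class TestSurvival:
    def test_two_deaths_step_curve(self):
        manifest = pd.DataFrame({"day": [10, 20], "dead": [True, True]})
        curve = survival_from_deaths(manifest)
        frac = curve.set_index("day")["fraction_alive"]
        assert frac.loc[10] == pytest.approx(0.5)
        assert frac.loc[20] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        manifest = pd.DataFrame({"day": [134, 134], "dead": [False, False]})
        curve = survival_from_deaths(manifest)
        assert (curve["fraction_alive"] == 1.0).all()

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(0)
        manifest = pd.DataFrame(
            {"day": rng.integers(5, 100, 30), "dead": rng.random(30) < 0.8}
        )
        curve = survival_from_deaths(manifest)
        assert (np.diff(curve["fraction_alive"]) <= 1e-12).all()
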