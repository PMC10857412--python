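"""ECG and zero-activity-run non-wear rules, joint wear, validity filter."""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import madwear as mw
from madwear.errors import ConfigError

START = pd.Timestamp("2016-07-01 08:00:00")


def brute_force_ecg_minutes(values, fs, start, window_s=2.0, thr=0.1, frac=0.02):
    """Literal re-statement of the rule: per-sample truncated centred moving
    average, 0.1 mV deviation labels, then the per-minute active fraction."""
    n = len(values)
    w = int(round(window_s * fs))
    left = w // 2
    right = w - left
    active = []
    for i in range(n):
        lo, hi = max(0, i - left), min(n, i + right)
        active.append(abs(values[i] - np.mean(values[lo:hi])) >= thr)
    minute0 = start.floor("min")
    off0 = (start - minute0).total_seconds()
    buckets: dict = {}
    for i, a in enumerate(active):
        buckets.setdefault(int((off0 + i / fs) // 60), []).append(a)
    return [np.mean(buckets[m]) >= frac for m in sorted(buckets)]


def make_ecg(values, fs=50.0, start=START):
    return mw.EcgSeries("p", start, fs, np.asarray(values, dtype=np.float64))


class TestEcgRule:
    def test_flat_signal_is_nonwear(self):
        mask = mw.ecg_nonwear(make_ecg(np.zeros(int(10 * 60 * 50))))
        assert len(mask) == 10
        assert not mask.wear.any()

    def test_square_wave_is_wear(self):
        t = np.arange(int(3 * 60 * 50)) / 50.0
        mask = mw.ecg_nonwear(make_ecg(np.where((t % 1) < 0.5, 1.0, -1.0)))
        assert mask.wear.all()

    def test_subthreshold_sine_is_nonwear(self):
        t = np.arange(int(3 * 60 * 50)) / 50.0
        mask = mw.ecg_nonwear(make_ecg(0.05 * np.sin(2 * np.pi * t)))
        assert not mask.wear.any()

    @pytest.mark.parametrize("kind", ["flat", "square", "sine", "mixed"])
    def test_matches_brute_force(self, kind, rng):
        fs = 50.0
        t = np.arange(int(4 * 60 * fs)) / fs
        signals = {
            "flat": np.zeros_like(t),
            "square": np.where((t % 1) < 0.5, 1.0, -1.0),
            "sine": 0.05 * np.sin(2 * np.pi * t),
            "mixed": np.where(t < 120, 0.0, 1.0) * np.sign(np.sin(2 * np.pi * 1.3 * t))
            + rng.normal(0, 0.002, t.size),
        }
        start = START + pd.Timedelta(seconds=17)  # partial first minute
        mask = mw.ecg_nonwear(make_ecg(signals[kind], fs, start))
        assert mask.wear.tolist() == brute_force_ecg_minutes(signals[kind], fs, start)

    def test_threshold_monotone(self, rng):
        values = rng.normal(0, 0.1, int(5 * 60 * 50))
        ecg = make_ecg(values)
        previous = mw.ecg_nonwear(ecg, threshold_mv=0.05).wear
        for thr in (0.1, 0.2, 0.5):
            current = mw.ecg_nonwear(ecg, threshold_mv=thr).wear
            assert not np.any(current & ~previous)  # raising thr never adds wear
            previous = current

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            mw.ecg_nonwear(make_ecg([]))


def minute_series(zero_flags, start=START):
    """60-s MAD epoch series: 0 g on flagged minutes, clearly active elsewhere."""
    flags = np.asarray(zero_flags, dtype=bool)
    mad = np.where(flags, 0.0, 0.05)
    idx = pd.DatetimeIndex(start + pd.to_timedelta(np.arange(flags.size), unit="min"))
    return mw.EpochSeries("p", "actigraph", 60, idx, mad, np.full(flags.size, 2400))


def brute_force_zero_runs(flags, run_minutes=90):
    """Independent scan: wear=False exactly inside maximal zero runs >= 90."""
    wear = [True] * len(flags)
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            if j - i >= run_minutes:
                for k in range(i, j):
                    wear[k] = False
            i = j
        else:
            i += 1
    return wear


class TestZeroActivityRule:
    def test_exact_90_minute_run_flagged(self):
        flags = [False] * 10 + [True] * 90 + [False] * 10
        mask = mw.actigraph_nonwear(minute_series(flags))
        assert (~mask.wear).sum() == 90
        assert not mask.wear[10:100].any()

    def test_89_minute_run_kept(self):
        flags = [False] * 10 + [True] * 89 + [False] * 10
        assert mw.actigraph_nonwear(minute_series(flags)).wear.all()

    def test_interrupted_run_kept(self):
        flags = [True] * 50 + [False] + [True] * 49
        assert mw.actigraph_nonwear(minute_series(flags)).wear.all()

    def test_missing_minutes_count_as_zero(self):
        series = minute_series([False] * 200)
        series.mad[100:190] = np.nan
        mask = mw.actigraph_nonwear(series)
        assert (~mask.wear).sum() == 90

    @given(st.lists(st.booleans(), min_size=1, max_size=250))
    def test_matches_brute_force_scan(self, flags):
        mask = mw.actigraph_nonwear(minute_series(flags))
        assert mask.wear.tolist() == brute_force_zero_runs(flags)

    def test_requires_minute_epochs(self):
        series = minute_series([False] * 5)
        series.epoch_length_s = 300
        with pytest.raises(ConfigError):
            mw.actigraph_nonwear(series)


def make_mask(start_hm, end_hm, day="2016-07-01", worn=True, label="a"):
    start = pd.Timestamp(f"{day} {start_hm}")
    n = int((pd.Timestamp(f"{day} {end_hm}") - start).total_seconds() // 60)
    return mw.NonwearMask("p", label, start, np.full(n, worn))


class TestJointWear:
    def test_idempotent_and_commutative(self, rng):
        wear = rng.random(100) < 0.7
        m = mw.NonwearMask("p", "a", START, wear)
        assert np.array_equal(mw.joint_wear(m, m).wear, wear)
        other = mw.NonwearMask("p", "b", START + pd.Timedelta(minutes=30), rng.random(80) < 0.5)
        ab = mw.joint_wear(m, other)
        ba = mw.joint_wear(other, m)
        assert np.array_equal(ab.wear, ba.wear)
        assert ab.start_minute == ba.start_minute

    def test_interval_intersection(self):
        a = make_mask("08:00", "20:00", label="a")
        b = make_mask("14:00", "22:00", label="b")
        joint = mw.joint_wear(a, b)
        worn_minutes = joint.minutes[joint.wear]
        assert worn_minutes[0] == pd.Timestamp("2016-07-01 14:00")
        assert worn_minutes[-1] == pd.Timestamp("2016-07-01 19:59")
        assert len(worn_minutes) == 360

    def test_one_device_off_kills_joint_wear(self):
        a = make_mask("08:00", "12:00", worn=True)
        b = make_mask("08:00", "12:00", worn=False, label="b")
        assert not mw.joint_wear(a, b).wear.any()

    def test_disjoint_spans_warn_and_pair_nothing(self, caplog):
        a = make_mask("08:00", "10:00")
        b = make_mask("11:00", "13:00", label="b")
        with caplog.at_level("WARNING"):
            joint = mw.joint_wear(a, b)
        assert not joint.wear.any()
        assert any("overlap" in m for m in caplog.messages)


def schedule_mask(days, start_hm, end_hm):
    """Joint mask worn daily between the given clock times."""
    start = pd.Timestamp("2016-07-01 00:00")
    minutes = start + pd.to_timedelta(np.arange(days * 1440), unit="min")
    mod = minutes.hour * 60 + minutes.minute
    s = int(start_hm[:2]) * 60 + int(start_hm[3:])
    e = int(end_hm[:2]) * 60 + int(end_hm[3:])
    worn = (mod >= s) & (mod < e) if s < e else (mod >= s) | (mod < e)
    return mw.NonwearMask("p", "joint", start, np.asarray(worn))


class TestValidityFilter:
    def test_three_days_of_exactly_ten_hours_included(self):
        summary = mw.validity_filter(schedule_mask(3, "08:00", "18:00"))
        assert summary.included
        assert summary.n_valid_days == 3
        assert all(m == 600 for m in summary.day_minutes)

    def test_two_valid_days_excluded(self):
        assert not mw.validity_filter(schedule_mask(2, "08:00", "18:00")).included

    def test_overnight_wear_mostly_out_of_window(self):
        summary = mw.validity_filter(schedule_mask(4, "23:00", "09:00"))
        # only 07:00-09:00 of each wear block falls inside 07:00-23:00
        assert all(m == 120 for m in summary.day_minutes[summary.day_minutes > 0])
        assert not summary.included

    def test_custom_window(self):
        summary = mw.validity_filter(
            schedule_mask(3, "00:00", "23:59"),
            min_days=3,
            min_hours=23.0,
            window=(datetime.time(0), datetime.time(23, 59)),
        )
        assert summary.included
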