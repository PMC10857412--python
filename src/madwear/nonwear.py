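"""Device-specific non-wear detection and the wear-validity filter.

Each device gets its own wear/non-wear rule at one-minute resolution:

* **Chest patch (ECG rule).** The ECG is smoothed with a centred 2-s
  rectangular moving average (edges truncated); timepoints whose absolute
  deviation from the smoothed trace is below 0.1 mV are non-wear candidates
  (a worn patch shows QRS deflections well above this, a disconnected lead
  is flat).  The pointwise labels are consolidated per minute: a minute
  counts as wear iff at least ``min_active_fraction`` (default 2%) of its
  samples deviate by ≥ 0.1 mV.  At a resting heart rate the R-waves alone
  occupy ~10% of samples, so worn minutes clear the 2% bar comfortably.

* **Hip device (zero-activity-run rule).** Non-wear is any maximal run of at
  least 90 consecutive "zero-activity" minutes.  Proprietary activity counts
  are not reproduced; instead a minute is zero-activity when its minute-level
  MAD of the vector magnitude falls below one quantization step of the device
  (0.00390625 g for the 12-bit ±8 g sensor) — a worn, resting device
  exhibits sensor and motion noise above one code step, an unworn one
  typically does not.

The cohort inclusion filter requires at least ``min_days`` calendar days with
at least ``min_hours`` hours of overlapping (joint) wear between 07:00 and
23:00 local time.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .device_io import EcgSeries, HIP_ACTIGRAPH, quantization_resolution
from .epoch_features import EpochSeries, segment_starts
from .errors import ConfigError

logger = logging.getLogger(__name__)

_NS_PER_MIN = 60 * 1_000_000_000

#: Default zero-activity threshold: one code step of the hip device, in g.
DEFAULT_ZERO_THRESHOLD_G = quantization_resolution(HIP_ACTIGRAPH)


@dataclasses.dataclass
class NonwearMask:
    """Minute-resolution wear labels for one device.

    ``wear[i]`` covers the minute starting at ``start_minute + i minutes``;
    minutes are contiguous and span the recording.
    """

    participant_id: str
    device_label: str
    start_minute: pd.Timestamp
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.start_minute = pd.Timestamp(self.start_minute).floor("min")
        self.wear = np.asarray(self.wear, dtype=bool)

    def __len__(self) -> int:
        return int(self.wear.size)

    @property
    def minutes(self) -> pd.DatetimeIndex:
        return self.start_minute + pd.to_timedelta(np.arange(self.wear.size), unit="min")

    def to_frame(self) -> pd.DataFrame:
        """Persistable long form: participant,device,minute_start,wear."""
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "device": self.device_label,
                "minute_start": self.minutes,
                "wear": self.wear.astype(int),
            }
        )


@dataclasses.dataclass
class ValiditySummary:
    """Per-day in-window joint wear minutes and the inclusion decision."""

    participant_id: str
    day_minutes: pd.Series  # index: normalized day, values: worn minutes in clock window
    valid_days: list
    included: bool

    @property
    def n_valid_days(self) -> int:
        return len(self.valid_days)


def centered_moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Rectangular moving average, centred, with truncated edges.

    Sample ``i`` averages the window ``[i - w//2, i + (w - w//2))`` clipped
    to the series; near the edges the mean is taken over the samples that
    exist.
    """
    x = np.asarray(values)
    n = x.size
    w = int(window_samples)
    if w < 1:
        raise ValueError("window must span at least one sample")
    left = w // 2
    right = w - left
    # interior in one C pass; ndimage's even-size window is exactly
    # [i - w//2, i + w - w//2), matching the definition above
    out = ndimage.uniform_filter1d(x, size=w, mode="nearest", output=np.float64)
    # truncated-mean edges (the C filter pads instead)
    for i in list(range(0, min(left, n))) + list(range(max(n - right + 1, 0), n)):
        lo, hi = max(0, i - left), min(n, i + right)
        out[i] = np.mean(x[lo:hi], dtype=np.float64)
    return out


def ecg_nonwear(
    ecg: EcgSeries,
    window_s: float = 2.0,
    threshold_mv: float = 0.1,
    min_active_fraction: float = 0.02,
    device_label: str = "zio",
) -> NonwearMask:
    """Minute-level wear mask from the ECG deviation rule (see module docs)."""
    n = ecg.n_samples
    if n == 0:
        raise ValueError("cannot detect wear on an empty ECG series")
    w = int(round(window_s * ecg.sampling_rate_hz))
    if w < 2:
        raise ValueError("window_s * sampling_rate must cover at least 2 samples")
    deviation = centered_moving_average(ecg.values, w)
    np.subtract(ecg.values, deviation, out=deviation)
    np.abs(deviation, out=deviation)
    active = (deviation >= threshold_mv).astype(np.int32)
    del deviation

    minute0 = ecg.start_time.floor("min")
    off0 = (ecg.start_time - minute0).total_seconds()
    _, starts = segment_starts(n, ecg.sampling_rate_hz, off0, 60.0)
    totals = np.diff(np.concatenate((starts, [n])))
    actives = np.add.reduceat(active, starts)
    with np.errstate(invalid="ignore", divide="ignore"):
        wear = (actives / totals) >= min_active_fraction
    wear[totals == 0] = False
    return NonwearMask(ecg.participant_id, device_label, minute0, wear)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    edges = np.diff(np.concatenate(([0], flags.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def actigraph_nonwear(
    minute_activity: EpochSeries,
    run_minutes: int = 90,
    zero_threshold_g: float = DEFAULT_ZERO_THRESHOLD_G,
) -> NonwearMask:
    """Hip-device wear mask from the 90-min zero-activity-run rule.

    ``minute_activity`` must be a one-minute epoch MAD series; a minute with
    missing MAD (too few samples) counts as zero-activity.
    """
    if minute_activity.epoch_length_s != 60:
        raise ConfigError("minute_activity must be a 60-s epoch series")
    mad = minute_activity.mad
    zero = np.isnan(mad) | (mad < zero_threshold_g)
    wear = np.ones(zero.size, dtype=bool)
    for start, end in _runs(zero):
        if end - start >= run_minutes:
            wear[start:end] = False
    return NonwearMask(
        minute_activity.participant_id,
        minute_activity.device_label,
        minute_activity.epoch_start[0],
        wear,
    )


def joint_wear(mask_a: NonwearMask, mask_b: NonwearMask) -> NonwearMask:
    """Minute mask that is worn iff worn in *both* devices.

    The result spans the union of the two devices' spans; minutes outside
    either span are non-wear.  With no temporal overlap at all there are no
    jointly worn minutes (an all-False mask; warning logged).
    """
    if mask_a.participant_id != mask_b.participant_id:
        raise ValueError("joint wear requires masks from the same participant")
    k0a = mask_a.start_minute.value // _NS_PER_MIN
    k0b = mask_b.start_minute.value // _NS_PER_MIN
    k0 = min(k0a, k0b)
    k1 = max(k0a + len(mask_a), k0b + len(mask_b))
    wa = np.zeros(k1 - k0, dtype=bool)
    wb = np.zeros(k1 - k0, dtype=bool)
    wa[k0a - k0: k0a - k0 + len(mask_a)] = mask_a.wear
    wb[k0b - k0: k0b - k0 + len(mask_b)] = mask_b.wear
    if k0a + len(mask_a) <= k0b or k0b + len(mask_b) <= k0a:
        logger.warning(
            "masks for %s (%s, %s) have no temporal overlap",
            mask_a.participant_id, mask_a.device_label, mask_b.device_label,
        )
    return NonwearMask(
        mask_a.participant_id,
        "joint",
        pd.Timestamp(k0 * _NS_PER_MIN),
        wa & wb,
    )


def validity_filter(
    joint: NonwearMask,
    min_days: int = 3,
    min_hours: float = 10.0,
    window: tuple[datetime.time, datetime.time] = (datetime.time(7), datetime.time(23)),
) -> ValiditySummary:
    """Cohort inclusion: ≥ ``min_days`` calendar days with ≥ ``min_hours``
    of joint wear inside the half-open clock window (default 07:00–23:00)."""
    w0 = window[0].hour * 60 + window[0].minute
    w1 = window[1].hour * 60 + window[1].minute
    if not 0 <= w0 < w1 <= 1440:
        raise ConfigError(f"clock window must lie within one day, got {window}")
    if len(joint) == 0:
        return ValiditySummary(joint.participant_id, pd.Series(dtype=np.int64), [], False)
    minutes = joint.minutes
    minute_of_day = minutes.hour * 60 + minutes.minute
    in_window = (minute_of_day >= w0) & (minute_of_day < w1)
    per_day = (
        pd.Series((joint.wear & in_window).astype(np.int64), index=minutes.normalize())
        .groupby(level=0)
        .sum()
    )
    threshold = min_hours * 60
    valid = [day for day, m in per_day.items() if m >= threshold]
    included = len(valid) >= min_days
    if not included:
        logger.info(
            "participant %s excluded: %d valid days (< %d required)",
            joint.participant_id, len(valid), min_days,
        )
    return ValiditySummary(joint.participant_id, per_day, valid, included)
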