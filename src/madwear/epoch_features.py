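"""Vector-magnitude and MAD epoch summaries on a midnight-anchored grid.

Activity intensity is summarised device-wise from raw tri-axial acceleration
in two steps:

1. collapse each sample to its Euclidean vector magnitude
   ``r(t) = sqrt(x(t)^2 + y(t)^2 + z(t)^2)`` (in g), which removes the
   dependence on sensor orientation up to the static gravity offset;
2. within each fixed epoch of H samples compute the mean amplitude
   deviation ``MAD = (1/H) * sum_h |r(t+h) - rbar|`` where ``rbar`` is the
   epoch mean.  Subtracting the epoch mean removes the (constant) gravity
   component, so MAD reflects dynamic motion only.

Epochs are contiguous, half-open ``[t, t + L)`` windows on a grid anchored at
local midnight, so that e.g. 5-min epochs start at :00, :05, ... regardless
of when the recording began; this makes diurnal (clock-time) averaging across
participants well defined.  Each device is summarised at its native sampling
rate — H differs between devices for the same epoch, and no resampling is
performed.  An epoch is reported missing when fewer than ``min_fraction`` of
its nominal ``L * fs`` samples are available (default 90%).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .device_io import RawAccelRecording
from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .nonwear import NonwearMask

logger = logging.getLogger(__name__)

#: The analysis epoch lengths, in seconds: 1, 5, 10, 30 min, 1 h and 2 h.
EPOCH_LENGTHS_S = (60, 300, 600, 1800, 3600, 7200)

_NS_PER_S = 1_000_000_000


@dataclasses.dataclass
class VectorMagnitudeSeries:
    """Per-sample Euclidean norm of the three axes, in g (non-negative)."""

    participant_id: str
    device_label: str
    start_time: pd.Timestamp
    sampling_rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float64)
        if self.values.size and np.min(self.values) < 0:
            raise ValueError("vector magnitudes must be non-negative")


@dataclasses.dataclass
class EpochSeries:
    """MAD values on a contiguous midnight-anchored epoch grid.

    ``mad`` is NaN wherever the epoch is excluded (too few samples);
    ``n_samples`` is the H actually available in each epoch.
    """

    participant_id: str
    device_label: str
    epoch_length_s: int
    epoch_start: pd.DatetimeIndex
    mad: np.ndarray
    n_samples: np.ndarray

    def __len__(self) -> int:
        return len(self.epoch_start)

    def to_frame(self) -> pd.DataFrame:
        """Persistable long form: participant,device,epoch_start,epoch_s,mad_g,n_samples."""
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "device": self.device_label,
                "epoch_start": self.epoch_start,
                "epoch_s": self.epoch_length_s,
                "mad_g": self.mad,
                "n_samples": self.n_samples,
            }
        )


@dataclasses.dataclass
class PairedEpochSeries:
    """Time-synchronized epoch MADs from the reference (hip) and test (chest)
    devices, restricted to epochs observed by both and jointly worn."""

    participant_id: str
    epoch_length_s: int
    epoch_start: pd.DatetimeIndex
    mad_a: np.ndarray  # reference device (hip)
    mad_b: np.ndarray  # test device (chest)

    def __len__(self) -> int:
        return len(self.epoch_start)

    def select(self, keep: np.ndarray) -> "PairedEpochSeries":
        """Subset by boolean mask (used e.g. to keep valid-day epochs)."""
        return PairedEpochSeries(
            self.participant_id,
            self.epoch_length_s,
            self.epoch_start[keep],
            self.mad_a[keep],
            self.mad_b[keep],
        )


def vector_magnitude(rec: RawAccelRecording) -> VectorMagnitudeSeries:
    """Collapse a tri-axial recording into per-sample vector magnitudes."""
    values = np.sqrt(rec.x * rec.x + rec.y * rec.y + rec.z * rec.z)
    return VectorMagnitudeSeries(
        participant_id=rec.participant_id,
        device_label=rec.device.label,
        start_time=rec.start_time,
        sampling_rate_hz=rec.device.sampling_rate_hz,
        values=values,
    )


def segment_starts(n: int, fs: float, offset_s: float, segment_s: float) -> tuple[int, np.ndarray]:
    """Start indices of the grid segments covering ``n`` regular samples.

    Sample ``i`` lives at ``offset_s + i / fs`` and belongs to the half-open
    segment ``[k * segment_s, (k+1) * segment_s)``. Returns the first segment
    index ``k0`` and, for every segment from ``k0`` through the one holding
    the last sample, the index of its first sample (contiguous partition:
    segment ``j`` spans ``starts[j]:starts[j+1]``, the last one to ``n``).
    """
    k0 = int(offset_s // segment_s)
    k_last = int((offset_s + (n - 1) / fs) // segment_s)
    j = np.arange(1, k_last - k0 + 1, dtype=np.float64)
    bounds = np.ceil(((k0 + j) * segment_s - offset_s) * fs).astype(np.int64)
    starts = np.concatenate(([0], np.clip(bounds, 0, n - 1)))
    return k0, starts


def epoch_mad(
    vm: VectorMagnitudeSeries,
    epoch_length_s: int,
    min_fraction: float = 0.9,
) -> EpochSeries:
    """Mean amplitude deviation per epoch on the midnight-anchored grid.

    Parameters
    ----------
    vm
        Vector-magnitude series at the device's native rate.
    epoch_length_s
        Epoch length L in seconds; must be a positive multiple of 60.
    min_fraction
        Minimum fraction of the nominal ``L * fs`` samples an epoch needs
        to be reported (otherwise its MAD is NaN).
    """
    L = int(epoch_length_s)
    if L <= 0 or L % 60 != 0:
        raise ConfigError(f"epoch_length_s must be a positive multiple of 60, got {epoch_length_s}")
    if not 0 < min_fraction <= 1:
        raise ConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n = vm.values.size
    if n == 0:
        raise ValueError("cannot epoch an empty series")
    values = np.asarray(vm.values, dtype=np.float64)

    midnight = vm.start_time.normalize()
    off0 = (vm.start_time - midnight).total_seconds()
    k0, starts = segment_starts(n, vm.sampling_rate_hz, off0, L)
    n_epochs = starts.size
    counts = np.diff(np.concatenate((starts, [n])))

    sums = np.add.reduceat(values, starts)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        deviations = np.abs(values - np.repeat(means, counts))
        mad = np.add.reduceat(deviations, starts) / counts
    required = min_fraction * L * vm.sampling_rate_hz
    mad[counts < required] = np.nan

    epoch_start = midnight + pd.to_timedelta((k0 + np.arange(n_epochs)) * L, unit="s")
    return EpochSeries(
        participant_id=vm.participant_id,
        device_label=vm.device_label,
        epoch_length_s=L,
        epoch_start=pd.DatetimeIndex(epoch_start),
        mad=mad,
        n_samples=counts.astype(np.int64),
    )


def _epochs_fully_worn(epoch_keys: np.ndarray, epoch_length_s: int, mask: "NonwearMask") -> np.ndarray:
    """True where every minute of the epoch is worn according to ``mask``.

    ``epoch_keys`` are epoch starts expressed in integer epochs-since-1970;
    minutes outside the mask's span count as not worn.
    """
    q = epoch_length_s // 60
    wear = mask.wear.astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(wear)))
    mask_key0 = mask.start_minute.value // (60 * _NS_PER_S)
    lo = epoch_keys * q - mask_key0
    hi = lo + q
    inside = (lo >= 0) & (hi <= wear.size)
    lo_c = np.clip(lo, 0, wear.size)
    hi_c = np.clip(hi, 0, wear.size)
    return inside & (cum[hi_c] - cum[lo_c] == q)


def align_epoch_grids(
    a: EpochSeries,
    b: EpochSeries,
    joint_wear: "NonwearMask",
) -> PairedEpochSeries:
    """Inner-join two devices' epoch grids on epoch start timestamps.

    Epochs missing in either series, or containing any minute that is not
    jointly worn, are dropped (counts logged per reason). The first series is
    the reference (hip) device.
    """
    if a.epoch_length_s != b.epoch_length_s:
        raise ConfigError(
            f"mismatched epoch lengths: {a.epoch_length_s} vs {b.epoch_length_s}"
        )
    if a.participant_id != b.participant_id:
        raise ValueError("paired series must belong to the same participant")
    L = a.epoch_length_s
    key_a = a.epoch_start.asi8 // (L * _NS_PER_S)
    key_b = b.epoch_start.asi8 // (L * _NS_PER_S)
    common, ia, ib = np.intersect1d(key_a, key_b, return_indices=True)

    mad_a = a.mad[ia]
    mad_b = b.mad[ib]
    present = ~np.isnan(mad_a) & ~np.isnan(mad_b)
    worn = _epochs_fully_worn(common, L, joint_wear)
    keep = present & worn
    logger.info(
        "align %s L=%ds: %d common epochs, dropped %d missing, %d not jointly worn",
        a.participant_id,
        L,
        common.size,
        int(np.sum(~present)),
        int(np.sum(present & ~worn)),
    )
    return PairedEpochSeries(
        participant_id=a.participant_id,
        epoch_length_s=L,
        epoch_start=a.epoch_start[ia[keep]],
        mad_a=mad_a[keep],
        mad_b=mad_b[keep],
    )
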