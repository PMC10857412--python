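"""Synthetic paired-device cohorts with known ground truth.

Real paired chest-patch / hip-accelerometer cohort data are access-restricted,
so every pipeline stage is exercised on simulated recordings that emulate the
measurement chain the two devices share and the ways they differ:

* a **shared latent activity-intensity profile** λ(t) at minute resolution —
  a sedentary floor plus randomly seeded activity bouts whose rate follows a
  diurnal envelope (most active 08:00–14:00, quiet overnight);
* **device-specific rendering**: per-sample motion is a band-limited
  oscillation (three walking-like components in 1–3 Hz, shared between
  devices because they ride on the same body) with amplitude γ·λ(t), directed
  along the gravity axis, plus white sensor noise, sampled at each device's
  native rate under a per-device quartz clock drift (ppm scale) and passed
  through the device's quantizer.  The chest patch therefore genuinely
  undersamples the motion (1.56 Hz vs a 1–3 Hz signal) and carries coarser
  quantization, while epoch-level MAD remains comparable;
* **scheduled non-wear**: the hip device is removed overnight (23:00–07:00 by
  default, emulating a waking-hours protocol), the chest patch is worn
  continuously.  During non-wear the signal is the constant gravity vector
  plus noise below one code step;
* an **ECG** at 199.8 Hz whose biphasic R-wave train (1 mV, ~0.1 s wide)
  guarantees that during wear well over 2% of each minute's samples deviate
  by ≥ 0.1 mV from the 2-s moving average, and whose non-wear baseline noise
  stays far below that threshold.

All randomness flows from a single integer seed through named per-participant
generator streams, so cohorts are bit-reproducible.  Generation is lazy: a
cohort holds only the cheap ground-truth records and renders each
participant's (large) raw signals on demand; ``SyntheticCohort.write``
persists everything in the text dialects of :mod:`madwear.device_io`.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .device_io import (
    CHEST_PATCH,
    HIP_ACTIGRAPH,
    DeviceSpec,
    EcgSeries,
    RawAccelRecording,
    quantize,
    write_actigraph_csv,
    write_ecg_csv,
    write_zacl,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Unit gravity direction in each device's own axis frame. Motion is modelled
#: along the gravity axis (dominant vertical component of ambulation), which
#: keeps the vector magnitude response linear in the motion amplitude.
GRAVITY_AXIS = {"chest": (1.0, 0.0, 0.0), "hip": (0.0, 0.0, 1.0)}

_STREAM_TRUTH, _STREAM_CHEST, _STREAM_HIP, _STREAM_ECG = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class SynthDeviceParams:
    """Per-device rendering parameters for one synthetic participant."""

    spec: DeviceSpec
    gain: float           # placement gain γ on the shared motion amplitude
    noise_sd_g: float     # white sensor noise during wear
    nonwear_noise_sd_g: float  # residual noise while off-body (< 1 code step)
    drift_ppm: float      # quartz clock drift
    stream: int           # rng stream id for this device's noise


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic cohort (defaults = the emulated study).

    20 participants wear both devices for 5 days starting 07:00 local time;
    the hip device is removed 23:00–07:00, the chest patch never. Amplitudes
    are in g: a 0.01 g sedentary floor and activity bouts peaking at 0.15 g
    put typical epoch MADs in the 0.005–0.1 g range of free-living data.
    """

    n_participants: int = 20
    n_days: int = 5
    start: str = "2016-07-01 07:00:00"
    chest_spec: DeviceSpec = CHEST_PATCH
    hip_spec: DeviceSpec = HIP_ACTIGRAPH
    chest_gain: float = 0.95
    hip_gain: float = 1.0
    chest_noise_sd_g: float = 0.005
    hip_noise_sd_g: float = 0.003
    nonwear_noise_sd_g: float = 0.0005
    drift_ppm_sd: float = 10.0
    sedentary_floor_g: float = 0.01
    bout_peak_g: float = 0.15
    bout_rate_per_hour: float = 2.0
    bout_mean_minutes: float = 10.0
    intensity_cap_g: float = 0.3
    hip_off_start: datetime.time = datetime.time(23, 0)
    hip_off_end: datetime.time = datetime.time(7, 0)
    ecg_fs_hz: float = 199.8
    heart_rate_mean_bpm: float = 70.0
    heart_rate_sd_bpm: float = 5.0
    r_wave_mv: float = 1.0
    r_wave_width_s: float = 0.1
    ecg_noise_sd_mv: float = 0.002

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ConfigError("cohort needs at least one participant and one day")
        for name in ("sedentary_floor_g", "bout_peak_g", "bout_rate_per_hour",
                     "bout_mean_minutes", "intensity_cap_g", "ecg_fs_hz"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown synth config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("hip_off_start", "hip_off_end"):
            if key in data and isinstance(data[key], str):
                data[key] = datetime.time.fromisoformat(data[key])
        for key in ("chest_spec", "hip_spec"):
            if key in data and isinstance(data[key], dict):
                data[key] = DeviceSpec(**data[key])
        return cls(**data)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests: the latent profile, wear
    schedule and device parameters behind one participant's recordings."""

    participant_id: str
    index: int
    seed: int
    start_time: pd.Timestamp
    n_days: int
    lam: np.ndarray                      # λ(t), g per minute, ≥ 0
    osc_freqs: np.ndarray                # Hz, shared motion components
    osc_phases: np.ndarray
    osc_weights: np.ndarray              # scaled to unit oscillation variance
    wear_s: dict                         # label -> [(start_s, end_s), ...]
    devices: dict                        # label -> SynthDeviceParams
    heart_rate_bpm: float
    ecg_fs_hz: float
    r_wave_mv: float
    r_wave_width_s: float
    ecg_noise_sd_mv: float

    @property
    def span_s(self) -> float:
        return self.n_days * 86400.0

    def expected_wear(self, minutes: pd.DatetimeIndex, label: str) -> np.ndarray:
        """Scheduled wear status of each minute (by its start instant)."""
        offsets = (minutes - self.start_time).total_seconds().to_numpy()
        return _worn_at(offsets, self.wear_s[label])

    def to_json_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "index": self.index,
            "seed": self.seed,
            "start_time": self.start_time.isoformat(),
            "n_days": self.n_days,
            "lam_g": [round(float(v), 6) for v in self.lam],
            "osc_freqs_hz": self.osc_freqs.tolist(),
            "osc_phases_rad": self.osc_phases.tolist(),
            "osc_weights": self.osc_weights.tolist(),
            "wear_s": {k: [[float(s), float(e)] for s, e in v] for k, v in self.wear_s.items()},
            "devices": {
                k: {
                    "label": d.spec.label,
                    "sampling_rate_hz": d.spec.sampling_rate_hz,
                    "bit_depth": d.spec.bit_depth,
                    "dynamic_range_g": d.spec.dynamic_range_g,
                    "placement": d.spec.placement,
                    "gain": d.gain,
                    "noise_sd_g": d.noise_sd_g,
                    "nonwear_noise_sd_g": d.nonwear_noise_sd_g,
                    "drift_ppm": d.drift_ppm,
                }
                for k, d in self.devices.items()
            },
            "heart_rate_bpm": self.heart_rate_bpm,
            "ecg_fs_hz": self.ecg_fs_hz,
        }


@dataclasses.dataclass
class ParticipantBundle:
    """One rendered participant: both recordings, the ECG and the truth."""

    participant_id: str
    truth: SyntheticTruth
    chest: RawAccelRecording
    hip: RawAccelRecording
    ecg: EcgSeries


def _quantize_inplace(signal: np.ndarray, spec: DeviceSpec) -> np.ndarray:
    """In-place float32 equivalent of :func:`madwear.device_io.quantize`.

    Codes (≤ 2^16) and code grids are exactly representable in float32, so
    round/clip/rescale in the signal's own dtype gives the same grid values
    as the reference implementation.
    """
    res = 2.0 * spec.dynamic_range_g / spec.n_levels
    half = spec.n_levels // 2
    signal *= np.float32(1.0 / res)
    np.rint(signal, out=signal)
    np.clip(signal, -half, half - 1, out=signal)
    signal *= np.float32(res)
    return signal


def _worn_at(t: np.ndarray, intervals: list) -> np.ndarray:
    """Vectorised membership of offset-seconds ``t`` in wear intervals."""
    if not intervals:
        return np.zeros(np.shape(t), dtype=bool)
    edges = np.array([edge for pair in intervals for edge in pair], dtype=np.float64)
    return np.searchsorted(edges, t, side="right") % 2 == 1


def _daily_wear_intervals(
    start: pd.Timestamp, n_days: int, off_start: datetime.time | None, off_end: datetime.time | None
) -> list:
    """Wear intervals (offset seconds) for a daily removal window; continuous
    wear when the window is absent."""
    span = n_days * 86400.0
    if off_start is None or off_end is None:
        return [(0.0, span)]
    n_minutes = n_days * 1440
    minute_offsets = np.arange(n_minutes, dtype=np.float64) * 60.0
    clock = ((start - start.normalize()).total_seconds() + minute_offsets) % 86400.0
    o0 = off_start.hour * 3600 + off_start.minute * 60
    o1 = off_end.hour * 3600 + off_end.minute * 60
    if o0 <= o1:
        off = (clock >= o0) & (clock < o1)
    else:  # wraps midnight, e.g. 23:00–07:00
        off = (clock >= o0) | (clock < o1)
    worn = ~off
    edges = np.diff(np.concatenate(([0], worn.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(float(s * 60.0), float(min(e * 60.0, span))) for s, e in zip(starts, ends)]


def latent_intensity_profile(
    n_minutes: int,
    start_minute_of_day: int,
    rng: np.random.Generator,
    floor_g: float = 0.01,
    peak_g: float = 0.15,
    bout_rate_per_hour: float = 2.0,
    bout_mean_minutes: float = 10.0,
    cap_g: float = 0.3,
) -> np.ndarray:
    """Minute-resolution latent motion amplitude λ(t) ≥ 0 (g).

    A sedentary floor plus Poisson-seeded activity bouts (geometric
    durations, uniform amplitudes up to ``peak_g``) whose start rate follows
    a diurnal envelope: full rate 08:00–14:00, 40% through the rest of the
    day, 5% overnight (22:00–06:00). Deterministic given the generator state.
    """
    if floor_g < 0 or peak_g < 0 or bout_rate_per_hour < 0:
        raise ConfigError("intensity parameters must be non-negative")
    hour = (((start_minute_of_day + np.arange(n_minutes)) % 1440) / 60.0)
    envelope = np.where((hour < 6) | (hour >= 22), 0.05, np.where((hour >= 8) & (hour < 14), 1.0, 0.4))
    p_start = bout_rate_per_hour / 60.0 * envelope
    starts = np.flatnonzero(rng.random(n_minutes) < p_start)
    lam = np.full(n_minutes, float(floor_g))
    for idx in starts:
        duration = int(rng.geometric(1.0 / bout_mean_minutes)) if bout_mean_minutes > 0 else 1
        amplitude = float(peak_g * rng.uniform(0.3, 1.0))
        lam[idx: idx + duration] += amplitude
    return np.clip(lam, 0.0, cap_g)


def _make_truth(config: SynthConfig, seed: int, index: int) -> SyntheticTruth:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, _STREAM_TRUTH)))
    start = pd.Timestamp(config.start)
    n_minutes = config.n_days * 1440
    lam = latent_intensity_profile(
        n_minutes,
        int((start - start.normalize()).total_seconds() // 60),
        rng,
        floor_g=config.sedentary_floor_g,
        peak_g=config.bout_peak_g,
        bout_rate_per_hour=config.bout_rate_per_hour,
        bout_mean_minutes=config.bout_mean_minutes,
        cap_g=config.intensity_cap_g,
    )
    freqs = rng.uniform(1.0, 3.0, size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    weights = rng.uniform(0.5, 1.0, size=3)
    weights = weights / np.sqrt(np.sum(weights**2) / 2.0)  # unit oscillation SD
    drift_chest, drift_hip = rng.normal(0.0, config.drift_ppm_sd, size=2)
    heart_rate = float(max(45.0, rng.normal(config.heart_rate_mean_bpm, config.heart_rate_sd_bpm)))
    span = config.n_days * 86400.0
    wear = {
        config.chest_spec.label: [(0.0, span)],
        config.hip_spec.label: _daily_wear_intervals(
            start, config.n_days, config.hip_off_start, config.hip_off_end
        ),
    }
    devices = {
        config.chest_spec.label: SynthDeviceParams(
            config.chest_spec, config.chest_gain, config.chest_noise_sd_g,
            config.nonwear_noise_sd_g, float(drift_chest), _STREAM_CHEST,
        ),
        config.hip_spec.label: SynthDeviceParams(
            config.hip_spec, config.hip_gain, config.hip_noise_sd_g,
            config.nonwear_noise_sd_g, float(drift_hip), _STREAM_HIP,
        ),
    }
    return SyntheticTruth(
        participant_id=f"P{index + 1:03d}",
        index=index,
        seed=seed,
        start_time=start,
        n_days=config.n_days,
        lam=lam,
        osc_freqs=freqs,
        osc_phases=phases,
        osc_weights=weights,
        wear_s=wear,
        devices=devices,
        heart_rate_bpm=heart_rate,
        ecg_fs_hz=config.ecg_fs_hz,
        r_wave_mv=config.r_wave_mv,
        r_wave_width_s=config.r_wave_width_s,
        ecg_noise_sd_mv=config.ecg_noise_sd_mv,
    )


def render_accel(truth: SyntheticTruth, label: str) -> RawAccelRecording:
    """Render one device's quantized tri-axial recording from the truth.

    Per axis: the static gravity component plus motion of amplitude
    γ·λ(t) along the gravity axis plus white noise, evaluated at the
    device's drifted sample times and snapped to its code grid. During
    scheduled non-wear the motion term is zero and the noise drops below
    one code step.
    """
    dev: SynthDeviceParams = truth.devices[label]
    spec = dev.spec
    n = int(round(truth.span_s * spec.sampling_rate_hz))
    t = np.arange(n, dtype=np.float64)
    t *= (1.0 + dev.drift_ppm * 1e-6) / spec.sampling_rate_hz
    worn = _worn_at(t, truth.wear_s[label])
    minute = np.clip((t * (1.0 / 60.0)).astype(np.int64), 0, truth.lam.size - 1)
    amplitude = (dev.gain * truth.lam)[minute]
    amplitude[~worn] = 0.0
    del minute
    motion = np.zeros(n)
    for f, ph, w in zip(truth.osc_freqs, truth.osc_phases, truth.osc_weights):
        motion += w * np.sin((2.0 * np.pi * f) * t + ph)
    del t
    motion *= amplitude
    del amplitude
    motion = motion.astype(np.float32)
    noise_sd = np.where(worn, np.float32(dev.noise_sd_g), np.float32(dev.nonwear_noise_sd_g))
    del worn
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.seed, spawn_key=(truth.index, dev.stream))
    )
    gravity = GRAVITY_AXIS[spec.placement]
    axes = []
    for component in gravity:
        signal = rng.standard_normal(n, dtype=np.float32)
        signal *= noise_sd
        if component != 0.0:
            signal += np.float32(component)
            signal += np.float32(component) * motion
        axes.append(_quantize_inplace(signal, spec))
    return RawAccelRecording(
        participant_id=truth.participant_id,
        device=spec,
        start_time=truth.start_time,
        x=axes[0],
        y=axes[1],
        z=axes[2],
    )


def render_ecg(truth: SyntheticTruth, fs: float | None = None) -> EcgSeries:
    """Render the chest patch's ECG: a biphasic R-wave train during wear
    (±``r_wave_mv`` pulses of ``r_wave_width_s`` at the scheduled heart
    rate) over a near-zero noisy baseline; baseline only during non-wear."""
    fs = float(fs if fs is not None else truth.ecg_fs_hz)
    chest_label = next(k for k, d in truth.devices.items() if d.spec.placement == "chest")
    dev = truth.devices[chest_label]
    n = int(round(truth.span_s * fs))
    drift_factor = 1.0 + dev.drift_ppm * 1e-6
    beat_hz = truth.heart_rate_bpm / 60.0
    intervals = truth.wear_s[chest_label]
    continuous = intervals == [(0.0, truth.span_s)]

    phase = np.arange(n, dtype=np.float64)
    phase *= drift_factor * beat_hz / fs  # beat phase at each (drifted) sample time
    if not continuous:
        worn = _worn_at(phase * (1.0 / beat_hz), intervals)
    np.mod(phase, 1.0, out=phase)
    half_width = 0.5 * truth.r_wave_width_s * beat_hz  # half pulse, in beat-phase units
    positive = phase < half_width
    negative = (phase < 2.0 * half_width) & ~positive
    del phase
    values = positive.astype(np.float32)
    values -= negative
    values *= np.float32(truth.r_wave_mv)
    del positive, negative
    if not continuous:
        values *= worn
        del worn
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.seed, spawn_key=(truth.index, _STREAM_ECG))
    )
    noise = rng.standard_normal(n, dtype=np.float32)
    noise *= np.float32(truth.ecg_noise_sd_mv)
    values += noise
    del noise
    return EcgSeries(
        participant_id=truth.participant_id,
        start_time=truth.start_time,
        sampling_rate_hz=fs,
        values=values,
    )


@dataclasses.dataclass
class SyntheticCohort:
    """A lazily rendered cohort: ground truths plus render-on-demand."""

    config: SynthConfig
    seed: int
    truths: list

    @property
    def participant_ids(self) -> list:
        return [t.participant_id for t in self.truths]

    def render(self, index: int) -> ParticipantBundle:
        truth = self.truths[index]
        return ParticipantBundle(
            participant_id=truth.participant_id,
            truth=truth,
            chest=render_accel(truth, self.config.chest_spec.label),
            hip=render_accel(truth, self.config.hip_spec.label),
            ecg=render_ecg(truth),
        )

    def providers(self) -> list:
        """(participant_id, loader) pairs for :func:`madwear.pipeline.run_pipeline`."""
        return [
            (truth.participant_id, (lambda i=i: self.render(i)))
            for i, truth in enumerate(self.truths)
        ]

    def write(self, out_dir: str | Path) -> None:
        """Persist every participant in the text dialects plus truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, truth in enumerate(self.truths):
            pdir = out / truth.participant_id
            pdir.mkdir(exist_ok=True)
            bundle = self.render(i)
            write_zacl(bundle.chest, pdir / "accel.zacl", pdir / "accel.hea")
            write_actigraph_csv(bundle.hip, pdir / "hip.csv")
            write_ecg_csv(bundle.ecg, pdir / "ecg.csv")
            (pdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
            logger.info("wrote synthetic participant %s (%s dir)", truth.participant_id, pdir)


def simulate_cohort(config: SynthConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Deterministically generate a cohort's ground truths (lazy rendering)."""
    config = config or SynthConfig()
    truths = [_make_truth(config, seed, i) for i in range(config.n_participants)]
    return SyntheticCohort(config=config, seed=seed, truths=truths)


def schedule_recovery(truth: SyntheticTruth, masks: dict) -> float:
    """Fraction of minutes whose detected wear label matches the schedule.

    ``masks`` maps device label -> detected :class:`NonwearMask`; minutes are
    compared over each mask's own span.
    """
    total = 0
    agree = 0
    for label, mask in masks.items():
        if label not in truth.wear_s:
            raise KeyError(f"no schedule for device {label!r}")
        expected = truth.expected_wear(mask.minutes, label)
        total += len(mask)
        agree += int(np.sum(expected == mask.wear))
    if total == 0:
        return float("nan")
    return agree / total
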