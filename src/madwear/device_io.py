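"""Device definitions and file I/O for the two accelerometer dialects.

The pipeline compares two body-worn tri-axial MEMS accelerometers that store
data very differently:

* a chest-worn ECG patch (Zio-XT-style) that samples at ~1.56 Hz per axis and
  stores each sample as an 8-bit unsigned integer over a ±2 g dynamic range,
  interleaved as x,y,z "trifectas" in a raw binary ``.zacl`` stream with a
  companion ``.hea`` text header carrying the start/finish timestamps;
* a hip-worn research accelerometer (ActiGraph-style) sampling at 40 Hz per
  axis with 12-bit codes over ±8 g, exchanged here as a raw CSV dialect.

This module owns the quantization arithmetic for both devices: a ``b``-bit
sensor with dynamic range ±R g has 2^b representable levels and a resolution
of 2R / 2^b g per level (0.00390625 g for the 12-bit ±8 g device, 0.015625 g
for the 8-bit ±2 g patch).

Byte-to-g convention: codes are offset binary with zero g at code 2^(b-1),
i.e. ``g = (code - 2^(b-1)) * 2R/2^b``.  The representable range is therefore
[-R, R - resolution]; encoding clips out-of-range samples to the extreme
codes (logged).  The zero offset is a convention of this package, centralised
in :func:`code_to_g` / :func:`g_to_code` so an alternative (e.g. mid-rise at
2^(b-1) - 0.5) is a one-line change.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import HeaderError, MalformedPayloadError, ParseError

logger = logging.getLogger(__name__)

#: Nominal sampling rate of the chest patch accelerometer (Hz per axis),
#: used when the header omits an explicit ``fs_accel`` line.
DEFAULT_PATCH_RATE_HZ = 1.56

_PLACEMENTS = ("chest", "hip")


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype == np.float32:
        return arr
    return arr.astype(np.float64, copy=False)


@dataclasses.dataclass(frozen=True)
class DeviceSpec:
    """Static description of an accelerometer's sampling and coding.

    Parameters
    ----------
    label
        Short device identifier (used in output tables and masks).
    sampling_rate_hz
        Samples per second per axis; must be positive.
    bit_depth
        Bits per stored sample (1..16); the device represents 2**bit_depth
        discrete acceleration levels.
    dynamic_range_g
        Half range R: accelerations are representable on (approximately)
        [-R, +R] g.
    placement
        Body location, ``"chest"`` or ``"hip"``.
    """

    label: str
    sampling_rate_hz: float
    bit_depth: int
    dynamic_range_g: float
    placement: str

    def __post_init__(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if not 1 <= int(self.bit_depth) <= 16:
            raise ValueError(f"bit_depth must be in 1..16, got {self.bit_depth}")
        if not self.dynamic_range_g > 0:
            raise ValueError(f"dynamic_range_g must be > 0, got {self.dynamic_range_g}")
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"placement must be one of {_PLACEMENTS}, got {self.placement!r}")

    @property
    def n_levels(self) -> int:
        """Number of representable code levels (2**bit_depth)."""
        return 2 ** int(self.bit_depth)


#: Chest ECG patch accelerometer: ~1.56 Hz/axis, 8-bit codes, ±2 g.
CHEST_PATCH = DeviceSpec("zio", DEFAULT_PATCH_RATE_HZ, 8, 2.0, "chest")

#: Hip research accelerometer: 40 Hz/axis, 12-bit codes, ±8 g.
HIP_ACTIGRAPH = DeviceSpec("actigraph", 40.0, 12, 8.0, "hip")


# ---------------------------------------------------------------------------
# Quantization arithmetic
# ---------------------------------------------------------------------------

def quantization_resolution(spec: DeviceSpec) -> float:
    """g per code level: full range divided by level count, 2R / 2**bits."""
    return 2.0 * spec.dynamic_range_g / spec.n_levels


def code_to_g(codes: np.ndarray, spec: DeviceSpec) -> np.ndarray:
    """Map integer codes to accelerations in g (offset-binary convention)."""
    zero = spec.n_levels // 2
    return (np.asarray(codes, dtype=np.float64) - zero) * quantization_resolution(spec)


def g_to_code(values: np.ndarray, spec: DeviceSpec) -> np.ndarray:
    """Map accelerations in g to the nearest integer code, clipped to range.

    Returns int codes in [0, 2**bits - 1]; clipping is silent here — callers
    that promise in-range data (e.g. :func:`encode_zacl`) log it.
    """
    zero = spec.n_levels // 2
    res = quantization_resolution(spec)
    codes = np.rint(np.asarray(values, dtype=np.float64) / res) + zero
    return np.clip(codes, 0, spec.n_levels - 1).astype(np.int64)


def quantize(values: np.ndarray, spec: DeviceSpec) -> np.ndarray:
    """Snap accelerations to the device's code grid (round then clip).

    Idempotent; for inputs within [-R, R - resolution] the error is at most
    half a resolution step.
    """
    return code_to_g(g_to_code(values, spec), spec)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RawAccelRecording:
    """Timestamped tri-axial acceleration in g for one device wear period.

    Sample ``i`` is implicitly timestamped ``start_time + i / sampling_rate``
    on the device's own (timezone-naive, local) clock.
    """

    participant_id: str
    device: DeviceSpec
    start_time: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tz is not None:
            raise ValueError("start_time must be timezone-naive local time")
        # float32 is preserved (large recordings); everything else → float64
        self.x = _as_float_array(self.x)
        self.y = _as_float_array(self.y)
        self.z = _as_float_array(self.z)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise ValueError("x, y, z must be equal-length 1-D sequences")
        r = self.device.dynamic_range_g
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            if axis.size and (np.min(axis) < -r or np.max(axis) > r):
                raise ValueError(f"axis {name} has samples outside ±{r} g")

    @property
    def n_samples(self) -> int:
        return int(self.x.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.device.sampling_rate_hz

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.to_timedelta(self.duration_s, unit="s")


@dataclasses.dataclass
class EcgSeries:
    """Single-lead ECG in millivolts on a regular sample grid."""

    participant_id: str
    start_time: pd.Timestamp
    sampling_rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        self.values = _as_float_array(self.values)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("ECG values must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)


@dataclasses.dataclass
class ZaclPayload:
    """Raw byte stream of x,y,z trifectas plus its parsed text header."""

    raw_bytes: np.ndarray
    header: Mapping[str, object]

    def __post_init__(self) -> None:
        self.raw_bytes = np.asarray(self.raw_bytes)
        if self.raw_bytes.dtype != np.uint8:
            if self.raw_bytes.size and (
                np.min(self.raw_bytes) < 0 or np.max(self.raw_bytes) > 255
            ):
                raise ValueError("raw_bytes must be 8-bit unsigned (0..255)")
            self.raw_bytes = self.raw_bytes.astype(np.uint8)
        if self.raw_bytes.size % 3 != 0:
            raise MalformedPayloadError(
                f"payload length {self.raw_bytes.size} is not a multiple of 3 "
                "(incomplete x,y,z trifecta)"
            )


# ---------------------------------------------------------------------------
# zacl binary dialect + hea header
# ---------------------------------------------------------------------------

def parse_header(text: str) -> dict:
    """Parse a ``.hea`` companion header.

    The dialect is one ``key value`` pair per line: ``start <ISO-8601>``,
    ``finish <ISO-8601>`` and an optional ``fs_accel <Hz>`` (defaulting to
    the nominal patch rate of 1.56 Hz, with a warning). Unknown keys are
    preserved verbatim.
    """
    fields: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"header line {lineno} is not 'key value': {line!r}")
        key, value = parts
        fields[key] = value

    if "start" not in fields or "finish" not in fields:
        raise HeaderError("header must contain 'start' and 'finish' timestamps")
    out = dict(fields)
    for key in ("start", "finish"):
        try:
            out[key] = pd.Timestamp(fields[key])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"unparseable {key} timestamp {fields[key]!r}") from exc
    if out["finish"] < out["start"]:
        raise HeaderError(f"finish {out['finish']} precedes start {out['start']}")
    if "fs_accel" in fields:
        try:
            out["sampling_rate_hz"] = float(fields["fs_accel"])
        except ValueError as exc:
            raise ParseError(f"unparseable fs_accel {fields['fs_accel']!r}") from exc
    else:
        logger.warning(
            "header has no fs_accel line; assuming nominal %.2f Hz", DEFAULT_PATCH_RATE_HZ
        )
        out["sampling_rate_hz"] = DEFAULT_PATCH_RATE_HZ
    return out


def format_header(start: pd.Timestamp, finish: pd.Timestamp, sampling_rate_hz: float) -> str:
    """Serialize a ``.hea`` header (inverse of :func:`parse_header`)."""
    return (
        f"start {pd.Timestamp(start).isoformat()}\n"
        f"finish {pd.Timestamp(finish).isoformat()}\n"
        f"fs_accel {sampling_rate_hz:g}\n"
    )


def decode_zacl(
    payload: ZaclPayload,
    spec: DeviceSpec = CHEST_PATCH,
    participant_id: str = "",
) -> RawAccelRecording:
    """De-interleave a trifecta byte stream into a tri-axial recording.

    Bytes at indices 0,3,6,... are x; 1,4,7,... are y; 2,5,8,... are z.
    Each byte b maps to g via the offset-binary affine map
    ``g = (b - 128) * 2R/256``.
    """
    if spec.bit_depth != 8:
        raise ValueError("zacl payloads carry 8-bit samples; spec.bit_depth must be 8")
    header = payload.header
    if "start" not in header:
        raise HeaderError("payload header lacks a start timestamp")
    raw = payload.raw_bytes  # multiple-of-3 enforced by ZaclPayload
    g = code_to_g(raw, spec)
    return RawAccelRecording(
        participant_id=participant_id,
        device=spec,
        start_time=pd.Timestamp(header["start"]),
        x=g[0::3],
        y=g[1::3],
        z=g[2::3],
    )


def encode_zacl(recording: RawAccelRecording) -> ZaclPayload:
    """Interleave a recording back into trifecta bytes (inverse of decode).

    Samples are rounded to the nearest 8-bit code and clipped to [0, 255];
    clipping is silent but logged.
    """
    spec = recording.device
    if spec.bit_depth != 8:
        raise ValueError("zacl payloads carry 8-bit samples; device bit_depth must be 8")
    codes = np.empty(3 * recording.n_samples, dtype=np.int64)
    res = quantization_resolution(spec)
    top = spec.dynamic_range_g - res
    n_clipped = 0
    for offset, axis in enumerate((recording.x, recording.y, recording.z)):
        n_clipped += int(np.sum((axis < -spec.dynamic_range_g) | (axis > top)))
        codes[offset::3] = g_to_code(axis, spec)
    if n_clipped:
        logger.warning("encode_zacl clipped %d out-of-range samples", n_clipped)
    header = {
        "start": recording.start_time,
        "finish": recording.end_time,
        "sampling_rate_hz": spec.sampling_rate_hz,
    }
    return ZaclPayload(raw_bytes=codes.astype(np.uint8), header=header)


def read_zacl(
    zacl_path: str | Path,
    hea_path: str | Path,
    spec: DeviceSpec = CHEST_PATCH,
    participant_id: str = "",
) -> RawAccelRecording:
    """Read a ``.zacl`` byte file and its ``.hea`` header from disk."""
    raw = np.fromfile(str(zacl_path), dtype=np.uint8)
    header = parse_header(Path(hea_path).read_text())
    rate = header.get("sampling_rate_hz", DEFAULT_PATCH_RATE_HZ)
    if rate != spec.sampling_rate_hz:
        spec = dataclasses.replace(spec, sampling_rate_hz=float(rate))
    payload = ZaclPayload(raw_bytes=raw, header=header)
    return decode_zacl(payload, spec, participant_id=participant_id)


def write_zacl(recording: RawAccelRecording, zacl_path: str | Path, hea_path: str | Path) -> None:
    """Write a recording as a ``.zacl`` byte file plus ``.hea`` header."""
    payload = encode_zacl(recording)
    payload.raw_bytes.tofile(str(zacl_path))
    Path(hea_path).write_text(
        format_header(
            payload.header["start"], payload.header["finish"], payload.header["sampling_rate_hz"]
        )
    )


# ---------------------------------------------------------------------------
# Raw CSV dialects (hip accelerometer, ECG)
# ---------------------------------------------------------------------------

def _read_hash_header(lines: list[str]) -> tuple[dict, int]:
    """Parse leading ``# key value`` lines; return (fields, first data line)."""
    fields: dict = {}
    i = 0
    for i, line in enumerate(lines):
        line = line.strip()
        if not line.startswith("#"):
            break
        parts = line.lstrip("#").strip().split(None, 1)
        if len(parts) == 2:
            fields[parts[0]] = parts[1]
    return fields, i


def read_actigraph_csv(source: str | Path | io.IOBase, participant_id: str = "") -> RawAccelRecording:
    """Read the hip-device raw CSV dialect.

    Layout: ``# start <ISO>``, ``# fs <Hz>``, ``# range_g <R>``, ``# bits <n>``
    header lines, a ``x,y,z`` column header, then one row per sample in g.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    meta, start_idx = _read_hash_header(lines)
    for key in ("start", "fs", "range_g", "bits"):
        if key not in meta:
            raise HeaderError(f"raw CSV header lacks '# {key}' line")
    try:
        start = pd.Timestamp(meta["start"])
        fs = float(meta["fs"])
        range_g = float(meta["range_g"])
        bits = int(meta["bits"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable raw CSV header: {meta}") from exc
    if start_idx >= len(lines) or lines[start_idx].strip().lower() != "x,y,z":
        raise ParseError("raw CSV must have an 'x,y,z' column header after the metadata block")
    body = "\n".join(lines[start_idx + 1:])
    try:
        frame = pd.read_csv(io.StringIO(body), header=None, names=["x", "y", "z"], dtype=np.float64)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed raw CSV data block: {exc}") from exc
    if frame.isna().any().any():
        raise ParseError("raw CSV has ragged or non-numeric rows")
    spec = DeviceSpec("actigraph", fs, bits, range_g, "hip")
    return RawAccelRecording(
        participant_id=participant_id,
        device=spec,
        start_time=start,
        x=frame["x"].to_numpy(),
        y=frame["y"].to_numpy(),
        z=frame["z"].to_numpy(),
    )


def write_actigraph_csv(recording: RawAccelRecording, target: str | Path | io.IOBase) -> None:
    """Write the hip-device raw CSV dialect (6-decimal g values)."""
    spec = recording.device
    header = (
        f"# start {recording.start_time.isoformat()}\n"
        f"# fs {spec.sampling_rate_hz:g}\n"
        f"# range_g {spec.dynamic_range_g:g}\n"
        f"# bits {spec.bit_depth}\n"
        "x,y,z\n"
    )
    frame = pd.DataFrame({"x": recording.x, "y": recording.y, "z": recording.z})
    body = frame.to_csv(index=False, header=False, float_format="%.6f")
    if isinstance(target, (str, Path)):
        Path(target).write_text(header + body)
    else:
        target.write(header + body)


def read_ecg_csv(source: str | Path | io.IOBase, participant_id: str = "") -> EcgSeries:
    """Read the ECG CSV dialect: ``# start``, ``# fs`` header and a ``mv`` column."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    meta, start_idx = _read_hash_header(lines)
    for key in ("start", "fs"):
        if key not in meta:
            raise HeaderError(f"ECG CSV header lacks '# {key}' line")
    try:
        start = pd.Timestamp(meta["start"])
        fs = float(meta["fs"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable ECG CSV header: {meta}") from exc
    if start_idx >= len(lines) or lines[start_idx].strip().lower() != "mv":
        raise ParseError("ECG CSV must have a 'mv' column header after the metadata block")
    body = "\n".join(lines[start_idx + 1:])
    try:
        values = pd.read_csv(io.StringIO(body), header=None, dtype=np.float64)[0].to_numpy()
    except (pd.errors.ParserError, ValueError, KeyError) as exc:
        raise ParseError(f"malformed ECG CSV data block: {exc}") from exc
    return EcgSeries(participant_id=participant_id, start_time=start, sampling_rate_hz=fs, values=values)


def write_ecg_csv(ecg: EcgSeries, target: str | Path | io.IOBase) -> None:
    """Write the ECG CSV dialect (4-decimal millivolt values)."""
    header = f"# start {ecg.start_time.isoformat()}\n# fs {ecg.sampling_rate_hz:g}\nmv\n"
    body = pd.Series(ecg.values).to_csv(index=False, header=False, float_format="%.4f")
    if isinstance(target, (str, Path)):
        Path(target).write_text(header + body)
    else:
        target.write(header + body)
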