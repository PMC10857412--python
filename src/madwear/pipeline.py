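"""End-to-end orchestration: ingest → VM → non-wear → MAD → pairing → tables.

``run_pipeline`` executes, for every participant and every epoch length, the
full validation procedure:

1. read (or receive) the chest-patch recording + ECG and the hip recording;
2. collapse each recording to vector magnitudes;
3. detect non-wear per device (ECG rule for the chest, 90-min zero-run rule
   on minute MAD for the hip), intersect into a joint wear mask, and apply
   the cohort inclusion filter (≥3 days × ≥10 h joint wear, 07:00–23:00);
4. for each epoch length, compute device-wise MAD, synchronize the two epoch
   grids, drop epochs that are missing, not jointly worn, or not on a valid
   day, and compute participant-level agreement;
5. aggregate cohort summaries, participant-level and pooled Bland–Altman
   results, the 5-min diurnal profile and the cohort flow report, and
   (optionally) write them as CSV tables.

Participants whose input files fail to parse are excluded with a logged
reason and do not stop the run (fault isolation); participants failing the
validity filter are dropped before any agreement computation. Two runs on
identical inputs and configuration produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementResult,
    BlandAltmanResult,
    bland_altman,
    cohort_summary,
    diurnal_profile,
    participant_agreement,
)
from .device_io import (
    EcgSeries,
    RawAccelRecording,
    read_actigraph_csv,
    read_ecg_csv,
    read_zacl,
)
from .epoch_features import EPOCH_LENGTHS_S, align_epoch_grids, epoch_mad, vector_magnitude
from .errors import ConfigError, FormatError
from .nonwear import (
    DEFAULT_ZERO_THRESHOLD_G,
    NonwearMask,
    ValiditySummary,
    actigraph_nonwear,
    ecg_nonwear,
    joint_wear,
    validity_filter,
)

logger = logging.getLogger(__name__)

_CSV_FLOAT_FORMAT = "%.10g"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds and output settings (all study parameters are
    configurable here, never hard-coded downstream)."""

    epoch_lengths_s: tuple = EPOCH_LENGTHS_S
    min_fraction: float = 0.9
    ecg_window_s: float = 2.0
    ecg_threshold_mv: float = 0.1
    ecg_min_active_fraction: float = 0.02
    run_minutes: int = 90
    zero_threshold_g: float = DEFAULT_ZERO_THRESHOLD_G
    min_days: int = 3
    min_hours: float = 10.0
    window_start: datetime.time = datetime.time(7, 0)
    window_end: datetime.time = datetime.time(23, 0)
    min_pairs: int = 10
    r_threshold: float = 0.8
    diurnal_epoch_s: int = 300
    mse_scale: float = 1e6  # table presentation scale for MSE

    def __post_init__(self) -> None:
        for L in self.epoch_lengths_s:
            if L <= 0 or L % 60 != 0:
                raise ConfigError(f"invalid epoch length {L}")
        for name in ("ecg_window_s", "ecg_threshold_mv", "run_minutes", "min_hours", "min_pairs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        data = dict(data)
        if "epoch_lengths_s" in data:
            data["epoch_lengths_s"] = tuple(int(v) for v in data["epoch_lengths_s"])
        for key in ("window_start", "window_end"):
            if key in data and isinstance(data[key], str):
                data[key] = datetime.time.fromisoformat(data[key])
        return cls(**data)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        d["epoch_lengths_s"] = list(self.epoch_lengths_s)
        return d


@dataclasses.dataclass
class ParticipantData:
    """One participant's raw inputs: both recordings plus the ECG."""

    participant_id: str
    chest: RawAccelRecording
    hip: RawAccelRecording
    ecg: EcgSeries


@dataclasses.dataclass
class RunReport:
    """Cohort flow counts, outputs and provenance of one pipeline run."""

    n_candidates: int
    included: list
    excluded: dict                       # participant_id -> reason
    wear_summary: dict                   # mean/sd/min/max valid days
    agreements: dict                     # L -> [AgreementResult]
    summaries: dict                      # L -> CohortSummary
    ba_participant: dict                 # L -> BlandAltmanResult
    ba_pooled: dict                      # L -> BlandAltmanResult
    pooled_pairs: dict                   # L -> (mad_a, mad_b) arrays
    participant_means: dict              # L -> DataFrame participant/mean_a/mean_b
    diurnal: pd.DataFrame | None
    masks: dict                          # participant_id -> {label: NonwearMask}
    validity: dict                       # participant_id -> ValiditySummary
    config: RunConfig
    version: str = __version__
    output_paths: dict = dataclasses.field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def flow_conserved(self) -> bool:
        return self.n_candidates == self.n_included + self.n_excluded


def load_participants(in_dir: str | Path) -> list:
    """Discover the ``<pid>/accel.zacl|accel.hea|hip.csv|ecg.csv`` layout.

    Returns lazy ``(participant_id, loader)`` providers so one corrupt file
    only excludes its own participant.
    """
    root = Path(in_dir)
    providers = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        pid = pdir.name

        def loader(pdir: Path = pdir, pid: str = pid) -> ParticipantData:
            return ParticipantData(
                participant_id=pid,
                chest=read_zacl(pdir / "accel.zacl", pdir / "accel.hea", participant_id=pid),
                hip=read_actigraph_csv(pdir / "hip.csv", participant_id=pid),
                ecg=read_ecg_csv(pdir / "ecg.csv", participant_id=pid),
            )

        providers.append((pid, loader))
    return providers


def _process_participant(data: ParticipantData, config: RunConfig):
    """Stages 2–3 for one participant: VM, masks, joint wear, validity."""
    vm_hip = vector_magnitude(data.hip)
    vm_chest = vector_magnitude(data.chest)
    minute_mad = epoch_mad(vm_hip, 60, config.min_fraction)
    hip_mask = actigraph_nonwear(minute_mad, config.run_minutes, config.zero_threshold_g)
    chest_mask = ecg_nonwear(
        data.ecg,
        config.ecg_window_s,
        config.ecg_threshold_mv,
        config.ecg_min_active_fraction,
        device_label=data.chest.device.label,
    )
    joint = joint_wear(hip_mask, chest_mask)
    validity = validity_filter(
        joint, config.min_days, config.min_hours, (config.window_start, config.window_end)
    )
    return vm_hip, vm_chest, hip_mask, chest_mask, joint, validity


def summarize_wear(validity: dict, included: Sequence[str]) -> dict:
    """Mean/SD/min/max of valid days across included participants."""
    days = np.array([validity[pid].n_valid_days for pid in included], dtype=np.float64)
    if days.size == 0:
        return {"n": 0, "mean_days": float("nan"), "sd_days": float("nan"),
                "min_days": float("nan"), "max_days": float("nan")}
    return {
        "n": int(days.size),
        "mean_days": float(np.mean(days)),
        "sd_days": float(np.std(days, ddof=1)) if days.size > 1 else 0.0,
        "min_days": float(np.min(days)),
        "max_days": float(np.max(days)),
    }


def run_pipeline(
    providers: Iterable,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run the full validation on lazily loaded participants.

    ``providers`` is an iterable of ``(participant_id, loader)`` pairs (see
    :func:`load_participants` or ``SyntheticCohort.providers``); loaders may
    also return any object with ``participant_id/chest/hip/ecg`` attributes.
    """
    config = config or RunConfig()
    providers = list(providers)
    included: list = []
    excluded: dict = {}
    masks: dict = {}
    validity_all: dict = {}
    agreements: dict = {L: [] for L in config.epoch_lengths_s}
    pooled: dict = {L: ([], []) for L in config.epoch_lengths_s}
    part_means: dict = {L: [] for L in config.epoch_lengths_s}
    diurnal_parts: list = []

    for pid, loader in providers:
        try:
            data = loader()
        except FormatError as exc:
            logger.warning("participant %s excluded: unreadable input (%s)", pid, exc)
            excluded[pid] = f"parse-error: {exc}"
            continue
        vm_hip, vm_chest, hip_mask, chest_mask, joint, validity = _process_participant(data, config)
        masks[pid] = {hip_mask.device_label: hip_mask, chest_mask.device_label: chest_mask,
                      "joint": joint}
        validity_all[pid] = validity
        if not validity.included:
            excluded[pid] = f"validity: {validity.n_valid_days} valid days < {config.min_days}"
            continue
        included.append(pid)
        valid_days = pd.DatetimeIndex(validity.valid_days)

        for L in config.epoch_lengths_s:
            series_hip = epoch_mad(vm_hip, L, config.min_fraction)
            series_chest = epoch_mad(vm_chest, L, config.min_fraction)
            paired = align_epoch_grids(series_hip, series_chest, joint)
            on_valid_day = paired.epoch_start.normalize().isin(valid_days)
            paired = paired.select(np.asarray(on_valid_day))
            agreements[L].append(participant_agreement(paired, config.min_pairs))
            pooled[L][0].append(paired.mad_a)
            pooled[L][1].append(paired.mad_b)
            if len(paired):
                part_means[L].append(
                    (pid, float(np.mean(paired.mad_a)), float(np.mean(paired.mad_b)))
                )
            if L == config.diurnal_epoch_s:
                diurnal_parts.append(paired)
        del vm_hip, vm_chest, data

    summaries: dict = {}
    ba_participant: dict = {}
    ba_pooled: dict = {}
    pooled_pairs: dict = {}
    mean_frames: dict = {}
    for L in config.epoch_lengths_s:
        a = np.concatenate(pooled[L][0]) if pooled[L][0] else np.empty(0)
        b = np.concatenate(pooled[L][1]) if pooled[L][1] else np.empty(0)
        pooled_pairs[L] = (a, b)
        means = pd.DataFrame(part_means[L], columns=["participant", "mean_a", "mean_b"])
        mean_frames[L] = means
        try:
            summaries[L] = cohort_summary(agreements[L], config.r_threshold)
        except ValueError:
            logger.warning("no usable correlations at L=%ds; summary skipped", L)
        if len(means) >= 2:
            ba_participant[L] = bland_altman(
                means["mean_a"].to_numpy(), means["mean_b"].to_numpy(),
                level="participant_mean", epoch_length_s=L,
            )
        if a.size >= 2:
            ba_pooled[L] = bland_altman(a, b, level="pooled", epoch_length_s=L)

    diurnal = diurnal_profile(diurnal_parts, config.diurnal_epoch_s) if diurnal_parts else None
    if not included:
        logger.warning("NO participant passed the validity filter; all tables are empty")

    report = RunReport(
        n_candidates=len(providers),
        included=included,
        excluded=excluded,
        wear_summary=summarize_wear(validity_all, included),
        agreements=agreements,
        summaries=summaries,
        ba_participant=ba_participant,
        ba_pooled=ba_pooled,
        pooled_pairs=pooled_pairs,
        participant_means=mean_frames,
        diurnal=diurnal,
        masks=masks,
        validity=validity_all,
        config=config,
    )
    if out_dir is not None:
        write_tables(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------

def _correlation_table(report: RunReport) -> pd.DataFrame:
    rows = []
    for L, s in sorted(report.summaries.items()):
        rows.append(
            {
                "window_s": L, "n_participants": s.n_participants,
                "r_min": s.r_min, "r_max": s.r_max, "r_mean": s.r_mean, "r_sd": s.r_sd,
                "r_median": s.r_median, "r_q1": s.r_q1, "r_q3": s.r_q3,
                "n_below_threshold": s.n_below_threshold,
                "pct_below_threshold": s.pct_below_threshold,
            }
        )
    return pd.DataFrame(rows)


def _mse_table(report: RunReport) -> pd.DataFrame:
    scale = report.config.mse_scale
    rows = []
    for L, s in sorted(report.summaries.items()):
        rows.append(
            {
                "window_s": L, "n_participants": s.n_participants,
                "mse_min_scaled": s.mse_min * scale, "mse_max_scaled": s.mse_max * scale,
                "mse_mean_scaled": s.mse_mean * scale, "mse_sd_scaled": s.mse_sd * scale,
                "mse_median_scaled": s.mse_median * scale,
                "mse_q1_scaled": s.mse_q1 * scale, "mse_q3_scaled": s.mse_q3 * scale,
                "mse_mean_g2": s.mse_mean, "mse_median_g2": s.mse_median,
            }
        )
    return pd.DataFrame(rows)


def _ba_table(results: dict) -> pd.DataFrame:
    rows = []
    for L, r in sorted(results.items()):
        rows.append(
            {
                "window_s": L, "n": r.n, "mean_reference": r.mean_a, "mean_test": r.mean_b,
                "bias": r.bias, "loa_low": r.loa_low, "loa_high": r.loa_high,
                "pct_outside": r.pct_outside,
            }
        )
    return pd.DataFrame(rows)


def write_tables(report: RunReport, out_dir: str | Path) -> None:
    """Write the five CSV tables, the participant results and the flow report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "table2_correlation.csv": _correlation_table(report),
        "table3_mse.csv": _mse_table(report),
        "table4_ba_participant.csv": _ba_table(report.ba_participant),
        "table5_ba_pooled.csv": _ba_table(report.ba_pooled),
    }
    per_participant = pd.DataFrame(
        [
            {
                "participant": res.participant_id, "window_s": res.epoch_length_s,
                "n_pairs": res.n_pairs, "pearson_r": res.pearson_r, "mse_g2": res.mse,
            }
            for L in sorted(report.agreements) for res in report.agreements[L]
        ]
    )
    tables["participant_agreement.csv"] = per_participant
    if report.diurnal is not None:
        tables["fig2_diurnal.csv"] = report.diurnal
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
        report.output_paths[name] = str(path)

    flow = {
        "version": report.version,
        "n_candidates": report.n_candidates,
        "n_included": report.n_included,
        "n_excluded": report.n_excluded,
        "excluded": report.excluded,
        "wear_summary": report.wear_summary,
        "config": report.config.to_json_dict(),
        "outputs": report.output_paths,
    }
    (out / "report.json").write_text(json.dumps(flow, indent=1, sort_keys=True))
    report.output_paths["report.json"] = str(out / "report.json")
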