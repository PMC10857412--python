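"""Multi-level agreement statistics between the two devices' MAD series.

Agreement is quantified at three levels:

* **participant** — Pearson correlation r and mean squared error (MSE, g²)
  between the synchronized epoch MADs of the two devices, one value per
  participant per epoch length;
* **cohort** — the distribution of those participant values (mean, SD,
  median, quartiles, range, and the count with r below a threshold,
  default 0.8);
* **Bland–Altman** — bias (mean difference, reference minus test, i.e.
  hip minus chest) and limits of agreement ``bias ± 1.96 × SD(diff)``
  (sample SD, n−1), with the percentage of differences strictly outside the
  limits; computed both on per-participant mean MADs (one pair per
  participant) and pooled over all epoch pairs.

A diurnal profile — clock-time-binned mean MAD per device across all valid
participant-days — summarises where in the day the devices agree.

Conventions where the field admits choices: quartiles use linear
interpolation; ties exactly on a limit of agreement count as inside;
"r < threshold" counting is strict.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epoch_features import PairedEpochSeries

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AgreementResult:
    """Per-participant, per-epoch-length agreement: r, MSE and pair count.

    ``pearson_r`` is NaN when degenerate: fewer than ``min_pairs`` pairs or
    zero variance in either series.
    """

    participant_id: str
    epoch_length_s: int
    n_pairs: int
    pearson_r: float
    mse: float


@dataclasses.dataclass
class CohortSummary:
    """Distribution of participant-level r and MSE for one epoch length."""

    epoch_length_s: int
    n_participants: int
    r_mean: float
    r_sd: float
    r_median: float
    r_q1: float
    r_q3: float
    r_min: float
    r_max: float
    n_below_threshold: int
    pct_below_threshold: float
    threshold: float
    mse_mean: float
    mse_sd: float
    mse_median: float
    mse_q1: float
    mse_q3: float
    mse_min: float
    mse_max: float


@dataclasses.dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements ``a - b``."""

    level: str  # "participant_mean" or "pooled"
    epoch_length_s: int
    n: int
    mean_a: float
    mean_b: float
    bias: float
    loa_low: float
    loa_high: float
    pct_outside: float


def participant_agreement(paired: PairedEpochSeries, min_pairs: int = 10) -> AgreementResult:
    """Pearson r and MSE between the two devices for one participant.

    r is reported missing (NaN, logged) when there are fewer than
    ``min_pairs`` synchronized epochs or either series is constant.
    """
    a, b = paired.mad_a, paired.mad_b
    n = len(paired)
    mse = float(np.mean((a - b) ** 2)) if n else float("nan")
    degenerate = n < min_pairs or n < 2 or np.ptp(a) == 0 or np.ptp(b) == 0
    if degenerate:
        logger.info(
            "participant %s L=%ds: correlation undefined (n=%d, degenerate)",
            paired.participant_id, paired.epoch_length_s, n,
        )
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementResult(
        participant_id=paired.participant_id,
        epoch_length_s=paired.epoch_length_s,
        n_pairs=n,
        pearson_r=r,
        mse=mse,
    )


def cohort_summary(results: Sequence[AgreementResult], threshold: float = 0.8) -> CohortSummary:
    """Summarise participant-level agreement across the cohort.

    Participants with missing r are excluded (from both the r and MSE
    summaries, so both describe the same set). Raises ``ValueError`` when no
    participant has a defined correlation.
    """
    if not results:
        raise ValueError("cohort_summary needs at least one participant result")
    lengths = {res.epoch_length_s for res in results}
    if len(lengths) != 1:
        raise ValueError(f"mixed epoch lengths in cohort summary: {sorted(lengths)}")
    usable = [res for res in results if np.isfinite(res.pearson_r)]
    if not usable:
        raise ValueError("all participant correlations are missing")
    r = np.array([res.pearson_r for res in usable])
    mse = np.array([res.mse for res in usable])
    n_below = int(np.sum(r < threshold))
    q = lambda x, p: float(np.quantile(x, p))  # noqa: E731 — linear interpolation
    return CohortSummary(
        epoch_length_s=usable[0].epoch_length_s,
        n_participants=len(usable),
        r_mean=float(np.mean(r)),
        r_sd=float(np.std(r, ddof=1)) if r.size > 1 else float("nan"),
        r_median=q(r, 0.5),
        r_q1=q(r, 0.25),
        r_q3=q(r, 0.75),
        r_min=float(np.min(r)),
        r_max=float(np.max(r)),
        n_below_threshold=n_below,
        pct_below_threshold=100.0 * n_below / len(usable),
        threshold=threshold,
        mse_mean=float(np.mean(mse)),
        mse_sd=float(np.std(mse, ddof=1)) if mse.size > 1 else float("nan"),
        mse_median=q(mse, 0.5),
        mse_q1=q(mse, 0.25),
        mse_q3=q(mse, 0.75),
        mse_min=float(np.min(mse)),
        mse_max=float(np.max(mse)),
    )


def bland_altman(
    a: np.ndarray,
    b: np.ndarray,
    level: str = "pooled",
    epoch_length_s: int = 0,
) -> BlandAltmanResult:
    """Bland–Altman bias and 95% limits of agreement for paired values.

    ``a`` is the reference (hip) measurement, ``b`` the test (chest) one;
    differences are ``a - b``. Limits are ``bias ± 1.96 × SD`` with the
    sample (n−1) standard deviation; ``pct_outside`` uses strict
    inequality, so ties on a limit count as inside.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError(f"Bland–Altman needs at least 2 pairs, got {n}")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    outside = (diff < loa_low) | (diff > loa_high)
    return BlandAltmanResult(
        level=level,
        epoch_length_s=epoch_length_s,
        n=n,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        bias=bias,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        pct_outside=100.0 * float(np.mean(outside)),
    )


def diurnal_profile(
    paired_series: Iterable[PairedEpochSeries],
    epoch_length_s: int = 300,
) -> pd.DataFrame:
    """Clock-time mean MAD per device over all jointly-worn participant-days.

    Returns a frame with one row per clock bin partitioning 24 h
    (``bin_start_s`` seconds past midnight), the mean MAD of the reference
    and test devices over every contributing epoch, and the number of
    contributing epochs ``n`` (means are NaN where ``n`` is 0).
    """
    L = int(epoch_length_s)
    n_bins = 86400 // L
    if n_bins * L != 86400:
        raise ValueError(f"epoch length {L}s does not partition 24 h")
    sums_a = np.zeros(n_bins)
    sums_b = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for paired in paired_series:
        if paired.epoch_length_s != L:
            raise ValueError(
                f"series has epoch length {paired.epoch_length_s}, expected {L}"
            )
        if len(paired) == 0:
            continue
        seconds_of_day = (paired.epoch_start.asi8 // 1_000_000_000) % 86400
        bins = (seconds_of_day // L).astype(np.int64)
        sums_a += np.bincount(bins, weights=paired.mad_a, minlength=n_bins)
        sums_b += np.bincount(bins, weights=paired.mad_b, minlength=n_bins)
        counts += np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.where(counts > 0, sums_a / counts, np.nan)
        mean_b = np.where(counts > 0, sums_b / counts, np.nan)
    return pd.DataFrame(
        {
            "bin_start_s": np.arange(n_bins) * L,
            "mean_mad_reference": mean_a,
            "mean_mad_test": mean_b,
            "n": counts,
        }
    )


def plot_bland_altman(result: BlandAltmanResult, a: np.ndarray, b: np.ndarray, path) -> None:
    """Scatter of differences vs means with bias and LoA lines (PNG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=4, alpha=0.4)
    ax.axhline(result.bias, color="black")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="red", linestyle="--")
    ax.set_xlabel("mean MAD (g)")
    ax.set_ylabel("difference, reference − test (g)")
    ax.set_title(f"{result.level}, {result.epoch_length_s // 60}-min epochs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_diurnal(profile: pd.DataFrame, path) -> None:
    """Line plot of the two devices' diurnal mean MAD profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hours = profile["bin_start_s"] / 3600.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(hours, profile["mean_mad_reference"], label="reference (hip)")
    ax.plot(hours, profile["mean_mad_test"], label="test (chest)")
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("mean MAD (g)")
    ax.set_xlim(0, 24)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
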