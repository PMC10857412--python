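# Methods

## The measurement problem

Chest-worn ambulatory ECG patches increasingly carry a tri-axial MEMS
accelerometer, but one with far weaker sampling specifications than the
research-grade actigraphs used for physical-activity (PA) epidemiology:
roughly 1.56 samples/s/axis at 8-bit ±2 g coding, against 40 samples/s/axis
at 12-bit ±8 g for a hip-worn research device. `madwear` implements the
validation analysis for such a device pair worn simultaneously in free
living: summarise both raw recordings with an epoch-level intensity metric,
remove non-wear with a device-appropriate rule for each, keep participants
with enough overlapping wear, and quantify agreement at the participant,
cohort and epoch level. Because paired free-living cohort data of this kind
are access-restricted, the package ships a synthetic cohort generator with
known ground truth; every pipeline stage is exercised, and its quality gates
are defined, on that generator.

## Intensity metric

Each recording is collapsed to per-sample vector magnitudes
r(t) = √(x² + y² + z²) (in g) and summarised per epoch by the mean amplitude
deviation

    MAD(t, H) = (1/H) Σ_{h=0}^{H−1} | r(t+h) − r̄(t;H) | ,

the mean absolute deviation of r from its epoch mean. Subtracting the epoch
mean removes the static gravity component, so MAD is invariant to sensor
orientation and to any constant offset (property-tested, including a
bit-exact case on a dyadic grid). Epochs of 1, 5, 10, 30, 60 and 120 min are
used; each device is summarised at its native rate (H ≈ 94 patch samples vs
2400 hip samples per 1-min epoch) with no resampling.

Epoch grids are anchored at local midnight, so 5-min epochs start at
:00, :05, …; this is what makes clock-time (diurnal) averaging across
participants well defined, and it lets the two devices' grids be joined by
epoch-start timestamp alone. Epochs are half-open [t, t+L) — every sample
belongs to exactly one epoch (property-tested). An epoch needs at least
`min_fraction` (default 0.9) of its nominal L·fs samples, otherwise its MAD
is missing. The grid arithmetic is implemented with segment boundaries and
`np.add.reduceat`, verified at 1e-12 against a naive two-pass loop.

## Non-wear rules

**Chest patch (ECG).** The ECG (199.8 Hz) is smoothed by a centred 2-s
rectangular moving average with truncated edges; samples deviating from the
smoothed trace by less than 0.1 mV are pointwise non-wear. Pointwise labels
are consolidated to minutes: a minute is wear iff ≥ 2% of its samples
deviate by ≥ 0.1 mV. The 2% threshold is a package convention (the pointwise
rule alone does not define periods): at 60 bpm the R-waves of a worn patch
occupy ~10% of samples, while a detached flat lead has sub-threshold noise
everywhere, so the bar separates the two regimes with a wide margin. It is
configurable (`ecg_min_active_fraction`).

**Hip device (zero-activity runs).** Non-wear is any maximal run of ≥ 90
consecutive zero-activity minutes. Vendor activity counts are proprietary;
the documented proxy for a "zero count minute" is a minute-level MAD of the
hip vector magnitude below one quantization step (0.00390625 g). A worn
resting device shows sensor noise and postural micro-movement above one code
step; an unworn device on a table does not. Minutes with missing MAD are
treated as zero-activity (absence of data is not evidence of wear).

**Joint wear and validity.** A minute is jointly worn iff worn on both
devices; minutes outside either device's span are non-wear. An epoch is
excluded if *any* of its minutes is not jointly worn (conservative union).
Participants need ≥ 3 calendar days with ≥ 10 h (600 min) of joint wear
inside 07:00–23:00 local time; excluded participants are dropped before any
agreement computation. Days are calendar days, consistent with the clock
window.

## Agreement statistics

Per participant and epoch length: Pearson r and MSE (g²) over the
synchronized, jointly worn, valid-day epoch pairs; r is treated as missing
below 10 pairs or under zero variance. Cohort level: mean, SD, median,
quartiles (linear interpolation) and range of the participant values, plus
the count with r strictly below 0.8. Bland–Altman: differences are
reference − test (hip − chest), bias is their mean, limits of agreement are
bias ± 1.96·SD with the sample (n−1) SD, and `pct_outside` counts strict
exceedances (ties on a limit are inside); computed both on per-participant
mean MADs and pooled over all epoch pairs. MSE tables are additionally
reported ×10⁶ for readability. A diurnal profile averages 5-min MAD per
clock bin per device over all valid participant-days.

## The synthetic cohort

The generator encodes the measurement model the device pair shares and the
ways the devices differ. Defaults (the study conditions for all quality
gates): 20 participants × 5 days starting 07:00 local.

* **Latent intensity λ(t)**, minute resolution, shared by both devices: a
  0.01 g sedentary floor plus Poisson-seeded activity bouts (2/h at full
  rate, geometric durations with 10-min mean, amplitudes 30–100% of 0.15 g,
  capped at 0.3 g). The bout rate follows a diurnal envelope — full between
  08:00 and 14:00, 40% over the rest of the day, 5% overnight — giving the
  morning-skewed activity profile typical of older free-living cohorts.
* **Motion rendering**: three shared sinusoidal components with frequencies
  drawn from 1–3 Hz (walking band) and unit combined variance, scaled by
  γ·λ(t) and directed along the gravity axis (the dominant vertical
  component of ambulation; this keeps the vector magnitude linear in the
  motion signal). The chest patch genuinely undersamples this band at
  1.56 Hz — aliasing preserves epoch-level amplitude but adds epoch-scale
  estimation noise, the mechanism behind the weaker 1-min agreement.
* **Device differences**: placement gain (hip 1.0, chest 0.95 — the chest
  sees slightly attenuated ambulation, which yields the positive hip-minus-
  chest bias expected of this pairing), white sensor noise (hip 0.003 g,
  chest 0.005 g), per-device quartz clock drift ~ N(0, 10 ppm), native
  sampling rates, and each device's own quantizer.
* **Non-wear**: the hip device is off 23:00–07:00 (waking-hours protocol);
  the chest patch is worn continuously. While off, the signal is the
  constant gravity vector plus 0.0005 g noise — below half a code step of
  either device, so the quantized trace is constant and minute MAD is zero.
* **ECG**: biphasic ±1 mV R-waves of 0.1 s at a per-participant heart rate
  ~ N(70, 5) bpm on a 0.002 mV noise baseline. The biphasic shape keeps the
  2-s moving average near zero, so during wear ~11% of samples deviate by
  ≥ 0.1 mV (comfortably above the 2% bar) and during non-wear none do.

All randomness flows from one integer seed through named per-participant
`SeedSequence` streams, making cohorts byte-reproducible. Rendering is lazy
(a 5-day, 40 Hz + 199.8 Hz participant is ~100M samples); files are written
only on request, in the package's text dialects.

**What the generator does not emulate** — and hence what passing its gates
does not show about real data: real gait and postural spectra (motion is a
three-tone band-limited proxy), arm-swing/breathing artefacts of chest
placement, anti-alias filter differences between vendors (unknown for the
patch), ECG morphology beyond R-waves, irregular wear behaviour, and
device-error artefacts. Agreement numbers from the synthetic cohort
characterise the pipeline, not the devices; the generator's high 1-min
correlations (~0.99, against ~0.66 reported for real device pairs) reflect
exactly those missing difference sources.

## Numerical choices

* Byte→g map for the 8-bit patch dialect: offset binary,
  g = (code − 128)·(2R/256), zero g at code 128 (two's-complement MEMS
  convention; the paper trail for the real device does not state the
  offset). Consequence: the representable range is [−R, R − res]; encoding
  clips to the extreme codes and logs. The round-trip error bound of half a
  step therefore holds on [−R, R − res].
* Quantization: round-to-nearest code then clip; idempotent.
* Moving average: interior via a single-pass C filter, edge windows
  truncated to the samples that exist (verified against a literal slice
  oracle).
* Degenerate inputs: empty ECG and empty paired series raise; a
  zero-variance MAD series yields a missing r; masks with no temporal
  overlap produce an all-non-wear union-span mask with a warning.
* Large-array arithmetic is float32 where only sensor-scale precision is
  needed (rendering, raw samples); all reductions (MAD sums, moving-average
  cumulatives) are float64.
* CSV outputs use a fixed `%.10g` float format, so identical inputs and
  configuration reproduce byte-identical tables.

## Scale of the shipped checks

The quality gates run the full default cohort (20×5 days at native rates,
~2×10⁹ rendered samples) once per session, shared across tests; the
brute-force oracle suites use short series (≤ 240 samples), 10,000 random
minute strings, 10⁶ normal differences for the limits-of-agreement coverage
check, and scaled-down renders (single days, reduced-rate device variants)
for the noise-degradation and file round-trip properties. `scripts/
acceptance.py` re-runs the default cohort from scratch at the given seed and
reports the computed summary quantities as JSON.

## Known limitations

* The zero-activity proxy is calibrated to the simulator's noise model; on
  real hip data, vendor-count non-wear algorithms may disagree near the
  90-min boundary.
* The ECG minute rule's 2% threshold assumes R-wave amplitudes well above
  0.1 mV; low-voltage ECGs would need a lower deviation threshold.
* Clock drift is modelled as a constant rate per device; real quartz drift
  wanders with temperature.
* The pooled Bland–Altman treats all epoch pairs as exchangeable; no
  within-participant correlation correction is applied (matching the
  analysis this package reproduces).
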