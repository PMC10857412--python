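"""Generator properties: determinism, diurnal structure, device rendering
physics (gravity, quantization, drift), ECG wear signatures, and the
agreement behaviour of the simulated device pair."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import madwear as mw
from madwear.synth import latent_intensity_profile

from conftest import fast_synth_config


def render_pair_r(seed: int, chest_noise: float, epoch_s: int = 300) -> float:
    """5-min MAD correlation of one simulated day, no ECG stage."""
    cfg = mw.SynthConfig(n_participants=1, n_days=1, chest_noise_sd_g=chest_noise)
    truth = mw.simulate_cohort(cfg, seed=seed).truths[0]
    hip = mw.render_accel(truth, "actigraph")
    chest = mw.render_accel(truth, "zio")
    series_hip = mw.epoch_mad(mw.vector_magnitude(hip), epoch_s)
    series_chest = mw.epoch_mad(mw.vector_magnitude(chest), epoch_s)
    minutes = truth.start_time + pd.to_timedelta(np.arange(truth.n_days * 1440), unit="min")
    joint = mw.NonwearMask(
        truth.participant_id, "joint", truth.start_time,
        truth.expected_wear(pd.DatetimeIndex(minutes), "actigraph"),
    )
    paired = mw.align_epoch_grids(series_hip, series_chest, joint)
    return mw.participant_agreement(paired).pearson_r


class TestLatentProfile:
    def test_deterministic_given_seed(self):
        a = latent_intensity_profile(1440, 0, np.random.default_rng(42))
        b = latent_intensity_profile(1440, 0, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_zero_amplitude_gives_zero_profile(self):
        lam = latent_intensity_profile(
            1440, 0, np.random.default_rng(0), floor_g=0.0, peak_g=0.0
        )
        assert np.all(lam == 0.0)

    def test_morning_peak_exceeds_night_over_100_seeds(self):
        # diurnal envelope: 08:00-14:00 more intense than 00:00-06:00
        # (Monte Carlo: the contrast holds on average and for nearly every
        # draw; an occasional long night bout may flip a single day)
        morning, night = [], []
        for seed in range(100):
            lam = latent_intensity_profile(1440, 0, np.random.default_rng(seed))
            morning.append(lam[8 * 60:14 * 60].mean())
            night.append(lam[0:6 * 60].mean())
        assert np.mean(morning) > np.mean(night)
        assert np.mean(np.array(morning) > np.array(night)) >= 0.9

    def test_non_negative_and_capped(self):
        lam = latent_intensity_profile(1440 * 3, 420, np.random.default_rng(3), cap_g=0.3)
        assert lam.min() >= 0.0 and lam.max() <= 0.3


class TestRenderAccel:
    def test_gravity_only_recording_has_unit_magnitude_and_zero_mad(self):
        cfg = mw.SynthConfig(
            n_participants=1, n_days=1, sedentary_floor_g=0.0, bout_peak_g=0.0,
            hip_noise_sd_g=0.0, chest_noise_sd_g=0.0, nonwear_noise_sd_g=0.0,
            drift_ppm_sd=0.0,
        )
        truth = mw.simulate_cohort(cfg, seed=0).truths[0]
        for label in ("actigraph", "zio"):
            vm = mw.vector_magnitude(mw.render_accel(truth, label))
            assert np.all(vm.values == 1.0)
            mad = mw.epoch_mad(vm, 300, min_fraction=1e-9).mad
            assert np.nanmax(mad) == 0.0

    def test_equal_gain_mad_difference_bounded_by_quantization(self):
        # same truth, no noise/drift, equal gains: the devices can differ in a
        # 5-min MAD by at most the sum of their code resolutions
        cfg = mw.SynthConfig(
            n_participants=1, n_days=1, chest_gain=1.0, hip_gain=1.0,
            chest_noise_sd_g=0.0, hip_noise_sd_g=0.0, nonwear_noise_sd_g=0.0,
            drift_ppm_sd=0.0, hip_off_start=None, hip_off_end=None,
        )
        truth = mw.simulate_cohort(cfg, seed=3).truths[0]
        mad_hip = mw.epoch_mad(mw.vector_magnitude(mw.render_accel(truth, "actigraph")), 300).mad
        mad_chest = mw.epoch_mad(mw.vector_magnitude(mw.render_accel(truth, "zio")), 300).mad
        bound = mw.quantization_resolution(mw.HIP_ACTIGRAPH) + mw.quantization_resolution(
            mw.CHEST_PATCH
        )
        assert np.nanmax(np.abs(mad_hip - mad_chest)) <= bound  # 0.01953125 g

    def test_clock_drift_shifts_scheduled_events(self):
        # a fast clock (+5%) sees the true 23:00 removal earlier in its own
        # timeline: boundary at 57600 / 1.05 s instead of 57600 s
        cfg = mw.SynthConfig(n_participants=1, n_days=1, drift_ppm_sd=0.0)
        truth = mw.simulate_cohort(cfg, seed=2).truths[0]
        drifted = dataclasses.replace(
            truth,
            devices={
                **truth.devices,
                "actigraph": dataclasses.replace(truth.devices["actigraph"], drift_ppm=5e4),
            },
        )
        for t, expected_s in ((truth, 57600.0), (drifted, 57600.0 / 1.05)):
            rec = mw.render_accel(t, "actigraph")
            mask = mw.actigraph_nonwear(mw.epoch_mad(mw.vector_magnitude(rec), 60))
            boundary_minute = int(np.flatnonzero(~mask.wear)[0])
            assert boundary_minute * 60 == pytest.approx(expected_s, abs=120)

    def test_rendering_respects_device_range(self):
        truth = mw.simulate_cohort(mw.SynthConfig(n_participants=1, n_days=1), seed=9).truths[0]
        rec = mw.render_accel(truth, "zio")
        for axis in (rec.x, rec.y, rec.z):
            assert np.max(np.abs(axis)) <= 2.0


class TestRenderEcg:
    def test_all_wear_detected_as_wear(self):
        cfg = mw.SynthConfig(n_participants=1, n_days=1)
        truth = dataclasses.replace(
            mw.simulate_cohort(cfg, seed=4).truths[0], heart_rate_bpm=60.0
        )
        mask = mw.ecg_nonwear(mw.render_ecg(truth))
        assert mask.wear.all()

    def test_all_nonwear_schedule_detected_as_nonwear(self):
        cfg = mw.SynthConfig(n_participants=1, n_days=1)
        truth = mw.simulate_cohort(cfg, seed=4).truths[0]
        truth = dataclasses.replace(truth, wear_s={**truth.wear_s, "zio": []})
        mask = mw.ecg_nonwear(mw.render_ecg(truth))
        assert not mask.wear.any()

    def test_partial_schedule_boundaries_within_one_minute(self):
        cfg = mw.SynthConfig(n_participants=1, n_days=1)
        truth = mw.simulate_cohort(cfg, seed=4).truths[0]
        # worn 08:00-22:00 on a recording that starts 07:00
        truth = dataclasses.replace(truth, wear_s={**truth.wear_s, "zio": [(3600.0, 54000.0)]})
        mask = mw.ecg_nonwear(mw.render_ecg(truth))
        worn = np.flatnonzero(mask.wear)
        assert abs(worn[0] - 60) <= 1
        assert abs(worn[-1] - 899) <= 1


class TestCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = fast_synth_config(n_participants=1, n_days=1)
        for d in ("a", "b"):
            mw.simulate_cohort(cfg, seed=11).write(tmp_path / d)
        for name in ("accel.zacl", "accel.hea", "hip.csv", "ecg.csv", "truth.json"):
            assert (tmp_path / "a" / "P001" / name).read_bytes() == (
                tmp_path / "b" / "P001" / name
            ).read_bytes()

    def test_written_cohort_parses_back(self, tmp_path):
        cfg = fast_synth_config(n_participants=1, n_days=1)
        cohort = mw.simulate_cohort(cfg, seed=11)
        cohort.write(tmp_path)
        pid, loader = mw.load_participants(tmp_path)[0]
        data = loader()
        bundle = cohort.render(0)
        assert pid == "P001"
        assert data.hip.n_samples == bundle.hip.n_samples
        assert np.allclose(data.hip.x, bundle.hip.x, atol=5.1e-7)
        assert data.chest.n_samples == bundle.chest.n_samples
        assert np.array_equal(data.chest.x, bundle.chest.x)  # zacl is exact
        assert data.ecg.n_samples == bundle.ecg.n_samples

    def test_chest_noise_degrades_agreement(self):
        # Monte Carlo over 20 seeds: more chest sensor noise, lower mean r
        seeds = range(20)
        means = [
            np.mean([render_pair_r(s, noise) for s in seeds])
            for noise in (0.005, 0.03, 0.08)
        ]
        assert means[0] > means[1] > means[2]

    def test_faithful_regime_recovers_high_correlation(self):
        # equal gains, noise <= 0.01 g: every participant's 5-min r above 0.9
        cfg = mw.SynthConfig(
            n_participants=3, n_days=3, chest_gain=1.0, hip_gain=1.0
        )
        cohort = mw.simulate_cohort(cfg, seed=21)
        report = mw.run_pipeline(cohort.providers(), mw.RunConfig(epoch_lengths_s=(300,)))
        rs = [res.pearson_r for res in report.agreements[300]]
        assert len(rs) == 3
        assert all(r > 0.9 for r in rs)


class TestDefaultCohortProperties:
    """Invariants of the full default study conditions (shared session run)."""

    def test_correlation_monotone_one_to_thirty_minutes(self, default_cohort_run):
        _, report = default_cohort_run
        means = [report.summaries[L].r_mean for L in (60, 300, 600, 1800)]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_nonwear_recovery_over_99_percent(self, default_cohort_run):
        cohort, report = default_cohort_run
        recoveries = [
            mw.schedule_recovery(
                cohort.truths[i],
                {k: v for k, v in report.masks[pid].items() if k != "joint"},
            )
            for i, pid in enumerate(cohort.participant_ids)
        ]
        assert min(recoveries) >= 0.99

    def test_every_participant_passes_validity(self, default_cohort_run):
        _, report = default_cohort_run
        assert report.n_included == 20
        assert report.wear_summary["mean_days"] == 5.0
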