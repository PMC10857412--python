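"""Shared fixtures: a full default synthetic cohort run (session-scoped,
computed once) and a fast small cohort for pipeline/file tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import madwear as mw

settings.register_profile(
    "madwear",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("madwear")


#: Low-rate device variants for fast file/pipeline tests: same dialects and
#: rules, far fewer samples.
FAST_HIP = dataclasses.replace(mw.HIP_ACTIGRAPH, sampling_rate_hz=8.0)


def fast_synth_config(**overrides) -> mw.SynthConfig:
    """A scaled-down cohort (low sampling rates) for structural tests."""
    defaults = dict(
        n_participants=2,
        n_days=3,
        hip_spec=FAST_HIP,
        ecg_fs_hz=20.0,
    )
    defaults.update(overrides)
    return mw.SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort_run():
    """2 participants x 3 days at reduced rates, run end to end in memory."""
    cohort = mw.simulate_cohort(fast_synth_config(), seed=5)
    report = mw.run_pipeline(cohort.providers(), mw.RunConfig(epoch_lengths_s=(60, 300, 600)))
    return cohort, report


@pytest.fixture(scope="session")
def default_cohort_run():
    """The default study conditions (20 participants x 5 days), fixed seed.

    This is the expensive full-scale run; every test needing it shares this
    single execution.
    """
    cohort = mw.simulate_cohort(seed=1)
    report = mw.run_pipeline(cohort.providers())
    return cohort, report


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
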