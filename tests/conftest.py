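"""Shared fixtures: scaled-down synthetic sessions reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from effr.pipeline import analyze_channel, prepare_trials
from effr.synthetic_data import (
    ArtifactSpec,
    GeneratorGroundTruth,
    NeuralGenerator,
    NoiseSpec,
    StimulusSpec,
    default_rate_list,
    make_rate_list,
    synth_session,
)

FS = 24414.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def mid_rates():
    """12 rates spanning 43-350 pps (no >500-pps tail; cheap)."""
    return tuple(make_rate_list(FS, 43, 350, 12))


@pytest.fixture(scope="session")
def full_rates():
    """22 rates spanning the full 43-642-pps protocol range."""
    return tuple(make_rate_list(FS, 43, 642, 22))


@pytest.fixture(scope="session")
def quiet_artifact():
    """Artifact disabled (and jitter off, so noiseless runs are exactly
    repeatable trial-to-trial)."""
    return ArtifactSpec(peak_uv=0.0, gain_jitter=0.0, time_jitter_samples=0)


@pytest.fixture(scope="session")
def no_noise():
    return NoiseSpec(rms_uv=0.0, burst_prob=0.0)


def single_generator(latency_ms=3.7, amp=6.0, width_ms=1.0, cutoff=None):
    return GeneratorGroundTruth(
        (NeuralGenerator("G", latency_ms, (amp, amp), width_ms, taper_cutoff_hz=cutoff),)
    )


@pytest.fixture(scope="session")
def single_gen_clean_session(mid_rates, quiet_artifact, no_noise):
    """Noiseless, artifact-free single-generator recording (latency 3.7 ms)."""
    spec = StimulusSpec(pulse_rates=mid_rates, n_trials_per_rate=4)
    return synth_session(spec, single_generator(3.7), quiet_artifact, no_noise, seed=101)


@pytest.fixture(scope="session")
def default_session_results(full_rates):
    """Default 4-generator session (artifact + noise on), both channels
    analyzed end to end.  16 trials/rate keeps the suite fast while leaving
    8 polarity pairs for the Rayleigh test."""
    spec = StimulusSpec(pulse_rates=tuple(default_rate_list()), n_trials_per_rate=16)
    rec = synth_session(spec, seed=11)
    out = {}
    for ch in (0, 1):
        trials, t_start, n_rej, n_tot = prepare_trials(rec, ch)
        out[ch] = analyze_channel(
            trials, FS, t_start, ch, n_rejected=n_rej, n_trials=n_tot
        )
    return rec, out
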