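import numpy as np
import pandas as pd
import pytest

from p300select import (TaskType, generate_task_schedule, preprocess_recording,
                        synthesize_recording)
from p300select.preprocess import EpochSet
from p300select.simulate import CHANNEL_NAMES, SubjectProfile


def quiet_profile(noise_sd=1e-9, late_amp=6.0, early_amp=4.0,
                  late_latency=420.0, jitter=0.0, nontarget_scale=0.5):
    """A hand-set subject profile; near-noiseless by default."""
    tasks = list(TaskType)
    return SubjectProfile(
        early_amp={t: early_amp for t in tasks},
        late_amp={t: late_amp for t in tasks},
        late_latency_ms={t: late_latency for t in tasks},
        latency_jitter_sd_ms=jitter,
        topography=np.array([0.7, 0.7, 0.75, 0.95, 0.75, 0.9, 0.9, 1.0]),
        noise_sd=noise_sd,
        nontarget_early_scale=nontarget_scale,
    )


def make_epochset(data, meta, times_ms=None, task_type=None, fs=64.0):
    """Assemble an EpochSet from raw arrays for toy decoding tests."""
    data = np.asarray(data, dtype=float)
    if times_ms is None:
        times_ms = (np.arange(data.shape[2]) - 13) / fs * 1000.0
    return EpochSet(
        data=data, sample_rate_hz=fs, times_ms=np.asarray(times_ms),
        trial_meta=pd.DataFrame(meta),
        channel_names=CHANNEL_NAMES[:data.shape[1]],
        task_type=task_type,
    )


def simulate_epochs(task=TaskType.TARGET_SELECTION, profile=None, seed=5,
                    sched_seed=1, **sched_kw):
    schedule = generate_task_schedule(task, seed=sched_seed, **sched_kw)
    profile = profile or quiet_profile(noise_sd=9.0)
    eeg = synthesize_recording(schedule, profile, rng_seed=seed)
    return schedule, profile, preprocess_recording(eeg, schedule)


@pytest.fixture(scope="session")
def ts_subject():
    """One moderately noisy target_selection subject (schedule, profile, epochs)."""
    return simulate_epochs()


@pytest.fixture(scope="session")
def separable_subject():
    """A near-noiseless, high-amplitude subject: perfectly decodable."""
    return simulate_epochs(profile=quiet_profile(noise_sd=0.05, late_amp=10.0))
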