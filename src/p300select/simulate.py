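"""Synthetic 8-channel EEG for scheduled tasks.

The generator writes a continuous 256 Hz recording per subject and task by
superimposing deterministic evoked responses on seeded pink (1/f) background
noise.  The evoked model is deliberately minimal but reproduces the
qualitative single-trial ERP structure the decoder relies on:

* every real (non-dummy) stimulus evokes an early visual component — a
  positive half-cosine bump centred near 188 ms — attenuated on non-targets;
* attended targets additionally evoke a late positive component (P300-like),
  a Gaussian bump whose centre latency is task dependent (roughly 300–550 ms)
  and jitters from trial to trial;
* dummy slots (target_only non-targets) evoke nothing at all;
* both components scale channel-wise with a centro-parietal topography.

Subjects are drawn from a cohort distribution so that amplitudes, latencies,
topography and noise level vary between simulated participants, mimicking
the large inter-individual ERP variability seen in real recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .paradigm import DUMMY, TaskSchedule, TaskType

__all__ = [
    "CHANNEL_NAMES",
    "SAMPLE_RATE_HZ",
    "SubjectProfile",
    "CohortParams",
    "ContinuousEEG",
    "sample_subject_profile",
    "synthesize_recording",
    "pink_noise",
]

#: Electrode montage, 10-10 names, fixed order.
CHANNEL_NAMES = ("FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "Pz")
N_CHANNELS = len(CHANNEL_NAMES)

#: Raw acquisition rate of the simulated amplifier.
SAMPLE_RATE_HZ = 256

#: Centre of the early visual component (ms post stimulus onset).
EARLY_LATENCY_MS = 188.0
#: Full width of the early half-cosine bump (ms).
EARLY_WIDTH_MS = 100.0
#: Gaussian SD of the late positive component (ms).
LATE_SD_MS = 60.0

_LEAD_IN_S = 1.0   # silence before the first stimulus
_TAIL_S = 1.0      # silence after the last epoch window


class SimulationError(ValueError):
    pass


@dataclass
class SubjectProfile:
    """Generative ERP parameters of one simulated subject.

    Amplitudes are in µV, latencies in ms.  ``topography`` holds one
    non-negative gain per channel in :data:`CHANNEL_NAMES` order with its
    maximum (1.0) at a centro-parietal site.
    """

    early_amp: dict[TaskType, float]
    late_amp: dict[TaskType, float]
    late_latency_ms: dict[TaskType, float]
    latency_jitter_sd_ms: float
    topography: np.ndarray
    noise_sd: float
    nontarget_early_scale: float

    def __post_init__(self):
        self.topography = np.asarray(self.topography, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.topography.shape != (N_CHANNELS,):
            raise SimulationError(f"topography must have {N_CHANNELS} entries")
        if np.any(self.topography < 0):
            raise SimulationError("topography gains must be non-negative")
        if not np.isclose(self.topography.max(), 1.0):
            raise SimulationError("topography maximum must be 1")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        if not 0.0 <= self.nontarget_early_scale <= 1.0:
            raise SimulationError("nontarget_early_scale must be in [0, 1]")
        for d in (self.early_amp, self.late_amp):
            if any(v < 0 for v in d.values()):
                raise SimulationError("component amplitudes must be >= 0")
        if any(not 0.0 < v < 800.0 for v in self.late_latency_ms.values()):
            raise SimulationError("late latency must lie inside the epoch window")

    def to_json(self, path=None) -> str:
        payload = {
            "early_amp": {k.value: v for k, v in self.early_amp.items()},
            "late_amp": {k.value: v for k, v in self.late_amp.items()},
            "late_latency_ms": {k.value: v for k, v in self.late_latency_ms.items()},
            "latency_jitter_sd_ms": self.latency_jitter_sd_ms,
            "topography": self.topography.tolist(),
            "noise_sd": self.noise_sd,
            "nontarget_early_scale": self.nontarget_early_scale,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SubjectProfile":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        for key in ("early_amp", "late_amp", "late_latency_ms"):
            payload[key] = {TaskType(k): v for k, v in payload[key].items()}
        payload["topography"] = np.asarray(payload["topography"])
        return cls(**payload)


def _task_dict(to, ot, ts):
    return {
        TaskType.TARGET_ONLY: to,
        TaskType.ODDBALL_TARGET: ot,
        TaskType.TARGET_SELECTION: ts,
    }


@dataclass
class CohortParams:
    """Cohort-level distribution settings for :func:`sample_subject_profile`.

    Per-task means follow the difficulty gradient: the late (P300-like)
    component is largest in target_only, intermediate in oddball_target and
    smallest — with the longest latency — in target_selection, so that
    decodability decreases with cognitive demand.  All SDs are
    between-subject; per-field values are truncated to the profile
    invariants after sampling.
    """

    early_amp_mean: dict[TaskType, float] = field(
        default_factory=lambda: _task_dict(6.0, 5.0, 4.0))
    early_amp_sd: float = 1.0
    late_amp_mean: dict[TaskType, float] = field(
        default_factory=lambda: _task_dict(8.0, 6.0, 4.0))
    late_amp_sd: float = 1.5
    late_latency_mean_ms: dict[TaskType, float] = field(
        default_factory=lambda: _task_dict(360.0, 420.0, 500.0))
    late_latency_sd_ms: float = 40.0
    late_latency_range_ms: tuple[float, float] = (300.0, 550.0)
    latency_jitter_sd_mean_ms: float = 25.0
    latency_jitter_sd_sd_ms: float = 8.0
    noise_sd_mean: float = 9.0
    noise_sd_sd: float = 2.0
    nontarget_early_scale_mean: float = 0.5
    nontarget_early_scale_sd: float = 0.1
    topography_base: tuple[float, ...] = (0.70, 0.70, 0.75, 0.95, 0.75, 0.90, 0.90, 1.0)
    topography_sd: float = 0.06

    def validate(self) -> None:
        sds = (self.early_amp_sd, self.late_amp_sd, self.late_latency_sd_ms,
               self.latency_jitter_sd_sd_ms, self.noise_sd_sd,
               self.nontarget_early_scale_sd, self.topography_sd)
        if any(s < 0 for s in sds):
            raise SimulationError("distribution SDs must be non-negative")
        if self.noise_sd_mean <= 0:
            raise SimulationError("noise_sd_mean must be positive")
        if len(self.topography_base) != N_CHANNELS:
            raise SimulationError(f"topography_base must have {N_CHANNELS} entries")


def sample_subject_profile(
    cohort_params: CohortParams | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> SubjectProfile:
    """Draw one subject's generative parameters from the cohort distribution.

    Gaussian draws per field, truncated to the :class:`SubjectProfile`
    invariants.  The Pz gain is held at 1 so the topography maximum stays
    centro-parietal.  Deterministic in ``rng_seed``.
    """
    cp = cohort_params or CohortParams()
    cp.validate()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    def tnorm(mean, sd, lo=None, hi=None):
        v = float(rng.normal(mean, sd))
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return v

    early = {t: tnorm(m, cp.early_amp_sd, lo=0.0)
             for t, m in cp.early_amp_mean.items()}
    late = {t: tnorm(m, cp.late_amp_sd, lo=0.0)
            for t, m in cp.late_amp_mean.items()}
    lo, hi = cp.late_latency_range_ms
    lat = {t: tnorm(m, cp.late_latency_sd_ms, lo=lo, hi=hi)
           for t, m in cp.late_latency_mean_ms.items()}
    jitter = tnorm(cp.latency_jitter_sd_mean_ms, cp.latency_jitter_sd_sd_ms, lo=1.0)
    noise = tnorm(cp.noise_sd_mean, cp.noise_sd_sd, lo=1.0)
    scale = tnorm(cp.nontarget_early_scale_mean, cp.nontarget_early_scale_sd,
                  lo=0.0, hi=1.0)
    topo = np.array([
        1.0 if base == 1.0 else min(max(tnorm(base, cp.topography_sd), 0.05), 0.98)
        for base in cp.topography_base
    ])
    return SubjectProfile(
        early_amp=early, late_amp=late, late_latency_ms=lat,
        latency_jitter_sd_ms=jitter, topography=topo,
        noise_sd=noise, nontarget_early_scale=scale,
    )


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording with stimulus events.

    ``data`` is channels x samples in µV.  ``events`` maps each schedule
    trial (by index in presentation order) to its onset sample.
    """

    sample_rate_hz: float
    data: np.ndarray
    channel_names: tuple[str, ...]
    events: list[tuple[int, int]]  # (sample_index, trial_index)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -------------------------------------------------------------- storage
    def save(self, path) -> None:
        """Write to an ``.npz`` tensor plus a ``.json`` event sidecar."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 data=self.data)
        side = path[:-4] if path.endswith(".npz") else path
        with open(side + ".json", "w") as fh:
            json.dump({
                "sample_rate_hz": self.sample_rate_hz,
                "channel_names": list(self.channel_names),
                "events": [[int(s), int(t)] for s, t in self.events],
            }, fh)

    @classmethod
    def load(cls, path) -> "ContinuousEEG":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        data = np.load(base + ".npz")["data"]
        with open(base + ".json") as fh:
            meta = json.load(fh)
        return cls(
            sample_rate_hz=meta["sample_rate_hz"], data=data,
            channel_names=tuple(meta["channel_names"]),
            events=[(int(s), int(t)) for s, t in meta["events"]],
        )

    @classmethod
    def from_edf(cls, edf_path, events_json) -> "ContinuousEEG":
        """Read a real recording from EDF plus a JSON event sidecar.

        Requires :mod:`mne`.  The sidecar has the same ``events`` layout as
        :meth:`save` writes.
        """
        import mne

        raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
        with open(events_json) as fh:
            meta = json.load(fh)
        return cls(
            sample_rate_hz=float(raw.info["sfreq"]),
            data=raw.get_data() * 1e6,  # volts -> µV
            channel_names=tuple(raw.ch_names),
            events=[(int(s), int(t)) for s, t in meta["events"]],
        )


def pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f ("pink") noise via spectral shaping.

    White Gaussian noise is transformed to the frequency domain, scaled by
    ``1/sqrt(f)`` (DC removed), transformed back and normalised to SD 1.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    return shaped / shaped.std()


def _early_bump(t_ms: np.ndarray) -> np.ndarray:
    """Unit-amplitude half-cosine bump centred at the early latency."""
    x = (t_ms - EARLY_LATENCY_MS) / EARLY_WIDTH_MS  # support |x| < 0.5
    out = np.cos(np.pi * x)
    out[np.abs(x) >= 0.5] = 0.0
    return out


def _late_bump(t_ms: np.ndarray, centre_ms: float) -> np.ndarray:
    """Unit-amplitude Gaussian bump (support truncated at ±4 SD)."""
    z = (t_ms - centre_ms) / LATE_SD_MS
    out = np.exp(-0.5 * z * z)
    out[np.abs(z) > 4.0] = 0.0
    return out


def synthesize_recording(
    schedule: TaskSchedule,
    profile: SubjectProfile,
    rng_seed: int = 0,
) -> ContinuousEEG:
    """Render one continuous recording for a scheduled task.

    The evoked part is deterministic given the seed (latency jitter uses a
    dedicated child stream), and the background noise uses another child
    stream, so zeroing all amplitudes with the same seed yields exactly the
    noise-only recording — the two parts superpose linearly.
    """
    profile.validate()
    task = schedule.task_type
    fs = SAMPLE_RATE_HZ
    noise_ss, jitter_ss = np.random.SeedSequence(rng_seed).spawn(2)
    noise_rng = np.random.default_rng(noise_ss)
    jitter_rng = np.random.default_rng(jitter_ss)

    if schedule.n_trials == 0:
        raise SimulationError("cannot synthesize an empty schedule")
    last_onset = schedule.trials[-1].onset_s
    n = int(np.ceil((_LEAD_IN_S + last_onset + _TAIL_S) * fs)) + fs

    data = np.empty((N_CHANNELS, n))
    for ch in range(N_CHANNELS):
        data[ch] = profile.noise_sd * pink_noise(n, noise_rng)

    # evoked responses, rendered on a 1 s post-onset grid
    seg_len = fs  # 1 s
    t_ms = np.arange(seg_len) / fs * 1000.0
    early_shape = _early_bump(t_ms)
    events: list[tuple[int, int]] = []
    for idx, trial in enumerate(schedule.trials):
        onset_sample = int(round((_LEAD_IN_S + trial.onset_s) * fs))
        events.append((onset_sample, idx))
        # per-trial jitter is drawn for every trial so the stream advances
        # identically regardless of amplitudes (linearity contract)
        jit = jitter_rng.normal(0.0, profile.latency_jitter_sd_ms)
        if trial.stimulus_id == DUMMY:
            continue
        amp = profile.early_amp[task] * (
            1.0 if trial.is_target else profile.nontarget_early_scale
        )
        wave = amp * early_shape
        if trial.is_target:
            centre = float(np.clip(profile.late_latency_ms[task] + jit, 100.0, 750.0))
            wave = wave + profile.late_amp[task] * _late_bump(t_ms, centre)
        sl = slice(onset_sample, onset_sample + seg_len)
        data[:, sl] += profile.topography[:, None] * wave[None, :]

    return ContinuousEEG(
        sample_rate_hz=fs, data=data,
        channel_names=CHANNEL_NAMES, events=events,
    )
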