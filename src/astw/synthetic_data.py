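"""Synthetic shoulder-movement EMG + accelerometer trial generator.

The generator emulates the statistical structure the feature-extraction
method assumes, so every pipeline stage can be exercised without any
recording hardware:

* 5 surface-EMG channels over the shoulder girdle.  During a movement
  segment, channel ``ch`` carries amplitude-modulated band-limited noise:
  ``A[class, ch] * (1 + drift(t)) * n(t)`` with ``n(t)`` Gaussian noise
  band-passed to 30-450 Hz, plus white sensor noise.  ``drift(t)`` is a
  slow (0.5-3 Hz) multiplicative gain fluctuation emulating force drift
  and physiological tremor; its correlation time of a few hundred
  milliseconds is what makes features computed on short windows noisier
  than features on long windows, as observed with real surface EMG.
  Rest keeps a small baseline tonus.
* 3 accelerometer axes.  Each class holds a distinct quasi-static offset
  ``G[class, axis]`` — the projection of gravity onto the sensor for that
  posture — plus a damped low-frequency (2-20 Hz) oscillation burst at each
  segment transition, plus white sensor noise.
* The label schedule follows the acquisition protocol: a rest segment,
  then each of the 6 movements followed by rest, 8 trials per subject.

Subject heterogeneity is modelled as multiplicative log-normal jitter on
the EMG gain matrix and additive Gaussian jitter on the ACC offsets, fixed
per subject.  Generation is fully deterministic given
``(seed, subject, trial)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io_preprocess import (
    ACC,
    EMG,
    N_CLASSES,
    REST_CLASS,
    FilterSpec,
    TrialRecording,
    bandpass_filter,
    write_trial,
)

N_EMG = 5
N_ACC = 3

#: EMG gain per (class, channel); rows 0..5 are the movements
#: (elevation, depression, protraction, retraction, upward rotation,
#: downward rotation), row 6 the rest tonus.  Rows overlap partially:
#: neighbouring movements share synergists, so EMG-only classification is
#: good but not trivial.
DEFAULT_ACTIVATION = np.array(
    [
        [1.2, 0.3, 0.8, 0.4, 0.3],
        [0.3, 1.1, 0.3, 0.9, 0.3],
        [0.9, 0.8, 0.2, 0.3, 1.0],
        [0.2, 0.4, 1.2, 0.8, 0.3],
        [0.8, 0.3, 0.5, 1.2, 0.6],
        [0.4, 0.9, 0.6, 0.3, 1.1],
        [0.05, 0.05, 0.05, 0.05, 0.05],
    ]
)

#: Gravity projection (in g) per (class, axis): each held posture tilts the
#: shoulder-mounted sensor differently; rest is the neutral posture.
DEFAULT_OFFSETS = np.array(
    [
        [0.15, 0.10, 0.98],
        [-0.12, -0.05, 0.99],
        [0.35, 0.05, 0.93],
        [-0.30, 0.08, 0.95],
        [0.10, 0.40, 0.91],
        [0.05, -0.35, 0.93],
        [0.00, 0.00, 1.00],
    ]
)

_MIN_SEGMENT_MS = 450.0  # three windows at the longest analysis epoch (150 ms)


@dataclass
class SynthConfig:
    """Generator settings; the defaults reproduce the acquisition protocol scale.

    ``movement_ms``/``rest_ms`` are segment durations; both must allow at
    least three 150 ms analysis windows.  ``emg_noise``/``acc_noise`` are
    white sensor-noise standard deviations (signal units / g).
    ``burst_amp`` scales the 2-20 Hz transition oscillation on the ACC axes.
    """

    n_subjects: int = 1
    n_trials: int = 8
    fs: float = 1000.0
    movement_ms: float = 3000.0
    rest_ms: float = 3000.0
    transition_ms: float = 300.0
    ramp_ms: float = 100.0
    emg_noise: float = 0.5
    emg_drift: float = 0.6
    drift_band: FilterSpec = field(default_factory=lambda: FilterSpec(0.5, 3.0, order=2))
    acc_noise: float = 0.02
    acc_wobble: float = 0.02
    burst_amp: float = 0.2
    subject_gain_jitter: float = 0.10
    subject_offset_jitter: float = 0.03
    activation: np.ndarray = field(default_factory=lambda: DEFAULT_ACTIVATION.copy())
    offsets: np.ndarray = field(default_factory=lambda: DEFAULT_OFFSETS.copy())
    emg_band: FilterSpec = field(default_factory=lambda: FilterSpec(30.0, 450.0))
    seed: int = 42

    def __post_init__(self):
        self.activation = np.asarray(self.activation, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.activation.shape != (N_CLASSES, N_EMG):
            raise ConfigError(f"activation matrix must be {N_CLASSES}x{N_EMG}")
        if self.offsets.shape != (N_CLASSES, N_ACC):
            raise ConfigError(f"offset matrix must be {N_CLASSES}x{N_ACC}")
        if np.any(self.activation < 0):
            raise ConfigError("EMG gains must be nonnegative")
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ConfigError("need at least one subject and one trial")
        if self.movement_ms < _MIN_SEGMENT_MS or self.rest_ms < _MIN_SEGMENT_MS:
            raise ConfigError(
                f"segment durations must be >= {_MIN_SEGMENT_MS} ms "
                "(three windows at the longest analysis epoch)"
            )
        if self.transition_ms < 3000.0 / self.emg_band.low_hz / 2:
            raise ConfigError("transition shorter than the filter warm-up")


def _schedule(cfg: SynthConfig):
    """Per-sample labels and the segment-boundary sample indices."""
    mv = int(round(cfg.movement_ms * cfg.fs / 1000.0))
    rest = int(round(cfg.rest_ms * cfg.fs / 1000.0))
    labels, boundaries = [], []
    pos = 0
    labels.append(np.full(rest, REST_CLASS))
    pos += rest
    for m in range(6):
        boundaries.append(pos)
        labels.append(np.full(mv, m))
        pos += mv
        boundaries.append(pos)
        labels.append(np.full(rest, REST_CLASS))
        pos += rest
    return np.concatenate(labels), boundaries


def _smooth_steps(step_signal: np.ndarray, ramp_samples: int) -> np.ndarray:
    """Raised-cosine smoothing of piecewise-constant per-sample profiles."""
    if ramp_samples < 2:
        return step_signal
    k = 0.5 * (1 - np.cos(2 * np.pi * np.arange(1, ramp_samples + 1) / (ramp_samples + 1)))
    k /= k.sum()
    out = np.empty_like(step_signal)
    for c in range(step_signal.shape[1]):
        padded = np.pad(step_signal[:, c], ramp_samples, mode="edge")
        out[:, c] = np.convolve(padded, k, mode="same")[ramp_samples:-ramp_samples]
    return out


def _slow_noise(rng, n: int, band: FilterSpec, fs: float) -> np.ndarray:
    """Unit-variance low-frequency noise (slow gain drift / postural wobble)."""
    x = bandpass_filter(rng.standard_normal(n), band, fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def _subject_params(cfg: SynthConfig, subject: int):
    """Per-subject gain and offset matrices (fixed across that subject's trials)."""
    rng = np.random.default_rng([cfg.seed, 104729, subject])
    A = cfg.activation * np.exp(
        rng.normal(0.0, cfg.subject_gain_jitter, size=cfg.activation.shape)
    )
    G = cfg.offsets + rng.normal(0.0, cfg.subject_offset_jitter, size=cfg.offsets.shape)
    return A, G


def generate_trial(cfg: SynthConfig, subject: int = 0, trial: int = 0) -> TrialRecording:
    """One labelled EMG+ACC trial, deterministic given ``(seed, subject, trial)``."""
    labels, boundaries = _schedule(cfg)
    n = labels.size
    A, G = _subject_params(cfg, subject)
    rng = np.random.default_rng([cfg.seed, subject, trial])
    ramp = int(round(cfg.ramp_ms * cfg.fs / 1000.0))

    # EMG: class-gain envelope modulating 30-450 Hz band-limited noise
    carrier = np.column_stack(
        [
            bandpass_filter(rng.standard_normal(n), cfg.emg_band, cfg.fs)
            for _ in range(N_EMG)
        ]
    )
    envelope = _smooth_steps(A[labels], ramp)
    if cfg.emg_drift > 0:
        drift = np.column_stack(
            [_slow_noise(rng, n, cfg.drift_band, cfg.fs) for _ in range(N_EMG)]
        )
        envelope = envelope * np.clip(1.0 + cfg.emg_drift * drift, 0.0, None)
    emg = envelope * carrier + cfg.emg_noise * rng.standard_normal((n, N_EMG))

    # ACC: quasi-static gravity projection + postural wobble + transition bursts
    acc = _smooth_steps(G[labels], ramp)
    if cfg.acc_wobble > 0:
        acc += cfg.acc_wobble * np.column_stack(
            [_slow_noise(rng, n, cfg.drift_band, cfg.fs) for _ in range(N_ACC)]
        )
    burst_len = int(round(cfg.transition_ms * cfg.fs / 1000.0))
    t_burst = np.arange(burst_len) / cfg.fs
    decay = np.exp(-t_burst / (cfg.transition_ms / 3000.0))
    for b in boundaries:
        for axis in range(N_ACC):
            f = rng.uniform(3.0, 18.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            amp = cfg.burst_amp * rng.uniform(0.5, 1.5)
            seg = amp * decay * np.sin(2 * np.pi * f * t_burst + phase)
            end = min(b + burst_len, n)
            acc[b:end, axis] += seg[: end - b]
    acc += cfg.acc_noise * rng.standard_normal((n, N_ACC))

    return TrialRecording(
        samples=np.hstack([emg, acc]),
        fs=cfg.fs,
        channel_roles=(EMG,) * N_EMG + (ACC,) * N_ACC,
        labels=labels,
        trial_id=trial,
        subject_id=subject,
    )


def generate_dataset(cfg: SynthConfig) -> list:
    """All ``n_subjects * n_trials`` trials, ordered by subject then trial."""
    return [
        generate_trial(cfg, subject=s, trial=t)
        for s in range(cfg.n_subjects)
        for t in range(cfg.n_trials)
    ]


def write_dataset(cfg: SynthConfig, out_dir) -> list:
    """Generate and write the dataset as CSV trial files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in generate_dataset(cfg):
        path = out_dir / f"subject{trial.subject_id}_trial{trial.trial_id}.csv"
        write_trial(trial, path)
        paths.append(path)
    return paths
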