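"""Trial I/O, zero-phase band-pass filtering, windowing, and derivative expansion.

A *trial* is a continuous multichannel recording of surface EMG and tri-axial
accelerometer (ACC) signals sampled synchronously (1000 Hz in the reference
protocol), with a per-sample class label.  Seven classes are used: six
shoulder movements (elevation, depression, protraction, retraction, upward
rotation, downward rotation) plus rest.

Trial files are plain CSV, one row per sample.  Column names starting with
``emg`` are tagged as EMG channels, names starting with ``acc`` as
accelerometer axes; a ``label`` column is mandatory and uses the 1-based
coding 1..6 for the movements and 7 for rest.  Internally labels are
remapped to 0..5 (movements) and 6 (rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    ConfigError,
    ContractError,
    EmptyStreamError,
    SchemaError,
    ValidationError,
)

EMG = "EMG"
ACC = "ACC"

N_CLASSES = 7
REST_CLASS = 6  # internal coding; file coding is 7
CLASS_NAMES = (
    "elevation",
    "depression",
    "protraction",
    "retraction",
    "upward_rotation",
    "downward_rotation",
    "rest",
)


@dataclass
class TrialRecording:
    """One trial's signal matrix (time x channels) with roles and labels."""

    samples: np.ndarray
    fs: float
    channel_roles: tuple
    labels: np.ndarray
    trial_id: int = 0
    subject_id: int = 0
    channel_names: tuple | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.channel_roles = tuple(self.channel_roles)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (time x channels) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_roles) != self.samples.shape[1]:
            raise ValidationError("one role per channel is required")
        if any(r not in (EMG, ACC) for r in self.channel_roles):
            raise ValidationError(f"channel roles must be {EMG!r} or {ACC!r}")
        if EMG not in self.channel_roles:
            raise ValidationError("at least one EMG channel is required")
        if self.labels.shape != (self.samples.shape[0],):
            raise ValidationError("labels must align with time samples")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValidationError(f"labels must lie in 0..{N_CLASSES - 1}")
        if self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != len(self.channel_roles):
                raise ValidationError("one name per channel is required")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def emg_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == EMG])

    @property
    def acc_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == ACC])


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design: passband edges in Hz and design order.

    ``zero_phase`` applies the filter forward and backward (doubling the
    effective order), which is the conventional reading of a "zero-phase
    Butterworth" in offline EMG processing.
    """

    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ConfigError("filter order must be a positive integer")
        if not (0.0 < self.low_hz < self.high_hz):
            raise ConfigError("require 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2.0:
            raise ConfigError(
                f"passband edge {self.high_hz} Hz reaches Nyquist ({fs / 2} Hz)"
            )


#: EMG band removes motion artefact and ECG contamination below 30 Hz.
EMG_BAND = FilterSpec(30.0, 450.0, order=4)
#: ACC band keeps voluntary-movement dynamics, discarding DC and vibration.
ACC_BAND = FilterSpec(2.0, 20.0, order=4)


def bandpass_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Band-pass filter a 1-D signal, zero phase when ``spec.zero_phase``.

    Edge transients are controlled by reflect-padding (scipy's ``even``
    extension) of roughly one filter length at each end.
    """
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ContractError("bandpass_filter expects a 1-D sequence")
    if x.size <= 3 * spec.order:
        raise ContractError("signal too short for the requested filter order")
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, padtype="even")
    return signal.sosfilt(sos, x)


def filter_trial(
    trial: TrialRecording,
    emg_band: FilterSpec | None = EMG_BAND,
    acc_band: FilterSpec | None = None,
) -> TrialRecording:
    """Apply role-specific band-pass filters to a trial.

    By default only the EMG channels are filtered (30-450 Hz).  The ACC
    channels carry a quasi-static gravity projection that encodes posture;
    band-passing them at 2-20 Hz (``acc_band=ACC_BAND``) removes that
    component, so it is opt-in and off by default in the feature path.
    """
    out = trial.samples.copy()
    for i, role in enumerate(trial.channel_roles):
        band = emg_band if role == EMG else acc_band
        if band is not None:
            out[:, i] = bandpass_filter(trial.samples[:, i], band, trial.fs)
    return replace(trial, samples=out)


@dataclass
class WindowStream:
    """Fixed-length windows cut from one trial, one class label per window."""

    windows: np.ndarray  # (n_windows, window_samples, n_channels)
    wl_ms: float
    stride_ms: float
    labels: np.ndarray
    channel_roles: tuple
    trial_id: int = 0
    subject_id: int = 0

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.channel_roles = tuple(self.channel_roles)
        if self.windows.ndim != 3:
            raise ValidationError("windows must be (n, samples, channels)")
        if self.labels.shape != (self.windows.shape[0],):
            raise ValidationError("one label per window is required")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def emg_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == EMG])

    @property
    def acc_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == ACC])


def _duration_to_samples(ms: float, fs: float, what: str) -> int:
    n = ms * fs / 1000.0
    if abs(n - round(n)) > 1e-9:
        raise ConfigError(f"{what} of {ms} ms is not an integer number of samples at {fs} Hz")
    return int(round(n))


def segment_windows(
    trial: TrialRecording, wl_ms: float, stride_ms: float | None = None
) -> WindowStream:
    """Cut a trial into consecutive windows of ``wl_ms`` milliseconds.

    Windows tile the trial from its start; a trailing partial window is
    dropped.  Each window's label is the majority of its per-sample labels;
    ties go to the label of the centre sample.  The default stride equals
    the window length (non-overlapping windows).
    """
    if stride_ms is None:
        stride_ms = wl_ms
    if stride_ms <= 0:
        raise ConfigError("stride must be positive")
    wl = _duration_to_samples(wl_ms, trial.fs, "window length")
    stride = _duration_to_samples(stride_ms, trial.fs, "stride")
    if wl < 1:
        raise ConfigError("window length must cover at least one sample")
    if trial.n_samples < wl:
        raise EmptyStreamError(
            f"trial of {trial.n_samples} samples is shorter than one {wl}-sample window"
        )
    starts = np.arange(0, trial.n_samples - wl + 1, stride)
    windows = np.stack([trial.samples[s : s + wl] for s in starts])
    labels = np.empty(len(starts), dtype=int)
    for k, s in enumerate(starts):
        seg = trial.labels[s : s + wl]
        counts = np.bincount(seg, minlength=N_CLASSES)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        labels[k] = winners[0] if winners.size == 1 else seg[wl // 2]
    return WindowStream(
        windows=windows,
        wl_ms=wl_ms,
        stride_ms=stride_ms,
        labels=labels,
        channel_roles=trial.channel_roles,
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
    )


@dataclass
class ChannelStack:
    """Per-window expansion of each channel into raw and differenced sequences.

    ``order0`` is the window itself (length l), ``order1`` its first discrete
    difference (length l-1) and ``order2`` the second difference (length l-2),
    all stored time x channels.
    """

    order0: np.ndarray
    order1: np.ndarray
    order2: np.ndarray

    @property
    def nc(self) -> int:
        return self.order0.shape[1]

    def orders(self):
        return (self.order0, self.order1, self.order2)


def expand_derivatives(window: np.ndarray) -> ChannelStack:
    """Expand a window (time x channels) into raw/1st/2nd-difference stacks."""
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.shape[0] < 3:
        raise ContractError("derivative expansion needs at least 3 samples")
    d1 = np.diff(window, axis=0)
    d2 = np.diff(d1, axis=0)
    return ChannelStack(order0=window, order1=d1, order2=d2)


# ---------------------------------------------------------------------------
# trial file I/O


def _infer_roles(columns) -> tuple:
    roles = []
    for name in columns:
        low = name.strip().lower()
        if low.startswith("emg"):
            roles.append(EMG)
        elif low.startswith("acc"):
            roles.append(ACC)
        else:
            roles.append(None)
    return tuple(roles)


def read_trial(
    path,
    schema: dict | None = None,
    trial_id: int = 0,
    subject_id: int = 0,
) -> TrialRecording:
    """Read one trial CSV into a :class:`TrialRecording`.

    ``schema`` may override the defaults with ``{"label": <column name>,
    "fs": <Hz>}``.  Signal columns are recognised by their ``emg``/``acc``
    name prefixes; other columns (e.g. a time stamp) are ignored.  Rows
    containing non-finite signal values are dropped.  File labels use the
    1..7 coding (1..6 movements, 7 rest) and are remapped to 0..6.
    """
    schema = dict(schema or {})
    label_col = schema.get("label", "label")
    fs = float(schema.get("fs", 1000.0))
    df = pd.read_csv(path, float_precision="round_trip")
    if label_col not in df.columns:
        raise SchemaError(f"trial file {path} has no {label_col!r} column")
    roles = _infer_roles(df.columns)
    sig_cols = [c for c, r in zip(df.columns, roles) if r is not None]
    sig_roles = tuple(r for r in roles if r is not None)
    if not sig_cols:
        raise SchemaError(f"trial file {path} declares no emg*/acc* signal columns")
    samples = df[sig_cols].to_numpy(dtype=float)
    raw_labels = df[label_col].to_numpy()
    keep = np.all(np.isfinite(samples), axis=1) & np.isfinite(
        raw_labels.astype(float)
    )
    samples = samples[keep]
    raw_labels = raw_labels[keep].astype(int)
    if raw_labels.size and (raw_labels.min() < 1 or raw_labels.max() > N_CLASSES):
        raise ValidationError(
            f"file labels must lie in 1..{N_CLASSES} (1..6 movements, 7 rest)"
        )
    return TrialRecording(
        samples=samples,
        fs=fs,
        channel_roles=sig_roles,
        labels=raw_labels - 1,
        trial_id=trial_id,
        subject_id=subject_id,
        channel_names=tuple(sig_cols),
    )


def default_channel_names(channel_roles) -> tuple:
    names, n_emg, n_acc = [], 0, 0
    axes = "xyz"
    for role in channel_roles:
        if role == EMG:
            n_emg += 1
            names.append(f"emg{n_emg}")
        else:
            names.append(f"acc{axes[n_acc] if n_acc < 3 else n_acc}")
            n_acc += 1
    return tuple(names)


def write_trial(trial: TrialRecording, path) -> None:
    """Write a trial to CSV in the layout :func:`read_trial` accepts."""
    names = trial.channel_names or default_channel_names(trial.channel_roles)
    df = pd.DataFrame(trial.samples, columns=list(names))
    df["label"] = trial.labels + 1
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# per-channel amplitude standardization (EMG in mV vs ACC in g)


def channel_stats(trials) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation pooled over a list of trials."""
    stacked = np.concatenate([t.samples for t in trials], axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def standardize_trial(
    trial: TrialRecording, mean: np.ndarray, std: np.ndarray
) -> TrialRecording:
    """Standardize each channel with precomputed global statistics.

    Statistics are global per channel (never per window), so within-trial
    offsets — in particular the class-dependent gravity projection on the
    ACC axes — survive as between-window differences.
    """
    return replace(trial, samples=(trial.samples - mean) / std)
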