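"""Signal conditioning: filtering, downsampling, referencing, epoching, rejection.

The conditioning chain mirrors standard endogenous-BCI practice: a
zero-phase 4th-order Butterworth bandpass (1-50 Hz) applied
forward-backward, decimation to 200 Hz, region-wise re-referencing
(common average reference within each 6-channel scalp ROI; for the ear
channels a modified CAR referencing each side to the mean of the three
electrodes on the opposite ear), epoching from -2 to 10 s around task
onset, baseline correction over -2 to 0 s, and peak-to-peak artifact
rejection (a trial is dropped when any channel's within-trial max-min
range strictly exceeds the threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import TASK_CONDITIONS
from .simulate import ContinuousRecording

__all__ = [
    "EpochSet",
    "RejectionReport",
    "bandpass",
    "bandpass_array",
    "downsample",
    "rereference_car",
    "rereference_ear",
    "extract_epochs",
    "baseline_correct",
    "reject_peak_to_peak",
]


@dataclass
class EpochSet:
    """trials x channels x time epochs (uV) with labels and a time axis."""

    data: np.ndarray
    labels: np.ndarray              # per-trial condition label
    channels: tuple[str, ...]
    time_axis: np.ndarray           # seconds relative to task onset
    fs: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channels length must equal channel axis")
        if len(self.time_axis) != self.data.shape[2]:
            raise ValueError("time_axis length must equal time axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, labels) -> np.ndarray:
        if isinstance(labels, str):
            labels = [labels]
        lookup = {ch: i for i, ch in enumerate(self.channels)}
        try:
            return np.array([lookup[ch] for ch in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown channel label {err.args[0]!r}") from None

    def select_channels(self, labels) -> "EpochSet":
        idx = self.channel_index(labels)
        return EpochSet(self.data[:, idx, :].copy(), self.labels.copy(),
                        tuple(labels), self.time_axis.copy(), self.fs)

    def select_trials(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(self.data[indices].copy(), self.labels[indices].copy(),
                        self.channels, self.time_axis.copy(), self.fs)

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples in the half-open window [start, end)."""
        start, end = window
        return (self.time_axis >= start - 1e-9) & (self.time_axis < end - 1e-9)


@dataclass(frozen=True)
class RejectionReport:
    kept_indices: np.ndarray
    rejected_indices: np.ndarray
    threshold: float
    peak_to_peak: np.ndarray        # per-trial max over channels of (max - min)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_indices)


def _butter_sos(lo: float, hi: float, order: int, fs: float):
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band edges ({lo}, {hi}) at fs={fs}")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, fs: float, lo: float, hi: float,
                   order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass of an array."""
    sos = _butter_sos(lo, hi, order, fs)
    return signal.sosfiltfilt(sos, x, axis=axis)


def bandpass(recording: ContinuousRecording, lo: float = 1.0, hi: float = 50.0,
             order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth bandpass of a continuous recording.

    The design order applies to each pass; filtering forward and backward
    doubles the effective magnitude order and cancels the phase response.
    """
    sos = _butter_sos(lo, hi, order, recording.fs)
    out = np.empty_like(recording.data)
    for ch in range(recording.data.shape[0]):    # channel loop caps memory
        out[ch] = signal.sosfiltfilt(sos, recording.data[ch])
    return ContinuousRecording(data=out, fs=recording.fs, montage=recording.montage,
                               schedule=recording.schedule, lowpass_hz=hi)


def downsample(recording: ContinuousRecording, target_fs: float = 200.0) -> ContinuousRecording:
    """Decimate by sample picking after an anti-alias lowpass has been applied."""
    factor = recording.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {recording.fs} not divisible by target_fs {target_fs}")
    if recording.lowpass_hz is None or recording.lowpass_hz > target_fs / 2:
        warnings.warn(
            "downsampling a recording without a prior lowpass below the new "
            "Nyquist frequency; aliasing may occur", UserWarning, stacklevel=2,
        )
    step = int(round(factor))
    return ContinuousRecording(
        data=recording.data[:, ::step].copy(), fs=target_fs,
        montage=recording.montage, schedule=recording.schedule,
        lowpass_hz=recording.lowpass_hz,
    )


def _group_rows(channels, group) -> np.ndarray:
    lookup = {ch: i for i, ch in enumerate(channels)}
    try:
        return np.array([lookup[ch] for ch in group], dtype=int)
    except KeyError as err:
        raise KeyError(f"unknown channel label {err.args[0]!r}") from None


def rereference_car(data: np.ndarray, channels, group) -> np.ndarray:
    """Common average reference within ``group``; other channels untouched.

    ``data`` may be 2-D (channels x samples) or 3-D (trials x channels x
    samples); the channel axis is the second-to-last.
    """
    if len(group) == 0:
        raise ValueError("reference group must be nonempty")
    rows = _group_rows(channels, group)
    out = np.array(data, copy=True)
    sub = np.take(out, rows, axis=-2)
    mean = sub.mean(axis=-2, keepdims=True)
    sub = sub - mean
    index = [slice(None)] * out.ndim
    index[-2] = rows
    out[tuple(index)] = sub
    return out


def rereference_ear(data: np.ndarray, channels, left, right,
                    strict: bool = True) -> np.ndarray:
    """Modified CAR for ear channels: each side referenced to the opposite
    ear's mean, computed from the pre-reference values."""
    if strict and (len(left) != 3 or len(right) != 3):
        raise ValueError("left and right ear groups must have 3 channels each "
                         "(pass strict=False to override)")
    lrows = _group_rows(channels, left)
    rrows = _group_rows(channels, right)
    out = np.array(data, copy=True)
    lmean = np.take(data, lrows, axis=-2).mean(axis=-2, keepdims=True)
    rmean = np.take(data, rrows, axis=-2).mean(axis=-2, keepdims=True)
    for rows, ref in ((lrows, rmean), (rrows, lmean)):
        index = [slice(None)] * out.ndim
        index[-2] = rows
        out[tuple(index)] = np.take(data, rows, axis=-2) - ref
    return out


def extract_epochs(recording: ContinuousRecording,
                   window: tuple[float, float] = (-2.0, 10.0),
                   task_labels=TASK_CONDITIONS) -> EpochSet:
    """One epoch per task event, half-open sample window relative to onset."""
    start, end = window
    if end <= start:
        raise ValueError("epoch window must have positive length")
    fs = recording.fs
    i_start = int(round(start * fs))
    i_stop = int(round(end * fs))
    n_time = i_stop - i_start
    events = recording.schedule.events_of(*task_labels)
    if not events:
        raise ValueError(f"schedule contains no events with labels {task_labels}")
    trials, labels = [], []
    for k, ev in enumerate(events):
        onset = int(round(ev.onset * fs))
        j0, j1 = onset + i_start, onset + i_stop
        if j0 < 0 or j1 > recording.n_samples:
            raise ValueError(
                f"epoch window {window} for trial {k} ({ev.label} at {ev.onset} s) "
                "exceeds recording bounds")
        trials.append(recording.data[:, j0:j1])
        labels.append(ev.label)
    time_axis = (np.arange(n_time) + i_start) / fs
    return EpochSet(data=np.stack(trials), labels=np.array(labels),
                    channels=tuple(recording.montage.channels),
                    time_axis=time_axis, fs=fs)


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-2.0, 0.0)) -> EpochSet:
    """Subtract each trial's and channel's mean over the baseline window."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside epoch time axis")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.labels.copy(), epochs.channels,
                    epochs.time_axis.copy(), epochs.fs)


def reject_peak_to_peak(epochs: EpochSet, threshold: float = 126.67,
                        channels=None) -> tuple[EpochSet, RejectionReport]:
    """Drop trials whose max channel peak-to-peak strictly exceeds ``threshold``.

    ``channels`` restricts the search scope (e.g. the ROI channels only);
    the default scans every channel in the epochs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    idx = (np.arange(len(epochs.channels)) if channels is None
           else epochs.channel_index(channels))
    ptp = np.ptp(epochs.data[:, idx, :], axis=2).max(axis=1)
    kept = np.flatnonzero(ptp <= threshold)
    rejected = np.flatnonzero(ptp > threshold)
    if len(kept) == 0:
        raise ValueError(f"all {epochs.n_trials} trials exceed the "
                         f"{threshold} uV peak-to-peak threshold")
    report = RejectionReport(kept_indices=kept, rejected_indices=rejected,
                             threshold=threshold, peak_to_peak=ptp)
    return epochs.select_trials(kept), report
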