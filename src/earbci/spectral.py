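"""Time-frequency analysis: STFT power, eyes-closed/eyes-open alpha SNR,
and event-related (de)synchronization maps.

The EC/EO contrast is summarized per region of interest as

    SNR = 10 * log10(alpha_EC / alpha_EO)   [dB]

where alpha_EC / alpha_EO are mean 8-13 Hz STFT powers (1 s Hann window,
50% overlap) over eyes-closed / eyes-open frames, averaged over the six
ROI channels in the power domain before the dB transform.

ERD/ERS maps express band power as percent change against a pre-task
baseline: value(f, t) = 100 * (P(f,t) - R(f)) / R(f), with P the
trial-averaged narrow-band power envelope (1 Hz-wide zero-phase bandpass
+ squared analytic-signal magnitude) and R(f) its mean over the baseline
window.  Desynchronization (ERD) is negative, synchronization (ERS)
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .montage import Montage
from .preprocessing import EpochSet, rereference_car, rereference_ear
from .simulate import ContinuousRecording

__all__ = [
    "TimeFreqMap",
    "SNRResult",
    "ErdErsMap",
    "stft_power",
    "snr_db",
    "ec_eo_snr",
    "erders_map",
    "roi_average_map",
]


@dataclass
class TimeFreqMap:
    power: np.ndarray           # [... x] frequency x time, uV^2
    freqs: np.ndarray           # Hz
    times: np.ndarray           # window centers, s
    name: str = ""

    def __post_init__(self) -> None:
        if self.power.shape[-2:] != (len(self.freqs), len(self.times)):
            raise ValueError("power trailing shape must match (freqs, times)")
        if (self.power < 0).any():
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class SNRResult:
    roi: str
    alpha_ec: float             # mean alpha power eyes-closed, uV^2
    alpha_eo: float             # mean alpha power eyes-open, uV^2
    snr_db: float               # 10*log10(alpha_ec/alpha_eo)


@dataclass
class ErdErsMap:
    values: np.ndarray          # frequency x time, percent change vs baseline
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple[float, float]
    name: str = ""

    def band_mean(self, band: tuple[float, float],
                  window: tuple[float, float] | None = None) -> float:
        """Mean map value over a frequency band and (optionally) time window."""
        fmask = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if window is None:
            tmask = np.ones_like(self.times, dtype=bool)
        else:
            tmask = (self.times >= window[0]) & (self.times < window[1])
        return float(self.values[np.ix_(fmask, tmask)].mean())


def stft_power(x: np.ndarray, fs: float, win_s: float = 1.0,
               overlap: float = 0.5, name: str = "") -> TimeFreqMap:
    """Magnitude-squared short-time Fourier transform with a Hann taper.

    Frames advance by ``win_s * (1 - overlap)``; frequency resolution is
    1/win_s.  Reported times are window centers.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(win_s * fs))
    if nperseg < 2:
        raise ValueError("window must span at least 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if x.shape[-1] < nperseg:
        raise ValueError("signal shorter than one window")
    noverlap = int(round(overlap * nperseg))
    freqs, times, spec = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="spectrum", mode="magnitude",
    )
    return TimeFreqMap(power=spec**2, freqs=freqs, times=times, name=name)


def snr_db(alpha_ec: float, alpha_eo: float) -> float:
    """Eyes-closed over eyes-open alpha power ratio in decibels."""
    if alpha_ec <= 0 or alpha_eo <= 0:
        raise ValueError("alpha powers must be strictly positive")
    return float(10.0 * np.log10(alpha_ec / alpha_eo))


def _rereference_roi(data: np.ndarray, channels, montage: Montage, roi: str) -> np.ndarray:
    """CAR within a scalp group; modified (cross-ear) CAR for the ear ROI."""
    group = montage.analysis_groups(include_scalp=True)[roi]
    if roi == "ear":
        return rereference_ear(data, channels, montage.ear_left, montage.ear_right)
    return rereference_car(data, channels, group)


def ec_eo_snr(recording: ContinuousRecording, montage: Montage | None = None,
              alpha_band: tuple[float, float] = (8.0, 13.0),
              win_s: float = 1.0, overlap: float = 0.5,
              rois=None) -> dict[str, SNRResult]:
    """Per-ROI alpha SNR of an EC/EO recording.

    Each ROI is re-referenced (CAR, or cross-ear modified CAR for the ear
    ROI), each of its channels is STFT-transformed, and alpha-band power
    is averaged over condition frames and over the six channels in the
    power domain; the EC/EO ratio is then expressed in dB.  A frame is
    assigned to a condition only when its full window lies inside one
    block.
    """
    montage = montage or recording.montage
    rois = list(rois) if rois is not None else list(montage.rois)
    ec_events = recording.schedule.events_of("EC")
    eo_events = recording.schedule.events_of("EO")
    if not ec_events or not eo_events:
        raise ValueError("schedule must contain both EC and EO events")

    results: dict[str, SNRResult] = {}
    frame_masks = None
    for roi in rois:
        reref = _rereference_roi(recording.data, recording.montage.channels,
                                 montage, roi)
        rows = recording.montage.index(montage.analysis_groups(True)[roi])
        tf = stft_power(reref[rows], recording.fs, win_s, overlap, name=roi)
        if frame_masks is None:
            starts = tf.times - win_s / 2.0
            stops = tf.times + win_s / 2.0
            def _mask(events):
                m = np.zeros(len(tf.times), dtype=bool)
                for ev in events:
                    m |= (starts >= ev.onset - 1e-9) & (stops <= ev.offset + 1e-9)
                return m
            frame_masks = (_mask(ec_events), _mask(eo_events))
        fmask = (tf.freqs >= alpha_band[0]) & (tf.freqs <= alpha_band[1])
        alpha = tf.power[:, fmask, :].mean(axis=1)      # channels x frames
        ec = float(alpha[:, frame_masks[0]].mean())
        eo = float(alpha[:, frame_masks[1]].mean())
        results[roi] = SNRResult(roi=roi, alpha_ec=ec, alpha_eo=eo,
                                 snr_db=snr_db(ec, eo))
    return results


def erders_map(epochs: EpochSet, baseline: tuple[float, float] = (-2.0, 0.0),
               freq_range: tuple[float, float] = (1.0, 50.0),
               step: float = 1.0, filter_order: int = 2) -> dict[str, ErdErsMap]:
    """Per-channel ERD/ERS maps over 1 Hz-wide bands.

    For every band center f the epochs are zero-phase bandpassed to
    (f - step/2, f + step/2), the squared analytic-signal magnitude gives
    the instantaneous power envelope, and envelopes are averaged over
    trials.  Values are percent change against the mean over the baseline
    window.
    """
    if epochs.n_trials == 0:
        raise ValueError("empty trial set")
    bmask = epochs.time_mask(baseline)
    if not bmask.any():
        raise ValueError(f"baseline window {baseline} outside epoch time axis")
    centers = np.arange(freq_range[0], freq_range[1] + 1e-9, step)
    n_time = epochs.data.shape[2]
    # reflect-pad ~1 s per side so narrow-band filter/Hilbert edge
    # transients fall outside the analyzed window
    n_pad = min(int(round(epochs.fs)), n_time - 1)
    padded = np.pad(epochs.data, ((0, 0), (0, 0), (n_pad, n_pad)), mode="reflect")
    nfft = next_fast_len(padded.shape[2])
    power = np.empty((len(centers), len(epochs.channels), n_time))
    for i, f in enumerate(centers):
        lo = max(f - step / 2.0, 0.05)
        hi = min(f + step / 2.0, epochs.fs / 2.0 - 0.05)
        sos = signal.butter(filter_order, [lo, hi], btype="bandpass",
                            fs=epochs.fs, output="sos")
        narrow = signal.sosfiltfilt(sos, padded, axis=2)
        analytic = signal.hilbert(narrow, N=nfft, axis=2)[..., n_pad:n_pad + n_time]
        power[i] = (np.abs(analytic) ** 2).mean(axis=0)     # avg over trials
    maps: dict[str, ErdErsMap] = {}
    for c, ch in enumerate(epochs.channels):
        p = power[:, c, :]
        ref = p[:, bmask].mean(axis=1, keepdims=True)
        maps[ch] = ErdErsMap(values=100.0 * (p - ref) / ref, freqs=centers,
                             times=epochs.time_axis.copy(), baseline=baseline,
                             name=ch)
    return maps


def roi_average_map(maps: dict[str, ErdErsMap] | list[ErdErsMap],
                    roi_channels=None, name: str = "") -> ErdErsMap:
    """Element-wise mean of per-channel ERD/ERS maps over a ROI."""
    if isinstance(maps, dict):
        if roi_channels is None:
            selected = list(maps.values())
        else:
            missing = [ch for ch in roi_channels if ch not in maps]
            if missing:
                raise KeyError(f"missing channel maps: {missing}")
            selected = [maps[ch] for ch in roi_channels]
    else:
        selected = list(maps)
    if not selected:
        raise ValueError("no maps to average")
    first = selected[0]
    for m in selected[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("maps must share shape")
    values = np.mean([m.values for m in selected], axis=0)
    return ErdErsMap(values=values, freqs=first.freqs.copy(),
                     times=first.times.copy(), baseline=first.baseline, name=name)
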