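"""Synthetic multichannel EEG with known, recoverable effect structure.

The generator realizes the statistical structure the downstream analysis
assumes, so every stage can be validated against ground truth:

* 1/f ("pink") background noise, independent per channel;
* a bilateral pair of occipital alpha sources (amplitude-modulated
  ~10 Hz sinusoids with slow frequency jitter) whose projection onto the
  electrodes decays exponentially with 2-D scalp distance, giving the
  leakage ordering occipital >> ear > central > frontal;
* a bilateral pair of fronto-central broadband beta/gamma (14-50 Hz)
  noise sources, so beta/gamma effects are strongest fronto-centrally;
* condition modulation: eyes-closed multiplies the alpha amplitude by
  ``ec_alpha_gain``; mental arithmetic multiplies alpha amplitude by
  ``ma_alpha_ers`` (alpha ERS) and beta/gamma source *power* by
  ``ma_beta_gamma_erd`` (broadband ERD); the light-cognitive task applies
  a mild ``lc_alpha_gain`` only.  Envelopes ramp over ~0.5 s
  (raised-cosine smoothing) at event edges;
* per-event lognormal jitter of the condition gains (attention varies
  from trial to trial); exactly zero when a gain is 1, so null worlds
  stay null;
* optional frontal-dominant eye-blink transients for testing artifact
  rejection.

A bilateral source pair (rather than a single midline source) is
essential: the ear channels are re-referenced to the mean of the
*opposite* ear, and a midline source projects mirror-symmetrically onto
the two ears, which would cancel nearly all ear-channel alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import Montage, Schedule, build_default_montage

__all__ = [
    "SimulationConfig",
    "ContinuousRecording",
    "pink_noise",
    "simulate_recording",
    "inject_blinks",
]

# source coordinates in the montage's 2-D layout
_ALPHA_SOURCE_POS = ((-0.30, -0.95), (0.30, -0.95))   # bilateral occipital
_BG_SOURCE_POS = ((-0.40, 0.50), (0.40, 0.50))        # bilateral fronto-central


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic EEG world (amplitudes in uV, rates in Hz).

    The condition gains are multiplicative on source *amplitude* except
    ``ma_beta_gamma_erd`` which is a *power* attenuation in (0, 1].
    """

    fs: float = 1000.0
    noise_exponent: float = 1.0
    noise_scale: float = 5.0            # per-channel 1/f noise RMS, uV
    alpha_freq: float = 10.0
    alpha_amplitude: float = 10.0       # per-source baseline amplitude, uV
    beta_gamma_amplitude: float = 14.0  # per-source broadband RMS, uV
    roi_alpha_gain: dict = field(
        default_factory=lambda: {"frontal": 1.0, "central": 1.0, "occipital": 1.0, "ear": 1.0}
    )
    ec_alpha_gain: float = 2.0
    ma_alpha_ers: float = 1.8
    ma_beta_gamma_erd: float = 0.7
    lc_alpha_gain: float = 1.1
    trial_gain_jitter: float = 0.7      # task-engagement jitter of log-gains per trial
    envelope_jitter: float = 0.25       # slow waxing/waning of alpha amplitude
    freq_jitter: float = 0.5            # max alpha frequency excursion, Hz
    blink_rate: float = 0.0             # events/min (used by the pipeline)
    blink_amplitude: float = 180.0      # uV at the frontopolar maximum
    mixing_spread: float = 0.6          # exponential distance-decay constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * 50.0:
            raise ValueError("fs must exceed twice the 50 Hz analysis band edge")
        for name in ("ec_alpha_gain", "ma_alpha_ers", "lc_alpha_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.ma_beta_gamma_erd <= 1:
            raise ValueError("ma_beta_gamma_erd must be in (0, 1]")
        if any(g <= 0 for g in self.roi_alpha_gain.values()):
            raise ValueError("roi_alpha_gain values must be > 0")


@dataclass
class ContinuousRecording:
    """channels x samples EEG (uV) with its montage and event schedule."""

    data: np.ndarray
    fs: float
    montage: Montage
    schedule: Schedule
    lowpass_hz: float | None = None     # set by bandpass(); downsample() checks it

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(), fs=self.fs, montage=self.montage,
            schedule=self.schedule, lowpass_hz=self.lowpass_hz,
        )


def pink_noise(n_channels: int, n_samples: int, exponent: float = 1.0,
               seed: int = 0) -> np.ndarray:
    """Zero-mean 1/f^exponent noise, unit RMS per channel, channel-independent.

    Generated by spectrally shaping white Gaussian noise (FFT domain);
    ``exponent=0`` reduces to white noise.
    """
    if n_channels < 1 or n_samples < 2:
        raise ValueError("need n_channels >= 1 and n_samples >= 2")
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    rng = np.random.default_rng(seed)
    nfft = next_fast_len(n_samples)
    freqs = rfftfreq(nfft, d=1.0)               # relative frequency scale
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    out = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        white = rng.standard_normal(nfft)
        spec = rfft(white) * shaping
        x = irfft(spec, n=nfft)[:n_samples]
        x -= x.mean()
        out[ch] = x / x.std()
    return out


def _smooth_ramp(envelope: np.ndarray, fs: float, ramp_s: float = 0.5) -> np.ndarray:
    """Raised-cosine smoothing of a piecewise-constant envelope (~ramp_s edges)."""
    n = max(3, int(round(ramp_s * fs)))
    if n % 2 == 0:
        n += 1
    kernel = np.hanning(n + 2)[1:-1]
    kernel /= kernel.sum()
    padded = np.pad(envelope, (n // 2, n // 2), mode="edge")
    return signal.fftconvolve(padded, kernel, mode="valid")


def _slow_noise(n_samples: int, fs: float, corr_s: float, rng) -> np.ndarray:
    """Unit-variance smooth noise with ~corr_s correlation time (linear interp)."""
    n_knots = max(int(np.ceil(n_samples / fs / corr_s)) + 2, 4)
    knots = rng.standard_normal(n_knots)
    t_knots = np.arange(n_knots) * corr_s
    t = np.arange(n_samples) / fs
    return np.interp(t, t_knots, knots)


def _condition_envelopes(schedule: Schedule, n_samples: int, fs: float,
                         config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (alpha_gain, beta_gamma_amplitude_gain) envelopes.

    Task (MA/LC) gains are jittered per trial on the log scale
    (gain -> gain**(1 + jitter*z)), modelling trial-to-trial variation
    in task engagement; this leaves unit gains exactly unmodulated, so
    null worlds stay null.  The eyes-closed alpha increase is treated as
    automatic and is not jittered.
    """
    alpha = np.ones(n_samples)
    bg = np.ones(n_samples)
    alpha_gain_of = {"EC": config.ec_alpha_gain, "MA": config.ma_alpha_ers,
                     "LC": config.lc_alpha_gain}
    for ev in schedule.events:
        i0 = int(round(ev.onset * fs))
        i1 = min(int(round(ev.offset * fs)), n_samples)
        if i1 <= i0:
            continue
        z_a, z_b = rng.standard_normal(2)
        jit = config.trial_gain_jitter if ev.label in ("MA", "LC") else 0.0
        g = alpha_gain_of.get(ev.label, 1.0)
        if g != 1.0:
            alpha[i0:i1] = g ** (1.0 + jit * z_a)
        if ev.label == "MA" and config.ma_beta_gamma_erd != 1.0:
            att = config.ma_beta_gamma_erd ** (1.0 + jit * z_b)
            bg[i0:i1] = np.sqrt(att)    # amplitude gain for a power attenuation
    return _smooth_ramp(alpha, fs), _smooth_ramp(bg, fs)


def _mixing_weights(montage: Montage, source_pos, spread: float) -> np.ndarray:
    """channels x sources exponential distance-decay mixing matrix."""
    pos = np.array([montage.positions[ch] for ch in montage.channels])
    src = np.asarray(source_pos, dtype=float)
    dist = np.linalg.norm(pos[:, None, :] - src[None, :, :], axis=2)
    return np.exp(-dist / spread)


def _roi_gain_vector(montage: Montage, roi_gain: dict) -> np.ndarray:
    gains = np.ones(montage.n_channels)
    for roi, g in roi_gain.items():
        gains[montage.index(montage.rois[roi])] = g
    return gains


def simulate_recording(montage: Montage | None, schedule: Schedule,
                       config: SimulationConfig | None = None) -> ContinuousRecording:
    """Simulate a continuous recording realizing ``schedule`` under ``config``."""
    if montage is None:
        montage = build_default_montage()
    if config is None:
        config = SimulationConfig()
    fs = config.fs
    n_samples = int(round(schedule.total_duration * fs))
    if n_samples < 2:
        raise ValueError("schedule too short to simulate")
    ss = np.random.SeedSequence(config.seed)
    s_noise, s_env, s_alpha, s_bg = ss.spawn(4)
    rng_env = np.random.default_rng(s_env)
    rng_alpha = np.random.default_rng(s_alpha)
    rng_bg = np.random.default_rng(s_bg)

    alpha_env, bg_env = _condition_envelopes(schedule, n_samples, fs, config, rng_env)

    w_alpha = _mixing_weights(montage, _ALPHA_SOURCE_POS, config.mixing_spread)
    w_alpha *= _roi_gain_vector(montage, config.roi_alpha_gain)[:, None]
    w_bg = _mixing_weights(montage, _BG_SOURCE_POS, config.mixing_spread)

    data = pink_noise(montage.n_channels, n_samples,
                      exponent=config.noise_exponent,
                      seed=s_noise.generate_state(1)[0] & 0x7FFFFFFF)
    data *= config.noise_scale

    # bilateral alpha sources: slow frequency jitter + waxing/waning amplitude
    t = np.arange(n_samples) / fs
    for k in range(w_alpha.shape[1]):
        jitter = _slow_noise(n_samples, fs, corr_s=1.0, rng=rng_alpha)
        freq = config.alpha_freq + np.clip(0.5 * config.freq_jitter * jitter,
                                           -config.freq_jitter, config.freq_jitter)
        phase = 2 * np.pi * (np.cumsum(freq) / fs + rng_alpha.uniform())
        wax = 1.0 + config.envelope_jitter * _slow_noise(n_samples, fs, 1.0, rng_alpha)
        wax = np.clip(wax, 0.05, None)
        source = config.alpha_amplitude * alpha_env * wax * np.sin(phase)
        data += np.outer(w_alpha[:, k], source)

    # bilateral broadband beta/gamma sources (band-limited Gaussian noise)
    sos = signal.butter(4, [14.0, 50.0], btype="bandpass", fs=fs, output="sos")
    for k in range(w_bg.shape[1]):
        raw = rng_bg.standard_normal(n_samples)
        band = signal.sosfiltfilt(sos, raw)
        band /= band.std()
        source = config.beta_gamma_amplitude * bg_env * band
        data += np.outer(w_bg[:, k], source)

    return ContinuousRecording(data=data, fs=fs, montage=montage, schedule=schedule)


def inject_blinks(recording: ContinuousRecording, rate: float,
                  amplitude: float, seed: int = 0):
    """Add frontal-dominant ~300 ms blink transients at Poisson times.

    Returns ``(contaminated_copy, blink_times_s)``.  The spatial profile
    decays exponentially from the frontopolar midline and is normalized
    so the most frontal channels (Fp1/Fp2) receive the full ``amplitude``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = recording.copy()
    if rate == 0:
        return out, np.array([])
    rng = np.random.default_rng(seed)
    dur = recording.duration
    n_blinks = rng.poisson(rate * dur / 60.0)
    if n_blinks == 0:
        return out, np.array([])
    times = np.sort(rng.uniform(0.3, max(dur - 0.3, 0.3), size=n_blinks))

    pos = np.array([recording.montage.positions[ch] for ch in recording.montage.channels])
    dist = np.linalg.norm(pos - np.array([0.0, 1.0]), axis=1)
    profile = np.exp(-(dist - dist.min()) / 0.6)    # 1.0 at Fp1/Fp2

    n_pulse = int(round(0.3 * recording.fs))
    pulse = amplitude * np.hanning(n_pulse)
    for t0 in times:
        i0 = int(round(t0 * recording.fs)) - n_pulse // 2
        j0, j1 = max(i0, 0), min(i0 + n_pulse, out.n_samples)
        if j1 <= j0:
            continue
        out.data[:, j0:j1] += np.outer(profile, pulse[j0 - i0:j1 - i0])
    return out, times
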