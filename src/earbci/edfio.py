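"""Minimal European Data Format (EDF) writer/reader for simulated recordings.

Implements the plain EDF layout (ASCII fixed-width header + 16-bit
little-endian integer data records with per-signal physical scaling),
sufficient to round-trip the simulator's output with standard EEG
software.  One data record spans 1 s, so the sampling rate must be a
positive integer; the signal is zero-padded to a whole number of
records on write and trimmed on read.

Amplitude resolution is (physical range)/(2^16 - 1) per channel, i.e.
round-trip error is bounded by half that quantization step.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_labels,
              physical_dim: str = "uV", patient: str = "X", recording: str = "X",
              start: _dt.datetime | None = None) -> None:
    """Write channels x samples data (physical units) as a plain EDF file."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_signals, n_samples = data.shape
    if len(channel_labels) != n_signals:
        raise ValueError("one label per channel required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("fs must be a positive integer (1 s data records)")
    spr = int(round(fs))                       # samples per record per signal
    n_records = int(np.ceil(n_samples / spr))
    start = start or _dt.datetime(2000, 1, 1)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    header_bytes = 256 * (1 + n_signals)
    parts = [
        _field("0", 8),
        _field(patient, 80),
        _field(recording, 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(header_bytes, 8),
        _field("", 44),
        _field(n_records, 8),
        _field("1", 8),                         # record duration, s
        _field(n_signals, 4),
    ]
    for label in channel_labels:
        parts.append(_field(label, 16))
    parts += [_field("", 80)] * n_signals       # transducer
    parts += [_field(physical_dim, 8)] * n_signals
    for v in phys_min:
        parts.append(_field(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        parts.append(_field(f"{v:.8g}"[:8], 8))
    parts += [_field(_DIG_MIN, 8)] * n_signals
    parts += [_field(_DIG_MAX, 8)] * n_signals
    parts += [_field("", 80)] * n_signals       # prefiltering
    parts += [_field(spr, 8)] * n_signals
    parts += [_field("", 32)] * n_signals       # reserved

    # re-parse the truncated 8-char physical bounds so scaling is self-consistent
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    pmax = np.where(pmax - pmin < 1e-12, pmin + 1.0, pmax)
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)

    padded = np.zeros((n_signals, n_records * spr))
    padded[:, :n_samples] = data
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for rec in range(n_records):
            block = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path):
    """Read a plain EDF file -> (data channels x samples, fs, labels)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode("ascii"))
        record_dur = float(head[244:252].decode("ascii"))
        n_signals = int(head[252:256].decode("ascii"))
        sig = fh.read(256 * n_signals)

        # per-signal field offsets in bytes within the signal header block
        labels = [sig[i * 16:(i + 1) * 16].decode("ascii").strip()
                  for i in range(n_signals)]
        off = 16 * n_signals + 80 * n_signals + 8 * n_signals
        def block(start, width):
            return [sig[start + i * width: start + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_signals)]
        pmin = np.array([float(v) for v in block(off, 8)])
        pmax = np.array([float(v) for v in block(off + 8 * n_signals, 8)])
        dmin = np.array([float(v) for v in block(off + 16 * n_signals, 8)])
        dmax = np.array([float(v) for v in block(off + 24 * n_signals, 8)])
        spr_off = off + 32 * n_signals + 80 * n_signals
        spr = np.array([int(v) for v in block(spr_off, 8)])
        if len(set(spr.tolist())) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr0 = int(spr[0])
        fs = spr0 / record_dur

        raw = np.frombuffer(fh.read(), dtype="<i2")
    raw = raw[: n_records * n_signals * spr0]
    raw = raw.reshape(n_records, n_signals, spr0)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return data, fs, labels
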