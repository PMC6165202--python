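"""Electrode montage, regions of interest, and experimental schedules.

The recording setup is a 31-channel montage: 25 scalp electrodes placed
according to the international 10-20 system plus six electrodes attached
behind the ears (three per side, labelled L1-L3 and R1-R3).  For analysis
the channels are grouped into four regions of interest (ROIs) of six
electrodes each: frontal, central, occipital, and ear.  Seven scalp
channels (Fz, Cz, CP1, CP2, Pz, P7, P8) belong to no ROI.

Two experimental paradigms are represented as event schedules:

* an eyes-closed / eyes-open (EC/EO) resting paradigm of alternating
  30 s blocks, EC first, repeated six times;
* a mental-arithmetic vs. light-cognitive (MA/LC) task paradigm of five
  sessions, each holding 10 MA and 10 LC trials in randomized order.
  A trial is 5 s instruction, 10 s task, and a uniformly drawn
  10-15 s rest; each session opens with a 15 s initial rest
  (5 s blank + 10 s rest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "Schedule",
    "ScheduleEvent",
    "build_default_montage",
    "generate_ec_eo_schedule",
    "generate_main_schedule",
]

#: valid condition labels for schedule events
CONDITIONS = ("EC", "EO", "MA", "LC", "REST", "INSTRUCTION")

#: task conditions that define epochs in the main experiment
TASK_CONDITIONS = ("MA", "LC")

# Approximate 2-D projections of the electrode positions on a unit-radius
# head (x: left->right, y: posterior->anterior).  The ear electrodes sit
# behind the ears, below the T7/T8 line and slightly outside the head
# circle.  Only relative distances matter (source mixing in the
# simulator); these are not calibrated head-surface coordinates.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "Fz": (0.0, 0.50), "F3": (-0.40, 0.52), "F4": (0.40, 0.52),
    "F7": (-0.81, 0.59), "F8": (0.81, 0.59),
    "FC5": (-0.78, 0.30), "FC6": (0.78, 0.30),
    "Cz": (0.0, 0.0), "C3": (-0.50, 0.0), "C4": (0.50, 0.0),
    "T7": (-1.00, 0.0), "T8": (1.00, 0.0),
    "CP1": (-0.28, -0.28), "CP2": (0.28, -0.28),
    "Pz": (0.0, -0.50), "P3": (-0.40, -0.52), "P4": (0.40, -0.52),
    "P7": (-0.81, -0.59), "P8": (0.81, -0.59),
    "PO7": (-0.62, -0.78), "PO8": (0.62, -0.78),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "L1": (-1.00, -0.30), "L2": (-1.05, -0.45), "L3": (-1.00, -0.60),
    "R1": (1.00, -0.30), "R2": (1.05, -0.45), "R3": (1.00, -0.60),
}

_SCALP_CHANNELS = [
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "Cz", "C3", "C4", "T7", "T8", "CP1", "CP2",
    "Pz", "P3", "P4", "P7", "P8", "PO7", "PO8", "O1", "O2",
]

_ROIS = {
    "frontal": ["Fp1", "Fp2", "F3", "F4", "F7", "F8"],
    "central": ["FC5", "FC6", "C3", "C4", "T7", "T8"],
    "occipital": ["P3", "P4", "PO7", "PO8", "O1", "O2"],
    "ear": ["R1", "R2", "R3", "L1", "L2", "L3"],
}


@dataclass(frozen=True)
class Montage:
    """Channel labels, ear groups and ROI membership.

    Attributes
    ----------
    channels
        Ordered list of all channel labels (scalp first, then ears).
    ear_left, ear_right
        The three behind-the-ear labels on each side.
    rois
        Mapping ROI name -> list of 6 member channel labels.
    positions
        2-D layout coordinates used by the simulator's mixing model.
    """

    channels: tuple[str, ...]
    ear_left: tuple[str, ...]
    ear_right: tuple[str, ...]
    rois: dict[str, tuple[str, ...]]
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        ears = set(self.ear_left) | set(self.ear_right)
        for name, labels in self.rois.items():
            missing = set(labels) - set(self.channels)
            if missing:
                raise ValueError(f"ROI {name!r} references unknown channels {sorted(missing)}")
        if "ear" in self.rois and not set(self.rois["ear"]) <= ears:
            raise ValueError("ear ROI must be a subset of ear_left + ear_right")
        all_roi = [ch for labels in self.rois.values() for ch in labels]
        if len(all_roi) != len(set(all_roi)):
            raise ValueError("ROIs must be disjoint")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        ears = set(self.ear_left) | set(self.ear_right)
        return tuple(ch for ch in self.channels if ch not in ears)

    def index(self, labels) -> np.ndarray:
        """Row indices of ``labels`` (a label or sequence) in ``channels``."""
        if isinstance(labels, str):
            labels = [labels]
        lookup = {ch: i for i, ch in enumerate(self.channels)}
        try:
            return np.array([lookup[ch] for ch in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown channel label {err.args[0]!r}") from None

    def analysis_groups(self, include_scalp: bool = False) -> dict[str, tuple[str, ...]]:
        """ROIs for analysis; optionally add the 25-scalp-channel pseudo-ROI.

        The "scalp" group is the all-scalp reference condition (CAR over
        the 25 scalp electrodes, ear electrodes excluded).
        """
        groups = dict(self.rois)
        if include_scalp:
            groups["scalp"] = self.scalp_channels
        return groups

    def to_json(self, path) -> None:
        payload = {
            "channels": list(self.channels),
            "ear_left": list(self.ear_left),
            "ear_right": list(self.ear_right),
            "rois": {k: list(v) for k, v in self.rois.items()},
            "positions": {k: list(v) for k, v in self.positions.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            channels=tuple(payload["channels"]),
            ear_left=tuple(payload["ear_left"]),
            ear_right=tuple(payload["ear_right"]),
            rois={k: tuple(v) for k, v in payload["rois"].items()},
            positions={k: tuple(v) for k, v in payload.get("positions", {}).items()},
        )


def build_default_montage() -> Montage:
    """The 31-channel scalp + behind-ear montage with its four ROIs."""
    channels = tuple(_SCALP_CHANNELS + ["R1", "R2", "R3", "L1", "L2", "L3"])
    return Montage(
        channels=channels,
        ear_left=("L1", "L2", "L3"),
        ear_right=("R1", "R2", "R3"),
        rois={k: tuple(v) for k, v in _ROIS.items()},
        positions=dict(CHANNEL_POSITIONS),
    )


@dataclass(frozen=True)
class ScheduleEvent:
    label: str
    onset: float        # seconds
    duration: float     # seconds

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Schedule:
    """Ordered, non-overlapping condition events spanning a recording."""

    events: tuple[ScheduleEvent, ...]
    total_duration: float

    def __post_init__(self) -> None:
        last_off = 0.0
        for ev in self.events:
            if ev.label not in CONDITIONS:
                raise ValueError(f"unknown condition label {ev.label!r}")
            if ev.onset < last_off - 1e-9:
                raise ValueError("events overlap or are unsorted")
            if ev.duration <= 0 or ev.onset < 0:
                raise ValueError("onsets must be >= 0 and durations > 0")
            last_off = ev.offset
        if self.total_duration < last_off - 1e-9:
            raise ValueError("total_duration shorter than last event offset")

    def events_of(self, *labels: str) -> list[ScheduleEvent]:
        return [ev for ev in self.events if ev.label in labels]

    def count(self, label: str) -> int:
        return sum(1 for ev in self.events if ev.label == label)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "label": [ev.label for ev in self.events],
                "onset_s": [ev.onset for ev in self.events],
                "duration_s": [ev.duration for ev in self.events],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, total_duration: float | None = None) -> "Schedule":
        df = pd.read_csv(path)
        events = tuple(
            ScheduleEvent(str(r.label), float(r.onset_s), float(r.duration_s))
            for r in df.itertuples()
        )
        if total_duration is None:
            total_duration = events[-1].offset if events else 0.0
        return cls(events=events, total_duration=total_duration)


def generate_ec_eo_schedule(block_s: float = 30.0, reps: int = 6) -> Schedule:
    """Alternating eyes-closed / eyes-open blocks, EC first, contiguous."""
    if block_s <= 0 or reps < 1:
        raise ValueError("block_s must be > 0 and reps >= 1")
    events = []
    t = 0.0
    for _ in range(reps):
        events.append(ScheduleEvent("EC", t, block_s))
        events.append(ScheduleEvent("EO", t + block_s, block_s))
        t += 2 * block_s
    return Schedule(events=tuple(events), total_duration=t)


def generate_main_schedule(
    sessions: int = 5,
    trials_per_cond: int = 10,
    rest_range_s: tuple[float, float] = (10.0, 15.0),
    seed: int = 0,
    instruction_s: float = 5.0,
    task_s: float = 10.0,
    initial_rest_s: float = 15.0,
) -> Schedule:
    """The MA/LC task paradigm.

    Each session starts with an initial rest (5 s blank + 10 s rest,
    emitted as one 15 s REST event) and holds ``trials_per_cond`` MA and
    as many LC trials in per-session randomized, balanced order.  A trial
    is INSTRUCTION (5 s) + task (10 s) + REST drawn uniformly from
    ``rest_range_s``.  Sessions are contiguous.  Deterministic per seed.
    """
    if sessions < 1 or trials_per_cond < 1:
        raise ValueError("sessions and trials_per_cond must be >= 1")
    lo, hi = rest_range_s
    if lo > hi or lo < 0:
        raise ValueError(f"invalid rest range {rest_range_s}")
    rng = np.random.default_rng(seed)
    events: list[ScheduleEvent] = []
    t = 0.0
    for _ in range(sessions):
        events.append(ScheduleEvent("REST", t, initial_rest_s))
        t += initial_rest_s
        order = np.array(["MA"] * trials_per_cond + ["LC"] * trials_per_cond)
        rng.shuffle(order)
        for cond in order:
            events.append(ScheduleEvent("INSTRUCTION", t, instruction_s))
            t += instruction_s
            events.append(ScheduleEvent(str(cond), t, task_s))
            t += task_s
            rest = float(rng.uniform(lo, hi))
            events.append(ScheduleEvent("REST", t, rest))
            t += rest
    return Schedule(events=tuple(events), total_duration=t)
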