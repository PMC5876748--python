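"""Four-phase gait model: phases, events, per-sample sequences, strides.

A gait cycle (stride) runs between two consecutive heel strikes of the same
foot and is partitioned into four phases delimited by four events:

    HS --LR--> TS --FF--> HO --PS--> TO --Sw--> next HS

Loading Response (LR): heel strike to toe strike.
Flat Foot (FF): toe strike to heel off.
Pre-Swing (PS): heel off to toe off.
Swing (Sw): toe off to the next heel strike.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class GaitPhase(enum.IntEnum):
    LR = 0
    FF = 1
    PS = 2
    SW = 3


class EventType(enum.Enum):
    HS = "HS"  # heel strike  -> LR begins
    TS = "TS"  # toe strike   -> FF begins
    HO = "HO"  # heel off     -> PS begins
    TO = "TO"  # toe off      -> Sw begins


#: phase that begins at each event
PHASE_AFTER_EVENT = {
    EventType.HS: GaitPhase.LR,
    EventType.TS: GaitPhase.FF,
    EventType.HO: GaitPhase.PS,
    EventType.TO: GaitPhase.SW,
}

#: event that starts each phase
EVENT_BEFORE_PHASE = {v: k for k, v in PHASE_AFTER_EVENT.items()}

#: canonical cyclic successor of each event type
NEXT_EVENT = {
    EventType.HS: EventType.TS,
    EventType.TS: EventType.HO,
    EventType.HO: EventType.TO,
    EventType.TO: EventType.HS,
}

PHASE_NAMES = ("LR", "FF", "PS", "Sw")


@dataclass(frozen=True, order=True)
class GaitEvent:
    time: float
    type: EventType = field(compare=False)


@dataclass
class PhaseSequence:
    """Per-sample phase labels on a uniform grid plus the event list.

    ``labels`` holds :class:`GaitPhase` integer codes; ``events`` is the
    time-ordered list of accepted gait events.  ``flagged`` collects events
    that violated the canonical HS->TS->HO->TO cycle and were dropped from
    the accepted stream (kept for diagnostics).
    """

    labels: np.ndarray
    rate: float
    t0: float = 0.0
    events: list[GaitEvent] = field(default_factory=list)
    flagged: list[GaitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.labels.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.labels.size - 1) / self.rate if self.labels.size else 0.0

    def events_of_type(self, kind: EventType) -> list[GaitEvent]:
        return [e for e in self.events if e.type is kind]

    def to_json(self) -> str:
        payload = {
            "rate_hz": self.rate,
            "t0_s": self.t0,
            "labels": [int(v) for v in self.labels],
            "events": [{"type": e.type.value, "time_s": e.time} for e in self.events],
            "flagged": [{"type": e.type.value, "time_s": e.time} for e in self.flagged],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PhaseSequence":
        payload = json.loads(text)
        return cls(
            labels=np.asarray(payload["labels"], dtype=np.int8),
            rate=float(payload["rate_hz"]),
            t0=float(payload.get("t0_s", 0.0)),
            events=[GaitEvent(float(e["time_s"]), EventType(e["type"]))
                    for e in payload.get("events", [])],
            flagged=[GaitEvent(float(e["time_s"]), EventType(e["type"]))
                     for e in payload.get("flagged", [])],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PhaseSequence":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class StridePhases:
    """Phase percentages of one stride (heel strike to next heel strike)."""

    stride_index: int
    bounds: tuple[float, float]
    percentages: np.ndarray  # (LR, FF, PS, Sw), sums to 100

    def __post_init__(self) -> None:
        pct = np.asarray(self.percentages, dtype=float)
        object.__setattr__(self, "percentages", pct)
        if pct.shape != (4,):
            raise ValueError("percentages must be a 4-vector")
        if np.any(pct < 0) or abs(pct.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must be non-negative and sum to 100")


def canonical_events(raw: list[GaitEvent]) -> tuple[list[GaitEvent], list[GaitEvent]]:
    """Greedily keep the longest-prefix event stream that follows the
    canonical cycle; return (accepted, flagged-and-dropped).

    The first event of any type is accepted; thereafter an event is accepted
    only if its type is the cyclic successor of the last accepted type.
    """
    accepted: list[GaitEvent] = []
    flagged: list[GaitEvent] = []
    for ev in sorted(raw):
        if not accepted or ev.type is NEXT_EVENT[accepted[-1].type]:
            accepted.append(ev)
        else:
            flagged.append(ev)
    return accepted, flagged


def events_to_labels(events: list[GaitEvent], n_samples: int, rate: float,
                     t0: float = 0.0) -> np.ndarray:
    """Rasterize an event list into per-sample phase labels.

    Each sample gets the phase begun by the most recent event at or before
    its time.  Samples before the first event get the phase preceding it.
    """
    labels = np.empty(n_samples, dtype=np.int8)
    if not events:
        labels.fill(GaitPhase.SW)
        return labels
    times = t0 + np.arange(n_samples) / rate
    ev_times = np.array([e.time for e in events])
    # tolerate floating-point jitter of half a sample
    idx = np.searchsorted(ev_times, times + 0.5 / rate, side="right") - 1
    phase_codes = np.array([int(PHASE_AFTER_EVENT[e.type]) for e in events],
                           dtype=np.int8)
    # before the first event: the phase that ends at that event
    first_phase = (int(PHASE_AFTER_EVENT[events[0].type]) - 1) % 4
    labels[idx < 0] = first_phase
    valid = idx >= 0
    labels[valid] = phase_codes[idx[valid]]
    return labels


def sequence_from_events(events: list[GaitEvent], n_samples: int, rate: float,
                         t0: float = 0.0) -> PhaseSequence:
    """Build a :class:`PhaseSequence` from raw detected events, enforcing the
    canonical cycle (violations are flagged, not silently kept)."""
    accepted, flagged = canonical_events(events)
    labels = events_to_labels(accepted, n_samples, rate, t0)
    return PhaseSequence(labels=labels, rate=rate, t0=t0, events=accepted,
                         flagged=flagged)


def labels_to_events(labels: np.ndarray, rate: float, t0: float = 0.0
                     ) -> tuple[list[GaitEvent], list[GaitEvent]]:
    """Extract events from per-sample labels at label-change samples.

    A change into phase p emits the event that begins p, stamped at the time
    of the first sample of the new run.  Changes that do not follow the
    canonical cycle are flagged.
    """
    labels = np.asarray(labels)
    accepted: list[GaitEvent] = []
    flagged: list[GaitEvent] = []
    change = np.flatnonzero(np.diff(labels)) + 1
    for i in change:
        ev = GaitEvent(t0 + i / rate, EVENT_BEFORE_PHASE[GaitPhase(int(labels[i]))])
        cyclic_step = (int(labels[i]) - int(labels[i - 1])) % 4 == 1
        follows = not accepted or ev.type is NEXT_EVENT[accepted[-1].type]
        if cyclic_step and follows:
            accepted.append(ev)
        else:
            flagged.append(ev)
    return accepted, flagged
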