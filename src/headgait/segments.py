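"""Shared motor-state segment, gait-event and metric containers.

All intervals are 0-based, half-open ``[start, end)`` frame indices on the
preprocessed 50 Hz grid, so a segment's duration is ``(end - start) / rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES = ("straight_walking", "turning", "squatting", "sit_to_stand", "stand_to_sit")


@dataclass
class MotorStateSegment:
    """A labelled half-open frame interval of one motor state in one source."""

    state: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def duration(self, rate: float) -> float:
        return (self.end - self.start) / rate

    def intersection(self, other: "MotorStateSegment") -> int:
        """Number of shared frames with ``other``."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GaitEventList:
    """Ordered gait-event frame indices (heel strikes or double-support minima)."""

    frames: np.ndarray
    kind: str  # "heel_strike" | "double_support"
    source: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("event frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def within(self, start: int, end: int) -> "GaitEventList":
        keep = (self.frames >= start) & (self.frames < end)
        return GaitEventList(self.frames[keep], self.kind, self.source)


@dataclass
class MetricsRecord:
    """Mobility-metric values (with units encoded in the key names)."""

    source: str
    state: str
    values: dict = field(default_factory=dict)
    n_segments: int = 0

    def get(self, key, default=None):
        return self.values.get(key, default)
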