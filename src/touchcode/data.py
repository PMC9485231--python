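"""Core containers for the two-whisker touch task.

The task presents a pole to a head-fixed mouse whisking with two spared
whiskers (W1, W2).  Touches are characterised by the signed change in
whisker curvature Δκ — negative for protraction touches, positive for
retraction touches — which serves as the proxy for contact force.  Neural
activity is a GCaMP ΔF/F trace sampled at the imaging frame rate and
concatenated across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four single-whisker touch types: whisker x direction.
TOUCH_TYPES = ("W1P", "W1R", "W2P", "W2R")

#: Trial types by which whiskers touched.
TRIAL_TYPES = ("none", "W1-only", "W2-only", "multi")

#: Neuron classes: non-touch, unidirectional single-whisker, bidirectional
#: single-whisker, multi-whisker.
NEURON_CLASSES = ("non-touch", "uSW", "bSW", "MW")

PROTRACTION = "protraction"
RETRACTION = "retraction"


class ConfigurationError(ValueError):
    """An invalid configuration field; the message names the field."""


class DegenerateTraceError(ValueError):
    """A trace lacks the samples an estimator requires."""


@dataclass(frozen=True)
class TouchEvent:
    """A single whisker-pole contact at imaging resolution.

    Frames are 0-based global indices into the concatenated recording and
    form a half-open interval ``[onset_frame, offset_frame)``.  The sign of
    ``peak_dkappa`` encodes direction: protraction touches have Δκ < 0,
    retraction touches Δκ > 0 (units 1/mm-scale curvature change).
    """

    whisker_id: int
    direction: str
    onset_frame: int
    offset_frame: int
    peak_dkappa: float

    def __post_init__(self) -> None:
        if self.whisker_id not in (1, 2):
            raise ValueError(f"whisker_id must be 1 or 2, got {self.whisker_id}")
        if self.direction not in (PROTRACTION, RETRACTION):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.onset_frame < self.offset_frame:
            raise ValueError("onset_frame must precede offset_frame")
        if self.direction == PROTRACTION and not self.peak_dkappa < 0:
            raise ValueError("protraction touch requires peak_dkappa < 0")
        if self.direction == RETRACTION and not self.peak_dkappa > 0:
            raise ValueError("retraction touch requires peak_dkappa > 0")

    @property
    def touch_type(self) -> str:
        d = "P" if self.direction == PROTRACTION else "R"
        return f"W{self.whisker_id}{d}"


@dataclass
class Trial:
    """One behavioural trial: per-frame Δκ for both whiskers plus events.

    ``frame_span`` is the half-open global frame interval covered by the
    trial; ``dkappa`` has shape ``(2, n_frames)`` (row 0 = whisker 1).
    """

    trial_id: int
    session_id: int
    pole: str  # "proximal" | "distal"
    frame_span: tuple[int, int]
    dkappa: np.ndarray
    touches: list[TouchEvent] = field(default_factory=list)
    first_lick_frame: int | None = None
    trial_type: str = "none"

    def __post_init__(self) -> None:
        self.dkappa = np.asarray(self.dkappa, dtype=float)
        start, stop = self.frame_span
        if self.dkappa.shape != (2, stop - start):
            raise ValueError(
                f"dkappa shape {self.dkappa.shape} does not match frame_span "
                f"{self.frame_span}"
            )
        for ev in self.touches:
            if ev.onset_frame < start or ev.offset_frame > stop:
                raise ValueError("touch frames outside trial frame_span")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")

    @property
    def n_frames(self) -> int:
        return self.frame_span[1] - self.frame_span[0]

    @property
    def sorted_touches(self) -> list[TouchEvent]:
        return sorted(self.touches, key=lambda e: (e.onset_frame, e.whisker_id))

    def touching_whiskers(self) -> set[int]:
        return {ev.whisker_id for ev in self.touches}

    def single_whisker_touch_type(self) -> str | None:
        """Touch type of a single-whisker trial (by its first touch), else None."""
        if self.trial_type not in ("W1-only", "W2-only"):
            return None
        return self.sorted_touches[0].touch_type

    def local_frames(self, event: TouchEvent) -> tuple[int, int]:
        """Event frame interval relative to trial start."""
        start = self.frame_span[0]
        return event.onset_frame - start, event.offset_frame - start


@dataclass
class NeuronRecord:
    """A neuron's concatenated ΔF/F trace and anatomical metadata."""

    neuron_id: int
    dff: np.ndarray
    depth_um: float
    layer: str  # "L2" | "L3" | "L4"
    subvolume: int = 0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 1:
            raise ValueError("dff must be a 1-D trace")


def total_frames(trials: list[Trial]) -> int:
    return max(t.frame_span[1] for t in trials)


def trials_of_type(trials: list[Trial], trial_type: str) -> list[Trial]:
    return [t for t in trials if t.trial_type == trial_type]


def single_whisker_trials(trials: list[Trial], touch_type: str) -> list[Trial]:
    """Single-whisker trials whose touches are of the given type (e.g. W1P)."""
    if touch_type not in TOUCH_TYPES:
        raise ValueError(f"unknown touch type {touch_type!r}")
    return [t for t in trials if t.single_whisker_touch_type() == touch_type]


def touch_trials(trials: list[Trial]) -> list[Trial]:
    return [t for t in trials if t.touches]


def frame_index(trials: list[Trial]) -> np.ndarray:
    """Global frame -> trial index map (-1 for frames outside any trial)."""
    n = total_frames(trials)
    idx = np.full(n, -1, dtype=int)
    for i, t in enumerate(trials):
        idx[t.frame_span[0] : t.frame_span[1]] = i
    return idx
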