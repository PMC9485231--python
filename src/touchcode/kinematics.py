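"""Whisker-curvature kinematics: downsampling, per-trial strength, tertiles.

Whisker curvature change Δκ is tracked at high rate (hundreds of Hz) but all
model fitting happens at the imaging frame rate (~7 Hz).  A frame's Δκ is the
within-frame sample of maximal magnitude with its sign preserved, so brief
strong touches are not washed out by averaging.  A trial's touch strength is
the mean Δκ over the frames during which the whisker touches, and trials of
one touch type are split into equal-sized weak/medium/strong thirds after
normalising by the type's 95th-percentile magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Trial


class EmptyFrameError(ValueError):
    """A frame window contained no samples."""


class NoTouchError(ValueError):
    """The trial has no touches by the requested whisker."""


STRENGTH_LABELS = ("weak", "medium", "strong")


@dataclass
class StrengthBins:
    """Tertile assignment of one touch type's trials by normalised |Δκ|.

    ``labels[i]`` is the tertile of ``trial_ids[i]``; ``norm_constant`` is the
    95th percentile of per-trial |Δκ| used for normalisation.  ``degenerate``
    flags the tie case where all strengths are identical and every trial
    shares one bin.
    """

    trial_ids: list[int]
    labels: list[str]
    norm_constant: float
    degenerate: bool = False

    def trials_in(self, label: str) -> list[int]:
        return [tid for tid, lab in zip(self.trial_ids, self.labels) if lab == label]


def downsample_curvature(
    kappa_hires: np.ndarray, frame_bounds: np.ndarray, times: np.ndarray | None = None
) -> np.ndarray:
    """Collapse a high-rate Δκ series to one signed value per imaging frame.

    Each output frame keeps the sample of maximal |Δκ| within the frame,
    preserving its sign.  On a magnitude tie between samples of opposite
    sign the earlier sample wins (deterministic, order-stable).

    Parameters
    ----------
    kappa_hires : high-rate Δκ samples.
    frame_bounds : monotone sample-time boundaries, length n_frames + 1;
        frame i covers ``[frame_bounds[i], frame_bounds[i+1])``.
    times : sample times; defaults to sample index.
    """
    kappa_hires = np.asarray(kappa_hires, dtype=float)
    frame_bounds = np.asarray(frame_bounds, dtype=float)
    if times is None:
        times = np.arange(kappa_hires.size, dtype=float)
    if np.any(np.diff(frame_bounds) <= 0):
        raise ValueError("frame_bounds must be strictly increasing")
    out = np.empty(frame_bounds.size - 1, dtype=float)
    for i in range(out.size):
        sel = (times >= frame_bounds[i]) & (times < frame_bounds[i + 1])
        if not np.any(sel):
            raise EmptyFrameError(f"frame {i} contains no samples")
        vals = kappa_hires[sel]
        # argmax returns the first maximal element: earlier sample wins ties
        out[i] = vals[np.argmax(np.abs(vals))]
    return out


def trial_strength(trial: Trial, whisker_id: int) -> float:
    """Mean Δκ over the frames during which the whisker touches.

    Frames inside any of the whisker's touch events are pooled and averaged,
    so a trial with several touches contributes a single frame-weighted mean.
    """
    events = [ev for ev in trial.touches if ev.whisker_id == whisker_id]
    if not events:
        raise NoTouchError(f"trial {trial.trial_id} has no touches by whisker {whisker_id}")
    mask = np.zeros(trial.n_frames, dtype=bool)
    for ev in events:
        lo, hi = trial.local_frames(ev)
        mask[lo:hi] = True
    return float(np.mean(trial.dkappa[whisker_id - 1][mask]))


def bin_trials_by_strength(
    trials: list[Trial], whisker_id: int | None = None
) -> StrengthBins:
    """Partition one touch type's trials into weak/medium/strong thirds.

    Per-trial strengths are normalised by the 95th percentile of their
    magnitudes (linear interpolation), ranked by |normalised strength|, and
    split into tertiles whose sizes differ by at most one.  Ties in strength
    are broken by trial order so the partition is deterministic.
    """
    if len(trials) < 3:
        raise ValueError(f"need >= 3 trials to form tertiles, got {len(trials)}")
    if whisker_id is None:
        whiskers = {ev.whisker_id for t in trials for ev in t.touches}
        if len(whiskers) != 1:
            raise ValueError("trials touch multiple whiskers; pass whisker_id")
        whisker_id = whiskers.pop()
    strengths = np.array([trial_strength(t, whisker_id) for t in trials])
    norm = float(np.percentile(np.abs(strengths), 95))
    degenerate = bool(np.all(strengths == strengths[0]))
    normed = np.abs(strengths) / norm if norm > 0 else np.abs(strengths)
    n = len(trials)
    order = np.argsort(normed, kind="stable")
    labels = [""] * n
    if degenerate:
        labels = [STRENGTH_LABELS[0]] * n
    else:
        sizes = [n // 3] * 3
        for i in range(n % 3):  # remainders go to the weaker bins first
            sizes[i] += 1
        pos = 0
        for label, size in zip(STRENGTH_LABELS, sizes):
            for j in order[pos : pos + size]:
                labels[j] = label
            pos += size
    return StrengthBins(
        trial_ids=[t.trial_id for t in trials],
        labels=labels,
        norm_constant=norm,
        degenerate=degenerate,
    )


def classify_trial_type(
    trial: Trial, frame_rate_hz: float
) -> tuple[str, int | None, float | None]:
    """Classify a trial by its first two touches.

    Returns ``(trial_type, first_toucher, first_to_second_ms)``.  For multi
    trials the first-touching whisker and the onset-to-onset interval of the
    first two touches (at imaging resolution, in ms) are reported; both are
    None otherwise.  The result does not depend on the storage order of the
    touch events.
    """
    touches = trial.sorted_touches
    if not touches:
        return "none", None, None
    whiskers = {ev.whisker_id for ev in touches}
    if whiskers == {1}:
        return "W1-only", None, None
    if whiskers == {2}:
        return "W2-only", None, None
    first, second = touches[0], touches[1]
    interval_ms = (second.onset_frame - first.onset_frame) / frame_rate_hz * 1000.0
    return "multi", first.whisker_id, interval_ms
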