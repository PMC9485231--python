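"""Single-neuron ROC decoding of touch force and whisker identity.

For each trial the response is the mean ΔF/F between the first touch and
the first lick (capped at 2 s after the first touch; the cap also applies
when no lick occurred).  Force decoding contrasts the strong vs weak Δκ
tertiles within one single-whisker touch type; identity decoding contrasts
whisker-1-only vs whisker-2-only trials.  The AUC is computed through the
rank-sum identity with midranks for ties — exactly the probability that a
random positive-class response exceeds a random negative-class one, with
ties counted 1/2 — and requires at least ten trials per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import NeuronRecord, Trial, single_whisker_trials
from .kinematics import bin_trials_by_strength

RESPONSE_WINDOW_S = 2.0
MIN_TRIALS_PER_CLASS = 10


@dataclass
class DecodingResult:
    """AUC for one neuron and contrast; ``reason`` explains an absent AUC."""

    neuron_id: int
    contrast: str
    auc: float | None
    n_a: int = 0
    n_b: int = 0
    reason: str | None = None


def response_window_mean(
    trace: np.ndarray, trial: Trial, frame_rate_hz: float
) -> float:
    """Mean ΔF/F over [first touch, min(first lick, first touch + 2 s))."""
    if not trial.touches:
        raise ValueError("response window requires a touch trial")
    first = trial.sorted_touches[0].onset_frame
    cap = first + int(round(RESPONSE_WINDOW_S * frame_rate_hz))
    end = cap
    if trial.first_lick_frame is not None:
        if trial.first_lick_frame <= first:
            raise ValueError(
                f"trial {trial.trial_id}: first lick precedes first touch"
            )
        end = min(trial.first_lick_frame, cap)
    end = min(end, trial.frame_span[1])
    if end <= first:
        raise ValueError(f"trial {trial.trial_id}: empty response window")
    return float(np.mean(trace[first:end]))


def roc_auc(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """P(random b > random a) with ties counted 1/2 (rank-sum identity).

    Equivalent to sliding a criterion threshold through the response range
    and integrating the ROC curve; symmetric: auc(a, b) = 1 − auc(b, a).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))  # midranks for ties
    rank_sum_b = ranks[a.size :].sum()
    u_b = rank_sum_b - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def decode_force(
    neuron: NeuronRecord,
    trials: list[Trial],
    touch_type: str,
    frame_rate_hz: float = 7.0,
    signed: bool = True,
) -> DecodingResult:
    """AUC separating strong from weak trials of one single-whisker type.

    Positive class = strong tertile.  ``signed=False`` folds the AUC to
    max(AUC, 1 − AUC), i.e. unsigned discriminability.
    """
    sel = single_whisker_trials(trials, touch_type)
    contrast = f"force:{touch_type}"
    if len(sel) < 3:
        return DecodingResult(
            neuron.neuron_id, contrast, None, reason="too few trials to form tertiles"
        )
    whisker = int(touch_type[1])
    bins = bin_trials_by_strength(sel, whisker_id=whisker)
    by_id = {t.trial_id: t for t in sel}
    strong = [by_id[i] for i in bins.trials_in("strong")]
    weak = [by_id[i] for i in bins.trials_in("weak")]
    if len(strong) < MIN_TRIALS_PER_CLASS or len(weak) < MIN_TRIALS_PER_CLASS:
        return DecodingResult(
            neuron.neuron_id, contrast, None,
            n_a=len(weak), n_b=len(strong),
            reason=f"fewer than {MIN_TRIALS_PER_CLASS} trials in a tertile",
        )
    vals_weak = [response_window_mean(neuron.dff, t, frame_rate_hz) for t in weak]
    vals_strong = [response_window_mean(neuron.dff, t, frame_rate_hz) for t in strong]
    auc = roc_auc(vals_weak, vals_strong)
    if not signed:
        auc = max(auc, 1.0 - auc)
    return DecodingResult(
        neuron.neuron_id, contrast, auc, n_a=len(weak), n_b=len(strong)
    )


def decode_identity(
    neuron: NeuronRecord,
    trials: list[Trial],
    frame_rate_hz: float = 7.0,
    signed: bool = True,
) -> DecodingResult:
    """AUC separating whisker-1-only from whisker-2-only touch trials.

    Positive class = whisker 1 (AUC > 0.5 means larger responses on W1
    trials).
    """
    w1 = [t for t in trials if t.trial_type == "W1-only"]
    w2 = [t for t in trials if t.trial_type == "W2-only"]
    if len(w1) < MIN_TRIALS_PER_CLASS or len(w2) < MIN_TRIALS_PER_CLASS:
        return DecodingResult(
            neuron.neuron_id, "identity", None, n_a=len(w2), n_b=len(w1),
            reason=f"fewer than {MIN_TRIALS_PER_CLASS} trials of a whisker",
        )
    vals_w2 = [response_window_mean(neuron.dff, t, frame_rate_hz) for t in w2]
    vals_w1 = [response_window_mean(neuron.dff, t, frame_rate_hz) for t in w1]
    auc = roc_auc(vals_w2, vals_w1)
    if not signed:
        auc = max(auc, 1.0 - auc)
    return DecodingResult(
        neuron.neuron_id, "identity", auc, n_a=len(w2), n_b=len(w1)
    )
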