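"""Trial-level responsiveness statistics and response concentration.

A neuron is responsive on a touch trial when its post-touch ΔF/F (mean from
first touch to two frames past the final touch) exceeds the pre-touch
baseline (mean of the 6 frames ≈ 0.85 s before the first touch) by the
neuron's half-normal noise scale σ AND exceeds the 99th percentile of 100
circular-shift shuffles of the same post-touch statistic.  Neurons
responding on at least 10% of trials of a touch type form the responsive
pool; a shuffled-response-probability variant of the pool criterion is also
provided and the conjunction is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    TOUCH_TYPES,
    DegenerateTraceError,
    NeuronRecord,
    Trial,
    single_whisker_trials,
)
from .encoding import calcium_event_frames

BASELINE_FRAMES = 6
POOL_MIN_PROBABILITY = 0.10
N_SHUFFLES = 100


def halfnormal_sigma(trace: np.ndarray) -> float:
    """Half-normal MLE noise scale from the negative ΔF/F samples.

    σ̂ = sqrt(mean of squares of |negative samples|); for a trace whose
    negative excursions are pure zero-mean Gaussian noise this estimates
    the noise standard deviation.
    """
    trace = np.asarray(trace, dtype=float)
    neg = trace[trace < 0]
    if neg.size == 0:
        raise DegenerateTraceError("trace has no negative samples")
    return float(np.sqrt(np.mean(neg**2)))


def _touch_window(trial: Trial) -> tuple[int, int]:
    """Global half-open frame window from first touch to 2 frames past the last."""
    touches = trial.sorted_touches
    first = touches[0].onset_frame
    last = max(ev.offset_frame for ev in touches)
    return first, min(last + 2, trial.frame_span[1])


def post_touch_mean(trace: np.ndarray, trial: Trial) -> float:
    lo, hi = _touch_window(trial)
    return float(np.mean(trace[lo:hi]))


def shuffled_post_touch(
    trace: np.ndarray,
    trial: Trial,
    rng: np.random.Generator,
    n_shuffles: int = N_SHUFFLES,
    min_shift_s: float = 10.0,
    frame_rate_hz: float = 7.0,
) -> np.ndarray:
    """Null distribution of the post-touch mean under circular time shifts."""
    lo, hi = _touch_window(trial)
    n = trace.size
    min_shift = int(round(min_shift_s * frame_rate_hz))
    hi_shift = max(n - min_shift, min_shift + 1)
    shifts = rng.integers(min_shift, hi_shift, size=n_shuffles)
    idx = (np.arange(lo, hi)[None, :] - shifts[:, None]) % n
    return trace[idx].mean(axis=1)


def trial_response(
    trace: np.ndarray,
    trial: Trial,
    sigma: float,
    null: np.ndarray,
) -> bool:
    """Did the neuron respond on this touch trial?

    Responded ⟺ post-touch mean > baseline + σ AND post-touch mean > 99th
    percentile of the shuffled post-touch null.  With fewer than 6 pre-touch
    frames the baseline uses the frames available (with a warning).
    """
    if not trial.touches:
        raise ValueError("trial_response requires a touch trial")
    first, _ = _touch_window(trial)
    b_lo = first - BASELINE_FRAMES
    if b_lo < trial.frame_span[0]:
        warnings.warn(
            f"trial {trial.trial_id}: only {first - trial.frame_span[0]} "
            "pre-touch frames available for baseline",
            stacklevel=2,
        )
        b_lo = trial.frame_span[0]
    if b_lo >= first:
        return False
    baseline = float(np.mean(trace[b_lo:first]))
    post = post_touch_mean(trace, trial)
    return post > baseline + sigma and post > float(np.percentile(null, 99))


@dataclass
class ResponseTable:
    """Per-neuron responses and response probabilities.

    ``responded[neuron_id]`` maps trial_id -> bool over touch trials;
    ``probability[neuron_id]`` maps stratum label (touch type, optionally
    tertile-qualified like ``"W1P:strong"``) -> response probability;
    ``sigma[neuron_id]`` is the half-normal noise scale.
    """

    responded: dict[int, dict[int, bool]] = field(default_factory=dict)
    probability: dict[int, dict[str, float]] = field(default_factory=dict)
    sigma: dict[int, float] = field(default_factory=dict)


@dataclass
class ResponsivePool:
    """Per-stratum sets of responsive neurons plus the admitting rule."""

    members: dict[str, set[int]] = field(default_factory=dict)
    criterion: dict[int, str] = field(default_factory=dict)


def response_probabilities(
    responded: dict[int, bool], trials: list[Trial]
) -> float:
    ids = [t.trial_id for t in trials]
    if not ids:
        raise ValueError("no trials in stratum")
    return float(np.mean([responded[i] for i in ids]))


def build_response_table(
    neurons: list[NeuronRecord],
    trials: list[Trial],
    frame_rate_hz: float = 7.0,
    strata: dict[str, list[Trial]] | None = None,
    seed: int | None = None,
    n_shuffles: int = N_SHUFFLES,
    pool_rule: str = "both",
) -> tuple[ResponseTable, ResponsivePool]:
    """Fill the response table and derive the responsive pool.

    ``strata`` maps stratum labels to trial subsets (default: the four
    single-whisker touch types over all their trials).  The pool admits a
    neuron when, for at least one stratum, its response probability is
    >= 10% (rule ``"fraction"``), exceeds the 99th percentile of shuffled
    response probabilities (rule ``"shuffle"``), or both (default
    ``"both"``); the criterion record names the rule that admitted it.
    """
    if pool_rule not in ("fraction", "shuffle", "both"):
        raise ValueError(f"unknown pool_rule {pool_rule!r}")
    # null draws are keyed by (seed, neuron, trial) so response outcomes do
    # not depend on the order in which trials are stored
    base_seed = (
        seed if seed is not None
        else int(np.random.default_rng().integers(2**31))
    )
    touch = [t for t in trials if t.touches]
    if strata is None:
        strata = {
            tt: single_whisker_trials(trials, tt) for tt in TOUCH_TYPES
        }
    strata = {k: v for k, v in strata.items() if v}

    table = ResponseTable()
    pool = ResponsivePool(members={k: set() for k in strata})
    for nr in neurons:
        sigma = halfnormal_sigma(nr.dff)
        table.sigma[nr.neuron_id] = sigma
        resp: dict[int, bool] = {}
        # per-trial shuffled nulls; shuffle response probability needs the
        # per-trial null outcomes as well
        shuffle_resp: dict[int, np.ndarray] = {}
        for t in touch:
            trial_rng = np.random.default_rng(
                (base_seed, nr.neuron_id, t.trial_id)
            )
            null = shuffled_post_touch(
                nr.dff, t, trial_rng, n_shuffles=n_shuffles,
                frame_rate_hz=frame_rate_hz,
            )
            resp[t.trial_id] = trial_response(nr.dff, t, sigma, null)
            if pool_rule in ("shuffle", "both"):
                # a shuffle "responds" when it beats the same criteria the
                # real statistic faced, against the pooled null
                first, _ = _touch_window(t)
                b_lo = max(first - BASELINE_FRAMES, t.frame_span[0])
                baseline = float(np.mean(nr.dff[b_lo:first])) if b_lo < first else 0.0
                thr = max(baseline + sigma, float(np.percentile(null, 99)))
                shuffle_resp[t.trial_id] = null > thr
        table.responded[nr.neuron_id] = resp
        probs: dict[str, float] = {}
        admitted = []
        for label, sel in strata.items():
            p = response_probabilities(resp, sel)
            probs[label] = p
            rules_ok = []
            if pool_rule in ("fraction", "both"):
                rules_ok.append(("fraction", p >= POOL_MIN_PROBABILITY))
            if pool_rule in ("shuffle", "both"):
                mat = np.stack([shuffle_resp[t.trial_id] for t in sel])
                null_probs = mat.mean(axis=0)
                rules_ok.append(("shuffle", p > float(np.percentile(null_probs, 99))))
            if all(ok for _, ok in rules_ok):
                pool.members[label].add(nr.neuron_id)
                admitted.append(label)
        table.probability[nr.neuron_id] = probs
        if admitted:
            pool.criterion[nr.neuron_id] = (
                f"{pool_rule} on {','.join(admitted)}"
            )
    return table, pool


def touch_evoked_event_counts(
    neurons: list[NeuronRecord],
    trials: list[Trial],
    frame_rate_hz: float = 7.0,
) -> dict[int, int]:
    """Per-neuron count of calcium events whose onset falls in a touch window."""
    windows = [_touch_window(t) for t in trials if t.touches]
    counts: dict[int, int] = {}
    for nr in neurons:
        onsets = calcium_event_frames(nr.dff, frame_rate_hz)
        n = 0
        for lo, hi in windows:
            n += int(np.sum((onsets >= lo) & (onsets < hi)))
        counts[nr.neuron_id] = n
    return counts


def touch_response_concentration(
    event_counts: dict[int, int], percentile: float = 1.0
) -> float:
    """Fraction of touch-evoked events carried by the most responsive neurons.

    Neurons are ranked by touch-evoked event count (ties broken by neuron
    id) and the top ``percentile`` percent (at least one neuron) is taken;
    returns their share of all touch-evoked events.
    """
    if not event_counts:
        raise ValueError("no neurons given")
    total = sum(event_counts.values())
    if total == 0:
        raise ValueError("zero touch-evoked events in the population")
    n = len(event_counts)
    if n < 100:
        warnings.warn(
            f"only {n} neurons: top-{percentile}% set is a single neuron",
            stacklevel=2,
        )
    k = max(int(np.ceil(n * percentile / 100.0)), 1)
    ranked = sorted(event_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = sum(c for _, c in ranked[:k])
    return top / total
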