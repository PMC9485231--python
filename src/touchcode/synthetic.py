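"""Synthetic two-whisker task datasets with known ground truth.

The generator emulates the study conditions downstream analyses assume:
~10 s trials imaged at ~7 Hz, half of trials touchless, touch trials split
evenly between whisker-1-only, whisker-2-only and multi-whisker types, four
single-whisker touch types (W1P/W1R/W2P/W2R) whose per-touch |Δκ| spans a
log range, short inter-touch intervals on multi-whisker trials, neurons
drawn from the non-touch/uSW/bSW/MW classes at configurable per-layer
frequencies, ΔF/F produced by the encoding model's forward prediction plus
Gaussian noise, per-session response scaling, and optionally planted
ensembles whose members share latent event drives (so their correlations
persist outside touch epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    PROTRACTION,
    RETRACTION,
    ConfigurationError,
    NeuronRecord,
    TouchEvent,
    Trial,
)
from .encoding import EncodingParams, NeuronClass, predict_trace

#: Per-layer frequencies of the touch classes used as generator defaults
#: (study estimates for L4/L3/L2; the remainder of each layer is non-touch).
DEFAULT_CLASS_FREQUENCIES: dict[str, dict[str, float]] = {
    "L4": {"uSW": 0.081, "bSW": 0.008, "MW": 0.002},
    "L3": {"uSW": 0.081, "bSW": 0.021, "MW": 0.014},
    "L2": {"uSW": 0.048, "bSW": 0.017, "MW": 0.016},
}

#: Layer depth ranges (μm) consistent with the default laminar borders at
#: 100 / 250 / 400 μm.
LAYER_DEPTH_RANGES = {"L2": (105.0, 245.0), "L3": (255.0, 395.0), "L4": (405.0, 545.0)}


@dataclass
class EnsembleSpec:
    """A planted ensemble: member count, shared-event rate and coupling gain."""

    size: int
    event_rate_hz: float = 0.20
    gain: float = 0.064


@dataclass
class SimConfig:
    """Conditions of a simulated two-whisker session block.

    Defaults mirror the task structure the analyses assume: 10 s trials at
    7 Hz, half touchless, touch trials evenly split among the three types,
    per-touch |Δκ| log-uniform over ``dkappa_log_range`` so the log10 model
    drive spans its dynamic range, and multi-whisker inter-touch intervals
    uniform over 0–400 ms so the 200 ms interaction gate is exercised on
    both sides.
    """

    n_trials: int = 120
    frame_rate_hz: float = 7.0
    trial_len_s: float = 10.0
    p_touchless: float = 0.5
    touch_type_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    dkappa_log_range: tuple[float, float] = (0.5, 50.0)
    touches_per_trial: tuple[int, int] = (1, 4)
    multi_iti_ms: tuple[float, float] = (0.0, 400.0)
    n_neurons_by_class_and_layer: dict[str, dict[str, int]] = field(
        default_factory=lambda: class_layer_counts_from_frequencies(100)
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"L2": 0.10, "L3": 0.13, "L4": 0.18}
    )
    slope_range: tuple[float, float] = (0.8, 2.5)
    offset_range: tuple[float, float] = (0.5, 2.0)
    tau_rise_range: tuple[float, float] = (0.1, 0.45)
    tau_decay_range: tuple[float, float] = (1.2, 3.5)
    j_range: tuple[float, float] | None = None
    ensemble_spec: list[EnsembleSpec] = field(default_factory=list)
    n_sessions: int = 2
    n_subvolumes: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 0:
            raise ConfigurationError("n_trials must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be > 0")
        if self.trial_len_s <= 0:
            raise ConfigurationError("trial_len_s must be > 0")
        if not 0.0 <= self.p_touchless <= 1.0:
            raise ConfigurationError("p_touchless must lie in [0, 1]")
        mix = np.asarray(self.touch_type_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ConfigurationError(
                "touch_type_mix must be 3 non-negative probabilities summing to 1"
            )
        lo, hi = self.dkappa_log_range
        if not (0 < lo < hi):
            raise ConfigurationError("dkappa_log_range must satisfy 0 < min < max")
        lo, hi = self.touches_per_trial
        if not (1 <= lo <= hi):
            raise ConfigurationError("touches_per_trial must satisfy 1 <= min <= max")
        if self.multi_iti_ms[0] < 0 or self.multi_iti_ms[1] < self.multi_iti_ms[0]:
            raise ConfigurationError("multi_iti_ms must be a non-negative range")
        for layer, classes in self.n_neurons_by_class_and_layer.items():
            for cls, n in classes.items():
                if n < 0:
                    raise ConfigurationError(
                        f"n_neurons_by_class_and_layer[{layer}][{cls}] must be >= 0"
                    )
        for layer, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd[{layer}] must be >= 0")
        for spec in self.ensemble_spec:
            if spec.size < 3:
                raise ConfigurationError("ensemble_spec sizes must be >= 3")
            if spec.event_rate_hz < 0 or spec.gain < 0:
                raise ConfigurationError("ensemble_spec rates and gains must be >= 0")
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if self.n_subvolumes < 1:
            raise ConfigurationError("n_subvolumes must be >= 1")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_len_s * self.frame_rate_hz))


def class_layer_counts_from_frequencies(
    n_per_layer: int, frequencies: dict[str, dict[str, float]] | None = None
) -> dict[str, dict[str, int]]:
    """Integer per-layer class counts from per-layer frequencies.

    Touch-class counts are the rounded frequencies times ``n_per_layer``;
    the remainder is non-touch.
    """
    frequencies = frequencies or DEFAULT_CLASS_FREQUENCIES
    out: dict[str, dict[str, int]] = {}
    for layer, freqs in frequencies.items():
        counts = {cls: int(round(f * n_per_layer)) for cls, f in freqs.items()}
        counts["non-touch"] = n_per_layer - sum(counts.values())
        out[layer] = counts
    return out


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knew: the oracle for downstream tests."""

    params: dict[int, EncodingParams]
    classes: dict[int, NeuronClass]
    ensembles: list[list[int]]
    ensemble_event_frames: list[np.ndarray]

    def __post_init__(self) -> None:
        for members in self.ensembles:
            if len(members) < 3:
                raise ValueError("planted ensembles must have >= 3 members")
        for nid in self.classes:
            if nid not in self.params:
                raise ValueError(f"neuron {nid} missing encoding parameters")


# ---------------------------------------------------------------------------
# touch kinematics
# ---------------------------------------------------------------------------

def _touch_magnitude(config: SimConfig, rng: np.random.Generator) -> float:
    lo, hi = config.dkappa_log_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _place_touches(
    whisker_id: int,
    direction: str,
    n_touches: int,
    first_onset: int,
    nf: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TouchEvent]:
    """Non-overlapping touches for one whisker, the first at ``first_onset``."""
    events = []
    onset = first_onset
    for _ in range(n_touches):
        dur = int(rng.integers(1, 3))  # 1-2 frames per contact
        if onset + dur > nf - 2:
            break
        mag = _touch_magnitude(config, rng)
        peak = -mag if direction == PROTRACTION else mag
        events.append(
            TouchEvent(
                whisker_id=whisker_id, direction=direction,
                onset_frame=onset, offset_frame=onset + dur, peak_dkappa=peak,
            )
        )
        onset = onset + dur + int(rng.integers(2, 6))  # refractory gap
    return events


def sample_touch_sequence(
    trial_type: str, config: SimConfig, rng: np.random.Generator
) -> tuple[list[TouchEvent], np.ndarray]:
    """Sample one trial's touch events and per-frame Δκ (frames trial-local).

    Protraction touches carry Δκ < 0 and retraction touches Δκ > 0; Δκ is
    nonzero only on touching frames.  Touch direction is drawn once per
    whisker per trial, so single-whisker trials have a well-defined touch
    type.  Multi trials place at least one touch per whisker with the
    first-to-second onset interval drawn from ``multi_iti_ms``.
    """
    nf = config.frames_per_trial
    dkappa = np.zeros((2, nf))
    if trial_type == "none":
        return [], dkappa
    if trial_type not in ("W1-only", "W2-only", "multi"):
        raise ValueError(f"unknown trial_type {trial_type!r}")

    lo_t, hi_t = config.touches_per_trial
    # pole is reachable roughly in the first half of the trial
    window_hi = max(nf // 2, 3)
    events: list[TouchEvent] = []
    if trial_type in ("W1-only", "W2-only"):
        w = 1 if trial_type == "W1-only" else 2
        direction = PROTRACTION if rng.random() < 0.5 else RETRACTION
        n_touches = int(rng.integers(lo_t, hi_t + 1))
        first = int(rng.integers(2, window_hi))
        events = _place_touches(w, direction, n_touches, first, nf, config, rng)
    else:
        first_w = 1 if rng.random() < 0.5 else 2
        second_w = 3 - first_w
        iti_ms = rng.uniform(*config.multi_iti_ms)
        iti_frames = int(round(iti_ms / 1000.0 * config.frame_rate_hz))
        first = int(rng.integers(2, window_hi))
        dirs = {
            w: PROTRACTION if rng.random() < 0.5 else RETRACTION for w in (1, 2)
        }
        n1 = int(rng.integers(lo_t, hi_t + 1))
        n2 = int(rng.integers(lo_t, hi_t + 1))
        ev_first = _place_touches(first_w, dirs[first_w], n1, first, nf, config, rng)
        ev_second = _place_touches(
            second_w, dirs[second_w], n2, first + iti_frames, nf, config, rng
        )
        if not ev_second:  # interval pushed past trial end: force one touch
            onset = min(first + iti_frames, nf - 3)
            mag = _touch_magnitude(config, rng)
            peak = -mag if dirs[second_w] == PROTRACTION else mag
            ev_second = [
                TouchEvent(second_w, dirs[second_w], onset, onset + 1, peak)
            ]
        events = ev_first + ev_second

    for ev in events:
        dkappa[ev.whisker_id - 1, ev.onset_frame : ev.offset_frame] = ev.peak_dkappa
    return events, dkappa


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------

def _draw_params(
    cls: str,
    layer: str,
    config: SimConfig,
    session_ids: list[int],
    rng: np.random.Generator,
) -> tuple[EncodingParams, NeuronClass]:
    """Encoding parameters for one neuron of the given class."""
    s_pro = np.zeros(2)
    s_ret = np.zeros(2)
    o_pro = rng.uniform(*config.offset_range, size=2)
    o_ret = rng.uniform(*config.offset_range, size=2)

    def slope() -> float:
        return float(rng.uniform(*config.slope_range))

    whisker = direction = None
    if cls == "uSW":
        whisker = int(rng.integers(1, 3))
        direction = PROTRACTION if rng.random() < 0.5 else RETRACTION
        if direction == PROTRACTION:
            s_pro[whisker - 1] = slope()
        else:
            s_ret[whisker - 1] = slope()
    elif cls == "bSW":
        whisker = int(rng.integers(1, 3))
        s_pro[whisker - 1] = slope()
        s_ret[whisker - 1] = slope()
    elif cls == "MW":
        for w in (1, 2):
            pick = rng.integers(0, 3)  # 0: pro, 1: ret, 2: both
            if pick in (0, 2):
                s_pro[w - 1] = slope()
            if pick in (1, 2):
                s_ret[w - 1] = slope()
    elif cls != "non-touch":
        raise ConfigurationError(f"unknown neuron class {cls!r}")

    d_raw = rng.uniform(0.5, 1.0, size=len(session_ids))
    d_raw /= d_raw.max()
    j1 = j2 = 1.0
    if config.j_range is not None:
        j1 = float(rng.uniform(*config.j_range))
        j2 = float(rng.uniform(*config.j_range))
    params = EncodingParams(
        s_pro=s_pro, s_ret=s_ret, o_pro=o_pro, o_ret=o_ret,
        tau_rise=float(rng.uniform(*config.tau_rise_range)),
        tau_decay=float(rng.uniform(*config.tau_decay_range)),
        d={sid: float(v) for sid, v in zip(session_ids, d_raw)},
        j_w1w2=j1, j_w2w1=j2,
        sigma2=config.noise_sd[layer] ** 2,
    )
    label = NeuronClass(cls, whisker=whisker, direction=direction)
    return params, label


def simulate_neuron_trace(
    params: EncodingParams,
    trials: list[Trial],
    rng: np.random.Generator,
    frame_rate_hz: float = 7.0,
    extra_drive: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-model ΔF/F: model prediction plus zero-mean Gaussian noise.

    ``extra_drive`` (already in ΔF/F units, e.g. a planted ensemble's
    event component) is added to the noiseless prediction before noise.
    """
    if params.sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    mean = predict_trace(params, trials, frame_rate_hz)
    if extra_drive is not None:
        mean = mean + extra_drive
    if params.sigma2 == 0:
        return mean
    return mean + rng.normal(0.0, np.sqrt(params.sigma2), mean.size)


def _ensemble_component(
    event_frames: np.ndarray,
    gain: float,
    params: EncodingParams,
    n_frames: int,
    frame_rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A member's share of the latent event drive, convolved with its kernel."""
    from .encoding import gcamp_kernel

    impulses = np.zeros(n_frames)
    amps = gain * rng.uniform(0.8, 1.2, size=event_frames.size)
    np.add.at(impulses, event_frames, amps)
    kernel = gcamp_kernel(params.tau_rise, params.tau_decay, 1.0 / frame_rate_hz)
    return np.convolve(impulses, kernel)[:n_frames]


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def generate_trials(
    config: SimConfig, rng: np.random.Generator
) -> list[Trial]:
    """The trial sequence alone (shared by all neurons of the dataset)."""
    nf = config.frames_per_trial
    trials: list[Trial] = []
    type_labels = ("W1-only", "W2-only", "multi")
    for i in range(config.n_trials):
        session_id = i * config.n_sessions // max(config.n_trials, 1)
        if rng.random() < config.p_touchless:
            ttype = "none"
        else:
            ttype = type_labels[rng.choice(3, p=np.asarray(config.touch_type_mix))]
        local_events, dkappa = sample_touch_sequence(ttype, config, rng)
        start = i * nf
        events = sorted(
            (
                TouchEvent(
                    ev.whisker_id, ev.direction,
                    ev.onset_frame + start, ev.offset_frame + start, ev.peak_dkappa,
                )
                for ev in local_events
            ),
            key=lambda e: (e.onset_frame, e.whisker_id),
        )
        lick = None
        if events:
            first = min(ev.onset_frame for ev in events)
            delay = rng.uniform(0.5, 2.5)  # s; straddles the 2 s decoding cap
            lick = min(first + int(round(delay * config.frame_rate_hz)), start + nf - 1)
        trials.append(
            Trial(
                trial_id=i, session_id=session_id,
                pole="distal" if ttype == "none" else "proximal",
                frame_span=(start, start + nf), dkappa=dkappa,
                touches=events, first_lick_frame=lick, trial_type=ttype,
            )
        )
    return trials


def generate_dataset(
    config: SimConfig,
) -> tuple[list[Trial], list[NeuronRecord], SyntheticGroundTruth]:
    """Generate a full synthetic dataset with ground truth.

    Deterministic given ``config.seed``.  Realised neuron-class counts
    exactly match ``n_neurons_by_class_and_layer``; each neuron's trace is
    the encoding model's forward prediction plus Gaussian noise, with
    planted-ensemble members receiving an additional shared latent event
    drive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials = generate_trials(config, rng)
    n_frames = config.n_trials * config.frames_per_trial
    session_ids = sorted({t.session_id for t in trials}) or [0]

    params: dict[int, EncodingParams] = {}
    classes: dict[int, NeuronClass] = {}
    neurons_meta: list[tuple[int, str, float, int]] = []  # id, layer, depth, subvol
    nid = 0
    for layer in sorted(config.n_neurons_by_class_and_layer):
        counts = config.n_neurons_by_class_and_layer[layer]
        lo_d, hi_d = LAYER_DEPTH_RANGES.get(layer, (100.0, 500.0))
        for cls in ("non-touch", "uSW", "bSW", "MW"):
            for _ in range(counts.get(cls, 0)):
                p, label = _draw_params(cls, layer, config, session_ids, rng)
                params[nid] = p
                classes[nid] = label
                depth = float(rng.uniform(lo_d, hi_d))
                subvol = int(rng.integers(0, config.n_subvolumes))
                neurons_meta.append((nid, layer, depth, subvol))
                nid += 1

    # planted ensembles: disjoint member sets sharing latent event times
    n_neurons = len(neurons_meta)
    perm = list(rng.permutation(n_neurons))
    ensembles: list[list[int]] = []
    event_frames_list: list[np.ndarray] = []
    member_drive: dict[int, np.ndarray] = {}
    duration_s = n_frames / config.frame_rate_hz
    for spec in config.ensemble_spec:
        if spec.size > len(perm):
            raise ConfigurationError(
                "ensemble_spec sizes exceed the neuron population"
            )
        members = sorted(int(perm.pop()) for _ in range(spec.size))
        n_events = rng.poisson(spec.event_rate_hz * duration_s)
        ev = np.sort(rng.integers(0, n_frames, size=max(n_events, 1)))
        ensembles.append(members)
        event_frames_list.append(ev)
        for m in members:
            member_drive[m] = _ensemble_component(
                ev, spec.gain, params[m], n_frames, config.frame_rate_hz, rng
            )

    neurons: list[NeuronRecord] = []
    for nid_, layer, depth, subvol in neurons_meta:
        trace = simulate_neuron_trace(
            params[nid_], trials, rng,
            frame_rate_hz=config.frame_rate_hz,
            extra_drive=member_drive.get(nid_),
        )
        neurons.append(
            NeuronRecord(
                neuron_id=nid_, dff=trace, depth_um=depth,
                layer=layer, subvolume=subvol,
            )
        )

    truth = SyntheticGroundTruth(
        params=params, classes=classes,
        ensembles=ensembles, ensemble_event_frames=event_frames_list,
    )
    return trials, neurons, truth
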