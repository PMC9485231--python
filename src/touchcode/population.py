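"""Population-level operations: depth normalisation, L4 noise matching,
layer-stratified summaries, and the end-to-end pipeline.

The laminar coordinate assigns 0/1/2 to the L1–L2, L2–L3 and L3–L4 borders
(the L2–L3 border sits midway between the other two); L4 depths extend past
2 by the same per-layer scaling.  Noise matching rescales superficial
traces to L4 amplitude statistics and adds L4-level Gaussian noise so
classification robustness to depth-dependent imaging noise can be probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import NeuronRecord, Trial
from .decoding import decode_force, decode_identity
from .encoding import (
    NeuronClass,
    TouchEncodingModel,
    classify_neuron,
    shuffled_null_scores,
)
from .ensembles import (
    Ensemble,
    class_pair_mean_correlation,
    detect_ensembles,
    label_touch_ensembles,
    nontouch_time_mask,
)
from .response import (
    build_response_table,
    touch_evoked_event_counts,
    touch_response_concentration,
)

BOUNDARY_EXCLUSION_UM = 50.0  # full slice width centred on each border
FOV_SCALE = 7.0 / 2.0  # imaged field spans ~7 barrels; 2 whiskers spared


@dataclass(frozen=True)
class LayerBounds:
    """Laminar border depths (μm, perpendicular to the dural surface)."""

    l1_l2_um: float
    l2_l3_um: float
    l3_l4_um: float

    def __post_init__(self) -> None:
        if not self.l1_l2_um < self.l2_l3_um < self.l3_l4_um:
            raise ValueError("layer borders must be strictly increasing")
        mid = (self.l1_l2_um + self.l3_l4_um) / 2.0
        if abs(self.l2_l3_um - mid) > 1e-6 * max(abs(mid), 1.0):
            raise ValueError(
                "L2-L3 border must be the midpoint of the L1-L2 and L3-L4 borders"
            )

    @classmethod
    def from_outer(cls, l1_l2_um: float, l3_l4_um: float) -> "LayerBounds":
        return cls(l1_l2_um, (l1_l2_um + l3_l4_um) / 2.0, l3_l4_um)


DEFAULT_BOUNDS = LayerBounds.from_outer(100.0, 400.0)


@dataclass
class NoiseMatchParams:
    """L4 matching: amplitude ratio α and the matched Gaussian noise scale."""

    alpha: float
    noise_scale: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")


def normalized_depth(depth_um: float, bounds: LayerBounds = DEFAULT_BOUNDS) -> float:
    """Laminar coordinate: 0/1/2 at the three borders, linear between.

    L4 depths extend beyond 2 as
    2 + (distance below the L3–L4 border) / (L2–L3 to L3–L4 distance).
    """
    if depth_um < bounds.l1_l2_um:
        raise ValueError(
            f"depth {depth_um} μm is above the L1-L2 border ({bounds.l1_l2_um} μm)"
        )
    half = bounds.l3_l4_um - bounds.l2_l3_um
    if depth_um <= bounds.l3_l4_um:
        return (depth_um - bounds.l1_l2_um) / half
    return 2.0 + (depth_um - bounds.l3_l4_um) / half


def layer_of_depth(depth_um: float, bounds: LayerBounds = DEFAULT_BOUNDS) -> str:
    nd = normalized_depth(depth_um, bounds)
    if nd < 1.0:
        return "L2"
    if nd < 2.0:
        return "L3"
    return "L4"


def exclude_boundary_neurons(
    neurons: list[NeuronRecord], bounds: LayerBounds = DEFAULT_BOUNDS
) -> list[NeuronRecord]:
    """Drop neurons within a 50 μm slice centred on the L2–L3 or L3–L4 border."""
    half = BOUNDARY_EXCLUSION_UM / 2.0
    out = []
    for nr in neurons:
        near = any(
            abs(nr.depth_um - b) <= half
            for b in (bounds.l2_l3_um, bounds.l3_l4_um)
        )
        if not near:
            out.append(nr)
    return out


def _top_percent_mean(trace: np.ndarray, percent: float = 1.0) -> float:
    k = max(int(np.ceil(trace.size * percent / 100.0)), 1)
    return float(np.mean(np.sort(trace)[-k:]))


def match_l4_noise(
    l23_traces: list[np.ndarray],
    l4_traces: list[np.ndarray],
    rng: np.random.Generator,
    per_cell: bool = True,
) -> tuple[list[np.ndarray], NoiseMatchParams]:
    """Rescale L2/3 traces to L4 amplitude statistics and add L4-level noise.

    α is the ratio of the L4 animal-level mean top-1% ΔF/F to each L2/3
    cell's own top-1% mean (``per_cell=True``; with ``per_cell=False`` a
    single animal-level α is applied to every trace).  The added Gaussian
    noise scale is fit to the negative ΔF/F samples pooled over L4.
    """
    if not l23_traces or not l4_traces:
        raise ValueError("both layer groups must be non-empty")
    for tr in list(l23_traces) + list(l4_traces):
        if np.all(tr == tr.flat[0]):
            raise ValueError("degenerate (constant) trace in input")
    l4_top = float(np.mean([_top_percent_mean(tr) for tr in l4_traces]))
    l23_tops = np.array([_top_percent_mean(tr) for tr in l23_traces])
    l4_neg = np.concatenate([tr[tr < 0] for tr in l4_traces])
    noise_scale = float(np.sqrt(np.mean(l4_neg**2))) if l4_neg.size else 0.0
    alpha_animal = l4_top / float(np.mean(l23_tops))
    adjusted = []
    for tr, top in zip(l23_traces, l23_tops):
        alpha = l4_top / top if per_cell else alpha_animal
        scaled = tr * alpha
        if noise_scale > 0:
            scaled = scaled + rng.normal(0.0, noise_scale, tr.size)
        adjusted.append(scaled)
    return adjusted, NoiseMatchParams(alpha=alpha_animal, noise_scale=noise_scale)


# ---------------------------------------------------------------------------
# pipeline + summaries
# ---------------------------------------------------------------------------

@dataclass
class PipelineResults:
    """Artifacts of the staged pipeline for one simulated/ingested dataset."""

    trials: list[Trial]
    neurons: list[NeuronRecord]
    classes: dict[int, NeuronClass]
    scores: dict[int, dict[str, float]]
    thresholds: dict[int, dict[str, float]]
    response_probability: pd.DataFrame | None = None
    responsive_pool: dict[str, set[int]] = field(default_factory=dict)
    decoding: pd.DataFrame | None = None
    ensembles_by_layer: dict[str, list[Ensemble]] = field(default_factory=dict)
    summary_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def classify_population(
    neurons: list[NeuronRecord],
    trials: list[Trial],
    frame_rate_hz: float = 7.0,
    folds: int = 5,
    restarts: int = 3,
    seed: int | None = None,
    return_params: bool = False,
):
    """Fit + shuffle-calibrate + classify every neuron of a subvolume.

    Returns (classes, per-type CV scores, per-type thresholds) keyed by
    neuron id; with ``return_params`` the fitted :class:`EncodingParams`
    dict is appended.
    """
    rng = np.random.default_rng(seed)
    thresholds, _ = shuffled_null_scores(
        neurons, trials, frame_rate_hz, folds=folds,
        seed=int(rng.integers(2**31)),
    )
    classes: dict[int, NeuronClass] = {}
    scores: dict[int, dict[str, float]] = {}
    params: dict[int, object] = {}
    for nr in neurons:
        res = TouchEncodingModel(nr.dff, trials, frame_rate_hz).fit(
            folds=folds, restarts=restarts, seed=int(rng.integers(2**31))
        )
        res.score.threshold = thresholds[nr.neuron_id]
        classes[nr.neuron_id] = classify_neuron(res.score)
        scores[nr.neuron_id] = dict(res.score.r)
        params[nr.neuron_id] = res.params
    if return_params:
        return classes, scores, thresholds, params
    return classes, scores, thresholds


def class_frequency_table(
    neurons: list[NeuronRecord], classes: dict[int, NeuronClass]
) -> pd.DataFrame:
    """Per-layer frequency of each touch class (rows sum to 1)."""
    rows = []
    for layer in sorted({nr.layer for nr in neurons}):
        ids = [nr.neuron_id for nr in neurons if nr.layer == layer]
        n = len(ids)
        row = {"layer": layer, "n_neurons": n}
        for cls in ("non-touch", "uSW", "bSW", "MW"):
            row[cls] = sum(classes[i].label == cls for i in ids) / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def fov_extrapolation(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Scale per-layer touch-class frequencies by 7/2.

    The imaged field of view spans ~7 barrels while only 2 whiskers are
    spared, so observed frequencies underestimate full-field touch coding
    by roughly that factor.  Percent units.
    """
    out = freq_table[["layer"]].copy()
    for cls in ("uSW", "bSW", "MW"):
        out[f"{cls}_pct"] = 100.0 * freq_table[cls]
        out[f"{cls}_fov_pct"] = 100.0 * freq_table[cls] * FOV_SCALE
    return out


def _largest_layer_subvolume(
    neurons: list[NeuronRecord], layer: str
) -> list[NeuronRecord]:
    """Neurons of the subvolume with the most neurons of the given layer."""
    in_layer = [nr for nr in neurons if nr.layer == layer]
    if not in_layer:
        return []
    counts: dict[int, int] = {}
    for nr in in_layer:
        counts[nr.subvolume] = counts.get(nr.subvolume, 0) + 1
    best = max(sorted(counts), key=lambda sv: counts[sv])
    return [nr for nr in in_layer if nr.subvolume == best]


def summarize_by_layer(
    neurons: list[NeuronRecord],
    trials: list[Trial],
    classes: dict[int, NeuronClass],
    frame_rate_hz: float = 7.0,
    seed: int | None = None,
    decode_types: tuple[str, ...] = ("W1P", "W2P"),
    with_ensembles: bool = True,
) -> dict[str, pd.DataFrame]:
    """Machine-readable analogue of the per-layer figure panels.

    Produces class frequencies (+ field-of-view extrapolation), responsive
    pool size and probabilities, top-percentile response concentration,
    per-class force/identity AUC, per-class mean correlations under both
    time masks, and ensemble counts/sizes/composition.
    """
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    freq = class_frequency_table(neurons, classes)
    tables["class_frequency"] = freq
    tables["fov_extrapolation"] = fov_extrapolation(freq)

    table, pool = build_response_table(
        neurons, trials, frame_rate_hz=frame_rate_hz,
        seed=int(rng.integers(2**31)),
    )
    rows = []
    for layer in sorted({nr.layer for nr in neurons}):
        ids = {nr.neuron_id for nr in neurons if nr.layer == layer}
        pooled = set().union(*pool.members.values()) if pool.members else set()
        in_pool = ids & pooled
        probs = [
            max(table.probability[i].values()) for i in in_pool
        ]
        rows.append(
            {
                "layer": layer,
                "responsive_pool_fraction": len(in_pool) / len(ids) if ids else 0.0,
                "pool_mean_response_probability": float(np.mean(probs)) if probs else np.nan,
            }
        )
    tables["responsive_pool"] = pd.DataFrame(rows)

    counts = touch_evoked_event_counts(neurons, trials, frame_rate_hz)
    rows = []
    for layer in sorted({nr.layer for nr in neurons}):
        layer_counts = {
            nr.neuron_id: counts[nr.neuron_id]
            for nr in neurons if nr.layer == layer
        }
        try:
            frac = touch_response_concentration(layer_counts)
        except ValueError:
            frac = np.nan
        rows.append({"layer": layer, "top_percentile_fraction": frac})
    tables["response_concentration"] = pd.DataFrame(rows)

    rows = []
    for nr in neurons:
        cls = classes[nr.neuron_id].label
        for tt in decode_types:
            res = decode_force(nr, trials, tt, frame_rate_hz)
            if res.auc is not None:
                rows.append(
                    {"layer": nr.layer, "class": cls,
                     "contrast": res.contrast, "auc": res.auc}
                )
        res = decode_identity(nr, trials, frame_rate_hz)
        if res.auc is not None:
            rows.append(
                {"layer": nr.layer, "class": cls,
                 "contrast": "identity", "auc": res.auc}
            )
    dec = pd.DataFrame(rows)
    if not dec.empty:
        tables["decoding"] = (
            dec.groupby(["layer", "class", "contrast"])["auc"]
            .agg(["mean", "count"]).reset_index()
        )
    else:
        tables["decoding"] = dec

    if with_ensembles:
        mask_nt = nontouch_time_mask(trials, frame_rate_hz)
        rows_corr = []
        rows_ens = []
        for layer in sorted({nr.layer for nr in neurons}):
            sub = _largest_layer_subvolume(neurons, layer)
            if len(sub) < 3:
                continue
            for mask, kind in ((None, "all-time"), (mask_nt, "non-touch")):
                ens, corr, thr = detect_ensembles(sub, mask=mask, mask_kind=kind)
                if kind == "all-time":
                    labeled = label_touch_ensembles(ens, classes)
                    sizes = [len(e) for e in labeled]
                    member_union = set().union(*[e.members for e in labeled]) if labeled else set()
                    rows_ens.append(
                        {
                            "layer": layer,
                            "n_ensembles": len(labeled),
                            "n_touch_ensembles": sum(e.touch for e in labeled),
                            "mean_size": float(np.mean(sizes)) if sizes else np.nan,
                            "fraction_in_ensemble": len(member_union) / len(sub),
                            "threshold": thr,
                        }
                    )
                for cls in ("uSW", "bSW", "MW"):
                    rows_corr.append(
                        {
                            "layer": layer, "class": cls, "mask": kind,
                            "mean_correlation": class_pair_mean_correlation(
                                corr, classes, cls
                            ),
                        }
                    )
        tables["ensembles"] = pd.DataFrame(rows_ens)
        tables["correlations"] = pd.DataFrame(rows_corr)
    return tables


def run_pipeline(
    config, seed: int | None = None, folds: int = 5, restarts: int = 2
) -> PipelineResults:
    """Simulate a dataset and run every stage on it.

    Stage order: simulate -> fit/classify -> respond -> decode ->
    correlate/ensembles -> summarise.  ``seed`` overrides the config seed
    for the analysis stages.
    """
    from .synthetic import generate_dataset

    trials, neurons, truth = generate_dataset(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes, scores, thresholds = classify_population(
        neurons, trials, config.frame_rate_hz, folds=folds,
        restarts=restarts, seed=int(rng.integers(2**31)),
    )
    tables = summarize_by_layer(
        neurons, trials, classes, config.frame_rate_hz,
        seed=int(rng.integers(2**31)),
    )
    return PipelineResults(
        trials=trials, neurons=neurons, classes=classes, scores=scores,
        thresholds=thresholds, summary_tables=tables,
    )
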