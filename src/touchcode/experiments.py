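"""Reproducibility experiments: self-contained simulation studies that
quantify how well each analysis stage recovers known ground truth.

Each experiment generates its own synthetic dataset, runs the relevant
stage(s), and returns a flat dict of summary numbers.  They are used by the
validation test suite and the reproduction script; problem sizes default to
values that keep a full run in the minutes range on one core.
"""

from __future__ import annotations

import numpy as np

from .data import TOUCH_TYPES
from .decoding import roc_auc
from .encoding import EncodingScore
from .ensembles import detect_ensembles
from .population import classify_population, fov_extrapolation
from .response import build_response_table
from .synthetic import (
    DEFAULT_CLASS_FREQUENCIES,
    EnsembleSpec,
    SimConfig,
    generate_dataset,
)


def parameter_recovery_experiment(
    n_per_class: int = 50,
    n_trials: int = 120,
    seed: int = 0,
    folds: int = 5,
    restarts: int = 2,
) -> dict[str, float]:
    """Simulate neurons of every class and refit them; summarise recovery.

    Relative errors are computed for the parameters the data identify:
    slopes and offsets of the touch types a neuron actually responds to
    (terms with true slope 0 have no identifiable offset), the kernel time
    constants and the session scalings of touch neurons.  Medians are taken
    across neurons.  Class recovery is the fraction of neurons whose
    shuffle-calibrated label matches the generating class.
    """
    cfg = SimConfig(
        n_trials=n_trials, seed=seed,
        n_neurons_by_class_and_layer={
            "L3": {
                "uSW": n_per_class, "bSW": n_per_class,
                "MW": n_per_class, "non-touch": n_per_class,
            }
        },
    )
    trials, neurons, truth = generate_dataset(cfg)
    classes, scores, _, params = classify_population(
        neurons, trials, cfg.frame_rate_hz, folds=folds, restarts=restarts,
        seed=seed + 1, return_params=True,
    )

    err_s, err_o, err_tr, err_td, err_d = [], [], [], [], []
    for nr in neurons:
        true = truth.params[nr.neuron_id]
        if not (np.any(true.s_pro > 0) or np.any(true.s_ret > 0)):
            continue
        fit = params[nr.neuron_id]
        for s_true, s_fit, o_true, o_fit in (
            (true.s_pro, fit.s_pro, true.o_pro, fit.o_pro),
            (true.s_ret, fit.s_ret, true.o_ret, fit.o_ret),
        ):
            for w in range(2):
                if s_true[w] > 0:
                    err_s.append(abs(s_fit[w] - s_true[w]) / s_true[w])
                    err_o.append(abs(o_fit[w] - o_true[w]) / o_true[w])
        err_tr.append(abs(fit.tau_rise - true.tau_rise) / true.tau_rise)
        err_td.append(abs(fit.tau_decay - true.tau_decay) / true.tau_decay)
        for sid, dv in true.d.items():
            err_d.append(abs(fit.d[sid] - dv) / dv)

    recovered = np.mean(
        [classes[n].label == truth.classes[n].label for n in classes]
    )
    return {
        "s_median_rel_err_pct": 100 * float(np.median(err_s)),
        "o_median_rel_err_pct": 100 * float(np.median(err_o)),
        "tau_rise_median_rel_err_pct": 100 * float(np.median(err_tr)),
        "tau_decay_median_rel_err_pct": 100 * float(np.median(err_td)),
        "d_median_rel_err_pct": 100 * float(np.median(err_d)),
        "class_recovery_pct": 100 * float(recovered),
        "n_neurons": len(neurons),
    }


def null_calibration_experiment(
    n_neurons: int = 100, n_trials: int = 100, seed: int = 0
) -> dict[str, float]:
    """False-positive rates of both significance screens on pure noise.

    All neurons are non-touch (their traces are Gaussian noise around 0),
    so any neuron passing the shuffle-calibrated encoding criterion for a
    touch type, and any trial scored responsive, is a false positive.
    """
    cfg = SimConfig(
        n_trials=n_trials, seed=seed,
        n_neurons_by_class_and_layer={"L3": {"non-touch": n_neurons}},
    )
    trials, neurons, truth = generate_dataset(cfg)
    classes, scores, thresholds = classify_population(
        neurons, trials, cfg.frame_rate_hz, restarts=1, seed=seed + 1
    )
    per_type = []
    for tt in TOUCH_TYPES:
        n_pass = sum(
            EncodingScore(r=scores[n], threshold=thresholds[n]).passes(tt)
            for n in scores
        )
        per_type.append(n_pass / n_neurons)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, pool = build_response_table(
            neurons, trials, cfg.frame_rate_hz, seed=seed + 2
        )
    n_resp = sum(sum(r.values()) for r in table.responded.values())
    n_total = sum(len(r) for r in table.responded.values())
    pooled = set().union(*pool.members.values()) if pool.members else set()
    return {
        "classification_fp_pct_max_type": 100 * max(per_type),
        "classification_fp_pct_mean_type": 100 * float(np.mean(per_type)),
        "response_trial_fp_pct": 100 * n_resp / n_total,
        "response_pool_fp_pct": 100 * len(pooled) / n_neurons,
        "n_neurons": n_neurons,
    }


def ensemble_recovery_experiment(
    seed: int = 0,
    n_background: int = 300,
    sizes: tuple[int, ...] = (5, 8, 12),
    n_trials: int = 150,
) -> dict[str, float]:
    """Recovery of planted correlated ensembles and the matched null.

    Ensembles are planted at the generator's default coupling (shared
    latent events placing the within-ensemble correlation above twice the
    background 99.5th percentile) on an otherwise uncorrelated population;
    the matched null uses the identical configuration without ensembles.
    """
    cfg = SimConfig(
        n_trials=n_trials, seed=seed, p_touchless=1.0,
        n_neurons_by_class_and_layer={"L3": {"non-touch": n_background}},
        ensemble_spec=[EnsembleSpec(size=s) for s in sizes],
    )
    trials, neurons, truth = generate_dataset(cfg)
    detected, corr, thr = detect_ensembles(neurons)
    jaccards = []
    for true in truth.ensembles:
        true_set = set(true)
        best = max(
            (
                len(true_set & set(e.members)) / len(true_set | set(e.members))
                for e in detected
            ),
            default=0.0,
        )
        jaccards.append(best)

    cfg_null = SimConfig(
        n_trials=n_trials, seed=seed + 1, p_touchless=1.0,
        n_neurons_by_class_and_layer={"L3": {"non-touch": n_background}},
    )
    _, null_neurons, _ = generate_dataset(cfg_null)
    null_detected, _, _ = detect_ensembles(null_neurons)
    return {
        "min_jaccard": float(min(jaccards)),
        "mean_jaccard": float(np.mean(jaccards)),
        "n_detected": len(detected),
        "n_null_detected": len(null_detected),
        "threshold": thr,
    }


def roc_oracle_experiment(
    n_instances: int = 200, max_trials: int = 50, seed: int = 0
) -> dict[str, float]:
    """Agreement of the rank-sum AUC with a brute-force all-pairs oracle."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        na = int(rng.integers(1, max_trials + 1))
        nb = int(rng.integers(1, max_trials + 1))
        # integer grid values force plenty of ties
        a = rng.integers(-4, 5, size=na).astype(float)
        b = rng.integers(-4, 5, size=nb).astype(float)
        brute = sum(
            (y > x) + 0.5 * (y == x) for x in a for y in b
        ) / (na * nb)
        max_err = max(max_err, abs(roc_auc(a, b) - brute))
    return {"max_abs_error": float(max_err), "n_instances": n_instances}


def fov_extrapolation_table() -> dict[str, float]:
    """7/2-scaled per-layer touch-class percentages from the default
    per-layer frequencies (percent units)."""
    import pandas as pd

    rows = []
    for layer, freqs in DEFAULT_CLASS_FREQUENCIES.items():
        row = {"layer": layer, "n_neurons": 0}
        row.update(freqs)
        row["non-touch"] = 1.0 - sum(freqs.values())
        rows.append(row)
    ext = fov_extrapolation(pd.DataFrame(rows))
    out = {}
    for _, row in ext.iterrows():
        for cls in ("uSW", "bSW", "MW"):
            out[f"{cls.lower()}_{row['layer'].lower()}_pct"] = float(
                row[f"{cls}_fov_pct"]
            )
    return out
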