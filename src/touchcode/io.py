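"""HDF5 container and CSV side tables for datasets and fit results.

Layout of the HDF5 container:

* ``/trials``: per-trial groups with Δκ arrays and attributes (session,
  pole, frame span, trial type, first lick), touch tables as datasets.
* ``/neurons``: one ΔF/F matrix per subvolume ordering plus metadata.
* ``/truth`` (optional): generating parameters and planted memberships.

CSV sidecars carry the touch-event and neuron-metadata tables with the
documented column names.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import NeuronRecord, TouchEvent, Trial

TOUCH_COLUMNS = [
    "trial_id", "whisker_id", "direction", "onset_frame", "offset_frame",
    "peak_dkappa",
]
NEURON_COLUMNS = ["neuron_id", "depth_um", "layer", "subvolume"]


def _string_dataset(group, name, values) -> None:
    """String dataset that tolerates empty value lists."""
    ds = group.create_dataset(name, shape=(len(values),), dtype=h5py.string_dtype())
    if len(values):
        ds[...] = list(values)


def touch_events_frame(trials: list[Trial]) -> pd.DataFrame:
    rows = [
        {
            "trial_id": t.trial_id, "whisker_id": ev.whisker_id,
            "direction": ev.direction, "onset_frame": ev.onset_frame,
            "offset_frame": ev.offset_frame, "peak_dkappa": ev.peak_dkappa,
        }
        for t in trials for ev in t.sorted_touches
    ]
    return pd.DataFrame(rows, columns=TOUCH_COLUMNS)


def neuron_metadata_frame(neurons: list[NeuronRecord]) -> pd.DataFrame:
    rows = [
        {
            "neuron_id": nr.neuron_id, "depth_um": nr.depth_um,
            "layer": nr.layer, "subvolume": nr.subvolume,
        }
        for nr in neurons
    ]
    return pd.DataFrame(rows, columns=NEURON_COLUMNS)


def write_dataset(
    path: str | Path,
    trials: list[Trial],
    neurons: list[NeuronRecord],
    truth=None,
    frame_rate_hz: float = 7.0,
) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate_hz"] = frame_rate_hz
        tg = f.create_group("trials")
        ev = touch_events_frame(trials)
        tg.create_dataset("touch_trial_id", data=ev["trial_id"].to_numpy(dtype=np.int64))
        tg.create_dataset("touch_whisker_id", data=ev["whisker_id"].to_numpy(dtype=np.int64))
        _string_dataset(tg, "touch_direction", ev["direction"])
        tg.create_dataset("touch_onset_frame", data=ev["onset_frame"].to_numpy(dtype=np.int64))
        tg.create_dataset("touch_offset_frame", data=ev["offset_frame"].to_numpy(dtype=np.int64))
        tg.create_dataset("touch_peak_dkappa", data=ev["peak_dkappa"].to_numpy(dtype=float))
        tg.create_dataset(
            "trial_id", data=np.array([t.trial_id for t in trials], dtype=np.int64)
        )
        tg.create_dataset(
            "session_id", data=np.array([t.session_id for t in trials], dtype=np.int64)
        )
        _string_dataset(tg, "pole", [t.pole for t in trials])
        _string_dataset(tg, "trial_type", [t.trial_type for t in trials])
        tg.create_dataset(
            "frame_span",
            data=np.array([t.frame_span for t in trials], dtype=np.int64),
        )
        tg.create_dataset(
            "first_lick_frame",
            data=np.array(
                [-1 if t.first_lick_frame is None else t.first_lick_frame for t in trials],
                dtype=np.int64,
            ),
        )
        tg.create_dataset(
            "dkappa", data=np.stack([t.dkappa for t in trials])
        )

        ng = f.create_group("neurons")
        ng.create_dataset("dff", data=np.stack([nr.dff for nr in neurons]))
        meta = neuron_metadata_frame(neurons)
        ng.create_dataset("neuron_id", data=meta["neuron_id"].to_numpy(dtype=np.int64))
        ng.create_dataset("depth_um", data=meta["depth_um"].to_numpy())
        _string_dataset(ng, "layer", meta["layer"])
        ng.create_dataset("subvolume", data=meta["subvolume"].to_numpy(dtype=np.int64))

        if truth is not None:
            gg = f.create_group("truth")
            _string_dataset(
                gg, "class_label",
                [truth.classes[nid].label for nid in sorted(truth.classes)],
            )
            for k, members in enumerate(truth.ensembles):
                gg.create_dataset(
                    f"ensemble_{k}", data=np.array(members, dtype=np.int64)
                )
                gg.create_dataset(
                    f"ensemble_{k}_events",
                    data=np.asarray(truth.ensemble_event_frames[k], dtype=np.int64),
                )
    # CSV sidecars
    touch_events_frame(trials).to_csv(path.with_suffix(".touches.csv"), index=False)
    neuron_metadata_frame(neurons).to_csv(path.with_suffix(".neurons.csv"), index=False)


def read_dataset(path: str | Path) -> tuple[list[Trial], list[NeuronRecord], float]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        frame_rate = float(f.attrs["frame_rate_hz"])
        tg = f["trials"]
        n_trials = tg["trial_id"].shape[0]
        touch_by_trial: dict[int, list[TouchEvent]] = {}
        for tid, w, d, on, off, pk in zip(
            tg["touch_trial_id"][:], tg["touch_whisker_id"][:],
            tg["touch_direction"][:], tg["touch_onset_frame"][:],
            tg["touch_offset_frame"][:], tg["touch_peak_dkappa"][:],
        ):
            touch_by_trial.setdefault(int(tid), []).append(
                TouchEvent(
                    whisker_id=int(w),
                    direction=d.decode() if isinstance(d, bytes) else str(d),
                    onset_frame=int(on), offset_frame=int(off),
                    peak_dkappa=float(pk),
                )
            )
        trials = []
        dk = tg["dkappa"][:]
        for i in range(n_trials):
            tid = int(tg["trial_id"][i])
            ttype = tg["trial_type"][i]
            pole = tg["pole"][i]
            lick = int(tg["first_lick_frame"][i])
            trials.append(
                Trial(
                    trial_id=tid,
                    session_id=int(tg["session_id"][i]),
                    pole=pole.decode() if isinstance(pole, bytes) else str(pole),
                    frame_span=tuple(int(x) for x in tg["frame_span"][i]),
                    dkappa=dk[i],
                    touches=touch_by_trial.get(tid, []),
                    first_lick_frame=None if lick < 0 else lick,
                    trial_type=ttype.decode() if isinstance(ttype, bytes) else str(ttype),
                )
            )
        ng = f["neurons"]
        dff = ng["dff"][:]
        neurons = []
        for i in range(dff.shape[0]):
            layer = ng["layer"][i]
            neurons.append(
                NeuronRecord(
                    neuron_id=int(ng["neuron_id"][i]),
                    dff=dff[i],
                    depth_um=float(ng["depth_um"][i]),
                    layer=layer.decode() if isinstance(layer, bytes) else str(layer),
                    subvolume=int(ng["subvolume"][i]),
                )
            )
    return trials, neurons, frame_rate


def params_frame(params_by_neuron: dict, scores_by_neuron: dict | None = None) -> pd.DataFrame:
    """One row per neuron with every encoding parameter and per-type score."""
    rows = []
    for nid in sorted(params_by_neuron):
        p = params_by_neuron[nid]
        row = {
            "neuron_id": nid,
            "s_pro_w1": p.s_pro[0], "s_pro_w2": p.s_pro[1],
            "s_ret_w1": p.s_ret[0], "s_ret_w2": p.s_ret[1],
            "o_pro_w1": p.o_pro[0], "o_pro_w2": p.o_pro[1],
            "o_ret_w1": p.o_ret[0], "o_ret_w2": p.o_ret[1],
            "tau_rise_s": p.tau_rise, "tau_decay_s": p.tau_decay,
            "j_w1w2": p.j_w1w2, "j_w2w1": p.j_w2w1, "sigma2": p.sigma2,
        }
        for sid, v in sorted(p.d.items()):
            row[f"d_session_{sid}"] = v
        if scores_by_neuron is not None and nid in scores_by_neuron:
            for t, r in scores_by_neuron[nid].items():
                row[f"score_{t}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
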