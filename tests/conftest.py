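import numpy as np
import pytest

from touchcode import SimConfig, TouchEvent, Trial, generate_dataset

FRAME_RATE = 7.0
NF = 70  # frames per 10 s trial


def make_trial(
    trial_id=0,
    session_id=0,
    touches=(),
    n_frames=NF,
    start=None,
    first_lick_frame=None,
    trial_type=None,
):
    """Build a trial from (whisker, direction, onset, offset, peak) tuples.

    Frames in the tuples are trial-local; the trial is placed at
    ``start = trial_id * n_frames`` by default.
    """
    if start is None:
        start = trial_id * n_frames
    dkappa = np.zeros((2, n_frames))
    events = []
    for w, d, on, off, pk in touches:
        events.append(TouchEvent(w, d, start + on, start + off, pk))
        dkappa[w - 1, on:off] = pk
    if trial_type is None:
        whiskers = {e.whisker_id for e in events}
        trial_type = {
            frozenset(): "none", frozenset({1}): "W1-only",
            frozenset({2}): "W2-only", frozenset({1, 2}): "multi",
        }[frozenset(whiskers)]
    return Trial(
        trial_id=trial_id, session_id=session_id,
        pole="proximal" if events else "distal",
        frame_span=(start, start + n_frames), dkappa=dkappa,
        touches=events,
        first_lick_frame=None if first_lick_frame is None else start + first_lick_frame,
        trial_type=trial_type,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed-class dataset shared by read-only tests."""
    cfg = SimConfig(
        n_trials=120, seed=1234,
        n_neurons_by_class_and_layer={
            "L3": {"uSW": 2, "bSW": 1, "MW": 1, "non-touch": 2}
        },
    )
    trials, neurons, truth = generate_dataset(cfg)
    return cfg, trials, neurons, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
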