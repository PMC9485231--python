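import numpy as np
import pytest

from touchcode import (
    LayerBounds,
    SimConfig,
    exclude_boundary_neurons,
    fov_extrapolation,
    generate_dataset,
    match_l4_noise,
    normalized_depth,
)
from touchcode.data import NeuronRecord
from touchcode.encoding import NeuronClass
from touchcode.population import (
    DEFAULT_BOUNDS,
    class_frequency_table,
    layer_of_depth,
    summarize_by_layer,
)

BOUNDS = LayerBounds.from_outer(100.0, 400.0)


class TestNormalizedDepth:
    @pytest.mark.parametrize(
        "depth,expected", [(100.0, 0.0), (250.0, 1.0), (400.0, 2.0)]
    )
    def test_anchor_points(self, depth, expected):
        assert normalized_depth(depth, BOUNDS) == pytest.approx(expected)

    def test_l4_extends_beyond_two(self):
        # L3 thickness 150 um; 75 um below the L3-L4 border -> 2.5
        assert normalized_depth(475.0, BOUNDS) == pytest.approx(2.5)

    def test_above_l1_l2_border_raises(self):
        with pytest.raises(ValueError, match="L1-L2"):
            normalized_depth(50.0, BOUNDS)

    def test_strictly_increasing(self):
        depths = np.linspace(100.0, 600.0, 200)
        nds = [normalized_depth(d, BOUNDS) for d in depths]
        assert np.all(np.diff(nds) > 0)

    def test_midpoint_invariant_enforced(self):
        with pytest.raises(ValueError, match="midpoint"):
            LayerBounds(100.0, 200.0, 400.0)
        with pytest.raises(ValueError, match="increasing"):
            LayerBounds(400.0, 250.0, 100.0)

    def test_layer_assignment(self):
        assert layer_of_depth(150.0, BOUNDS) == "L2"
        assert layer_of_depth(300.0, BOUNDS) == "L3"
        assert layer_of_depth(450.0, BOUNDS) == "L4"


class TestBoundaryExclusion:
    def _neuron(self, depth):
        return NeuronRecord(0, np.zeros(10) - 0.01, depth, "L3")

    def test_neuron_at_border_excluded(self):
        assert exclude_boundary_neurons([self._neuron(250.0)], BOUNDS) == []
        assert exclude_boundary_neurons([self._neuron(400.0)], BOUNDS) == []

    def test_within_half_width_excluded_beyond_retained(self):
        assert exclude_boundary_neurons([self._neuron(274.0)], BOUNDS) == []
        kept = exclude_boundary_neurons([self._neuron(276.0)], BOUNDS)
        assert len(kept) == 1  # 26 um from the border

    def test_empty_input(self):
        assert exclude_boundary_neurons([], BOUNDS) == []


class TestL4NoiseMatching:
    def test_identical_statistics_alpha_one(self, rng):
        traces = [rng.normal(0, 0.1, 5000) for _ in range(6)]
        _, params = match_l4_noise(traces[:3], traces[3:], rng, per_cell=False)
        assert params.alpha == pytest.approx(1.0, abs=0.1)

    def test_half_amplitude_alpha_half(self, rng):
        l23 = [rng.normal(0, 0.1, 20000) + np.where(rng.random(20000) < 0.02, 2.0, 0.0)
               for _ in range(4)]
        l4 = [0.5 * tr for tr in l23]
        _, params = match_l4_noise(l23, l4, rng, per_cell=False)
        assert params.alpha == pytest.approx(0.5, rel=0.05)

    def test_zero_l4_noise_gives_exact_scaling(self, rng):
        l23 = [rng.uniform(0.1, 1.0, 1000) for _ in range(3)]
        l4 = [rng.uniform(0.1, 0.5, 1000) for _ in range(3)]  # no negatives
        adjusted, params = match_l4_noise(l23, l4, rng, per_cell=False)
        assert params.noise_scale == 0.0
        for adj, tr in zip(adjusted, l23):
            np.testing.assert_allclose(adj, params.alpha * tr)

    def test_degenerate_trace_raises(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            match_l4_noise([np.zeros(100)], [rng.normal(size=100)], rng)

    def test_empty_group_raises(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            match_l4_noise([], [rng.normal(size=100)], rng)

    def test_noise_matching_reduces_touch_classification(self):
        # adding L4-level noise to clean traces can only lose detections
        from touchcode.population import classify_population

        cfg = SimConfig(
            n_trials=100, seed=41,
            noise_sd={"L2": 0.05, "L4": 0.6},
            n_neurons_by_class_and_layer={
                "L2": {"uSW": 4, "non-touch": 2}, "L4": {"non-touch": 4}
            },
        )
        trials, neurons, truth = generate_dataset(cfg)
        l2 = [nr for nr in neurons if nr.layer == "L2"]
        l4 = [nr for nr in neurons if nr.layer == "L4"]
        rng = np.random.default_rng(0)
        adjusted, _ = match_l4_noise(
            [nr.dff for nr in l2], [nr.dff for nr in l4], rng
        )
        classes, _, _ = classify_population(
            l2, trials, cfg.frame_rate_hz, restarts=1, seed=1
        )
        noisy = [
            NeuronRecord(nr.neuron_id, adj, nr.depth_um, nr.layer)
            for nr, adj in zip(l2, adjusted)
        ]
        classes_noisy, _, _ = classify_population(
            noisy, trials, cfg.frame_rate_hz, restarts=1, seed=1
        )
        n_before = sum(c.label != "non-touch" for c in classes.values())
        n_after = sum(c.label != "non-touch" for c in classes_noisy.values())
        assert n_after <= n_before


class TestSummaries:
    def _classes(self, neurons, labels):
        return {nr.neuron_id: NeuronClass(lab) for nr, lab in zip(neurons, labels)}

    def test_non_touch_population_all_zero_frequencies(self):
        neurons = [
            NeuronRecord(i, np.zeros(10) - 0.01, 300.0, "L3") for i in range(5)
        ]
        classes = self._classes(neurons, ["non-touch"] * 5)
        freq = class_frequency_table(neurons, classes)
        assert freq.loc[0, ["uSW", "bSW", "MW"]].sum() == 0.0
        assert freq.loc[0, "non-touch"] == 1.0

    def test_frequency_rows_sum_to_one(self):
        neurons = [
            NeuronRecord(i, np.zeros(10) - 0.01, 300.0, ["L2", "L3"][i % 2], )
            for i in range(10)
        ]
        labels = ["uSW", "bSW", "MW", "non-touch", "uSW"] * 2
        freq = class_frequency_table(neurons, self._classes(neurons, labels))
        for _, row in freq.iterrows():
            assert row[["non-touch", "uSW", "bSW", "MW"]].sum() == pytest.approx(1.0)

    def test_fov_extrapolation_is_seven_halves(self):
        neurons = [NeuronRecord(i, np.zeros(10) - 0.01, 300.0, "L3") for i in range(8)]
        labels = ["uSW", "uSW", "bSW", "MW", "non-touch", "non-touch", "non-touch", "non-touch"]
        freq = class_frequency_table(neurons, self._classes(neurons, labels))
        ext = fov_extrapolation(freq)
        for cls in ("uSW", "bSW", "MW"):
            assert ext.loc[0, f"{cls}_fov_pct"] == pytest.approx(
                3.5 * ext.loc[0, f"{cls}_pct"]
            )

    def test_summary_tables_present(self, small_dataset):
        cfg, trials, neurons, truth = small_dataset
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tables = summarize_by_layer(
                neurons, trials, truth.classes, cfg.frame_rate_hz, seed=0,
                with_ensembles=True,
            )
        for key in ("class_frequency", "fov_extrapolation", "responsive_pool",
                    "response_concentration", "decoding", "ensembles",
                    "correlations"):
            assert key in tables

    def test_largest_subvolume_selection(self):
        from touchcode.population import _largest_layer_subvolume

        neurons = [
            NeuronRecord(i, np.zeros(10) - 0.01, 300.0, "L3", subvolume=(0 if i < 3 else 1))
            for i in range(10)
        ]
        sub = _largest_layer_subvolume(neurons, "L3")
        assert {nr.subvolume for nr in sub} == {1} and len(sub) == 7
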