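import numpy as np
import pytest

from touchcode import (
    Ensemble,
    correlation_matrix,
    detect_ensembles,
    detection_threshold,
    ensemble_overlap,
    grow_ensemble,
    label_touch_ensembles,
    merge_ensembles,
    nontouch_time_mask,
    seed_clusters,
)
from touchcode.data import NeuronRecord
from touchcode.encoding import NeuronClass
from touchcode.ensembles import CorrelationMatrix

from conftest import make_trial


def neurons_from_traces(traces):
    return [NeuronRecord(i, tr, 300.0, "L3") for i, tr in enumerate(traces)]


def block_population(rng, n=40, block=(0, 1, 2, 3), r=0.8, n_frames=4000):
    """Independent noise plus one correlated block sharing a latent signal."""
    traces = rng.normal(size=(n, n_frames))
    shared = rng.normal(size=n_frames)
    lam = np.sqrt(r / (1 - r))
    for i in block:
        traces[i] = (traces[i] + lam * shared) / np.sqrt(1 + lam**2)
    return neurons_from_traces(traces)


class TestNontouchMask:
    def test_touchless_session_all_true(self):
        trials = [make_trial(trial_id=i) for i in range(3)]
        assert nontouch_time_mask(trials, 7.0).all()

    def test_single_touch_excludes_eleven_seconds(self):
        trials = [make_trial(trial_id=i) for i in range(3)]
        trials[1] = make_trial(trial_id=1, touches=[(1, "protraction", 30, 31, -1.0)])
        mask = nontouch_time_mask(trials, 7.0)
        # 1 s before + 10 s after = 11 s = 77 frames at 7 Hz
        assert (~mask).sum() == 77
        onset = 70 + 30
        assert not mask[onset - 7 : onset + 70].any()
        assert mask[onset - 8] and mask[onset + 70]

    def test_overlapping_windows_union(self):
        t = make_trial(
            trial_id=0, n_frames=300,
            touches=[(1, "protraction", 100, 101, -1.0),
                     (1, "protraction", 114, 115, -1.0)],  # 2 s apart
        )
        mask = nontouch_time_mask([t], 7.0)
        assert (~mask).sum() == 77 + 14  # union, no double counting


class TestCorrelationMatrix:
    def test_self_correlation_and_antiphase(self, rng):
        x = rng.normal(size=1000)
        corr = correlation_matrix(neurons_from_traces([x, x.copy(), -x]))
        assert corr.matrix[0, 1] == pytest.approx(1.0)
        assert corr.matrix[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        corr = correlation_matrix(
            neurons_from_traces(rng.normal(size=(2, 10_000)))
        )
        assert abs(corr.matrix[0, 1]) < 0.05

    def test_zero_variance_is_nan_excluded(self, rng):
        traces = [rng.normal(size=100), np.zeros(100), rng.normal(size=100)]
        corr = correlation_matrix(neurons_from_traces(traces))
        assert np.isnan(corr.matrix[0, 1])
        assert not np.isnan(corr.matrix[0, 2])
        assert not np.any(np.isnan(corr.offdiag_values()))

    def test_mask_applies(self, rng):
        a = rng.normal(size=200)
        b = a.copy()
        b[100:] = rng.normal(size=100)  # only first half matches
        mask = np.zeros(200, dtype=bool)
        mask[:100] = True
        corr = correlation_matrix(neurons_from_traces([a, b]), mask=mask)
        assert corr.matrix[0, 1] == pytest.approx(1.0)

    def test_too_few_unmasked_frames(self, rng):
        mask = np.zeros(100, dtype=bool)
        mask[0] = True
        with pytest.raises(ValueError, match="unmasked"):
            correlation_matrix(neurons_from_traces(rng.normal(size=(3, 100))), mask=mask)


class TestDetectionThreshold:
    def _corr_with_offdiag(self, values):
        n = len(values) + 1
        m = np.eye(n)
        # place the values on the first row/column for a valid symmetric matrix
        for k, v in enumerate(values):
            m[0, k + 1] = m[k + 1, 0] = v
        return CorrelationMatrix(neuron_ids=list(range(n)), matrix=m)

    def test_twice_percentile(self):
        corr = self._corr_with_offdiag([0.2] * 50)
        assert detection_threshold(corr) == pytest.approx(0.4, abs=0.02)

    def test_cap_at_099(self):
        corr = self._corr_with_offdiag([0.6] * 50)
        assert detection_threshold(corr) == pytest.approx(0.99)

    def test_all_zero(self):
        corr = self._corr_with_offdiag([0.0] * 50)
        assert detection_threshold(corr) == 0.0


class TestSeedClusters:
    def test_planted_block_recovered(self, rng):
        neurons = block_population(rng, block=(3, 8, 15, 22), r=0.8)
        corr = correlation_matrix(neurons)
        seeds = seed_clusters(corr, threshold=0.4)
        # the maximal passing seed contains the planted block (it may carry
        # one chance neuron, removed later by the growth/merge threshold)
        assert any({3, 8, 15, 22} <= set(s) for s in seeds)

    def test_independent_noise_no_seeds(self, rng):
        corr = correlation_matrix(neurons_from_traces(rng.normal(size=(30, 5000))))
        assert seed_clusters(corr) == []

    def test_two_disjoint_blocks(self, rng):
        neurons = block_population(rng, n=40, block=(0, 1, 2), r=0.8)
        shared = rng.normal(size=4000)
        lam = np.sqrt(0.8 / 0.2)
        for i in (10, 11, 12, 13):
            neurons[i].dff = (rng.normal(size=4000) + lam * shared) / np.sqrt(1 + lam**2)
        corr = correlation_matrix(neurons)
        seeds = seed_clusters(corr, threshold=0.4)
        hit1 = [s for s in seeds if {0, 1, 2} <= set(s)]
        hit2 = [s for s in seeds if {10, 11, 12, 13} <= set(s)]
        assert hit1 and hit2
        assert not (set(hit1[0]) & set(hit2[0]))  # blocks stay disjoint


class TestGrowEnsemble:
    def _toy_corr(self):
        # 6-neuron block at r=0.8, 4 background neurons near 0
        n = 10
        m = np.full((n, n), 0.01)
        for i in range(6):
            for j in range(6):
                m[i, j] = 0.8
        np.fill_diagonal(m, 1.0)
        return CorrelationMatrix(neuron_ids=list(range(n)), matrix=m)

    def test_grows_seed_to_full_block(self):
        corr = self._toy_corr()
        # threshold 0.6: background dilution (mean 0.574) stops growth at 6
        ens = grow_ensemble([0, 1, 2], corr, threshold=0.6)
        assert ens.members == frozenset(range(6))
        assert ens.mean_correlation == pytest.approx(0.8)

    def test_maximal_seed_fixed_point(self):
        corr = self._toy_corr()
        ens = grow_ensemble(list(range(6)), corr, threshold=0.6)
        assert ens.members == frozenset(range(6))

    def test_stops_before_diluting_below_threshold(self):
        corr = self._toy_corr()
        # high threshold: even one background neuron would dilute below it
        ens = grow_ensemble([0, 1, 2], corr, threshold=0.79)
        assert ens.members == frozenset(range(6))

    def test_seed_below_threshold_raises(self):
        corr = self._toy_corr()
        with pytest.raises(ValueError, match="seed"):
            grow_ensemble([6, 7, 8], corr, threshold=0.4)


class TestMergeAndOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({1, 2, 3}, {1, 2, 3}, 1.0), ({1, 2}, {3, 4}, 0.0),
         ({1, 2, 3}, {3, 4, 5}, 0.2)],
    )
    def test_overlap_values(self, a, b, expected):
        ea = Ensemble(frozenset(a), 0.5)
        eb = Ensemble(frozenset(b), 0.5)
        assert ensemble_overlap(ea, eb) == pytest.approx(expected)

    def _uniform_corr(self, n, r):
        m = np.full((n, n), r)
        np.fill_diagonal(m, 1.0)
        return CorrelationMatrix(neuron_ids=list(range(n)), matrix=m)

    def test_duplicates_collapse(self):
        corr = self._uniform_corr(6, 0.8)
        es = [Ensemble(frozenset({0, 1, 2}), 0.8)] * 3
        merged = merge_ensembles(es, corr, threshold=0.4)
        assert len(merged) == 1

    def test_half_overlap_not_merged(self):
        corr = self._uniform_corr(8, 0.8)
        a = Ensemble(frozenset({0, 1, 2, 3}), 0.8)
        b = Ensemble(frozenset({2, 3, 4, 5}), 0.8)  # overlap 1/3 < 0.75
        merged = merge_ensembles([a, b], corr, threshold=0.4)
        assert len(merged) == 2

    def test_high_overlap_merge_blocked_by_threshold(self):
        # two ensembles sharing 3 of 4 members, but the two non-shared
        # members are anti-correlated: the union fails the threshold
        n = 5
        m = np.full((n, n), 0.8)
        m[3, 4] = m[4, 3] = -1.0
        np.fill_diagonal(m, 1.0)
        corr = CorrelationMatrix(neuron_ids=list(range(n)), matrix=m)
        a = Ensemble(frozenset({0, 1, 2, 3}), 0.8)
        b = Ensemble(frozenset({0, 1, 2, 4}), 0.8)
        merged = merge_ensembles([a, b], corr, threshold=0.7)
        assert {e.members for e in merged} == {a.members, b.members}

    def test_high_overlap_merged_when_threshold_holds(self):
        corr = self._uniform_corr(5, 0.8)
        a = Ensemble(frozenset({0, 1, 2, 3}), 0.8)
        b = Ensemble(frozenset({0, 1, 2, 4}), 0.8)  # overlap 3/5 -> not merged
        c = Ensemble(frozenset({0, 1, 2, 3, 4}), 0.8)  # 4/5 with both
        merged = merge_ensembles([a, b, c], corr, threshold=0.4)
        assert len(merged) == 1 and merged[0].members == frozenset(range(5))

    def test_undersized_discarded(self):
        corr = self._uniform_corr(4, 0.8)
        small = Ensemble(frozenset({0, 1}), 0.8)
        merged = merge_ensembles([small], corr, threshold=0.4)
        assert merged == []


class TestTouchLabels:
    def _classes(self, labels):
        return {i: NeuronClass(lab) for i, lab in enumerate(labels)}

    def test_all_touch(self):
        cls = self._classes(["uSW", "bSW", "MW"])
        out = label_touch_ensembles([Ensemble(frozenset({0, 1, 2}), 0.5)], cls)
        assert out[0].touch is True
        assert out[0].composition["non-touch"] == 0.0

    def test_two_of_five_is_non_touch(self):
        cls = self._classes(["uSW", "uSW", "non-touch", "non-touch", "non-touch"])
        out = label_touch_ensembles([Ensemble(frozenset(range(5)), 0.5)], cls)
        assert out[0].touch is False  # 0.4 < 0.5

    def test_exactly_half_is_touch(self):
        cls = self._classes(["uSW", "MW", "non-touch", "non-touch"])
        out = label_touch_ensembles([Ensemble(frozenset(range(4)), 0.5)], cls)
        assert out[0].touch is True  # inclusive >=


def test_detector_permutation_equivariance(rng):
    neurons = block_population(rng, n=30, block=(2, 5, 9, 12, 20), r=0.75)
    ens1, _, _ = detect_ensembles(neurons)
    perm = rng.permutation(30)
    relabel = {old: new for new, old in enumerate(perm)}
    permuted = [
        NeuronRecord(relabel[nr.neuron_id], nr.dff, nr.depth_um, nr.layer)
        for nr in neurons
    ]
    permuted.sort(key=lambda nr: nr.neuron_id)
    ens2, _, _ = detect_ensembles(permuted)
    sets1 = {frozenset(relabel[n] for n in e.members) for e in ens1}
    sets2 = {e.members for e in ens2}
    assert sets1 == sets2
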