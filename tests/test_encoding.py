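import dataclasses

import numpy as np
import pytest

from touchcode import (
    EncodingParams,
    EncodingScore,
    SimConfig,
    TouchEncodingModel,
    classify_neuron,
    fit_interaction_terms,
    gcamp_kernel,
    generate_dataset,
    predict_trace,
    shuffled_null_scores,
    whisker_drive,
)
from touchcode.data import NeuronRecord
from touchcode.encoding import ParameterError, calcium_event_rate, sigma2_from_trace

from conftest import make_trial

DT = 1.0 / 7.0


def default_params(**over):
    base = dict(
        s_pro=[1.0, 0.0], s_ret=[0.0, 0.0], o_pro=[1.0, 1.0], o_ret=[1.0, 1.0],
        tau_rise=0.15, tau_decay=1.5, d={0: 1.0},
    )
    base.update(over)
    return EncodingParams(**base)


class TestKernel:
    @pytest.mark.parametrize("taus", [(0.1, 1.0), (0.3, 2.5), (0.5, 5.0)])
    def test_peak_normalised_and_zero_at_origin(self, taus):
        k = gcamp_kernel(*taus, dt=DT)
        assert k[0] == pytest.approx(0.0)
        assert k.max() == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_peak_time(self):
        # t* = ln(tau_d/tau_r) / (1/tau_r - 1/tau_d) = ln(10)/9 for (0.1, 1)
        k = gcamp_kernel(0.1, 1.0, dt=1e-4)
        t_star = np.argmax(k) * 1e-4
        assert t_star == pytest.approx(np.log(10.0) / 9.0, abs=2e-4)

    def test_invalid_time_constants(self):
        with pytest.raises(ParameterError):
            gcamp_kernel(1.0, 0.5, dt=DT)

    def test_dt_refinement_convergence(self):
        # peak stays 1 under dt halving; area converges to the analytic value
        area_exact = 0.0
        tr, td = 0.2, 2.0
        t_star = np.log(td / tr) / (1 / tr - 1 / td)
        peak = np.exp(-t_star / td) - np.exp(-t_star / tr)
        area_exact = (td - tr) / peak
        areas = []
        for dt in (DT, DT / 2, DT / 4, DT / 8):
            k = gcamp_kernel(tr, td, dt=dt, duration=60.0)
            assert k.max() == pytest.approx(1.0, abs=1e-9)
            areas.append(k.sum() * dt)
        errs = [abs(a - area_exact) for a in areas]
        assert errs[-1] < errs[0] and errs[-1] / area_exact < 0.01


class TestWhiskerDrive:
    def test_zero_curvature_zero_drive(self):
        assert not whisker_drive(np.zeros(50), 2.0, 1.0, 2.0, 1.0).any()

    def test_protraction_arithmetic(self):
        out = whisker_drive(np.array([-9.0]), 2.0, 1.0, 0.0, 1.0)
        assert out[0] == pytest.approx(2.0)  # 2*log10(9+1)

    def test_retraction_only_neuron_ignores_protraction(self):
        dk = -np.abs(np.random.default_rng(0).uniform(1, 50, size=30))
        assert not whisker_drive(dk, 0.0, 1.0, 3.0, 1.0).any()

    def test_drive_never_negative(self, rng):
        dk = rng.uniform(-60, 60, size=200)
        out = whisker_drive(dk, 1.5, 0.1, 2.0, 0.1)
        assert np.all(out >= 0)


class TestPredictTrace:
    def test_zero_drive_zero_prediction(self):
        t = make_trial()
        p = default_params()
        assert not predict_trace(p, [t], 7.0).any()

    def test_impulse_reproduces_kernel_and_d_linearity(self):
        # one 1-frame protraction touch of amplitude giving drive A
        t = make_trial(touches=[(1, "protraction", 5, 6, -9.0)])
        p = default_params(s_pro=[2.0, 0.0])  # drive = 2*log10(10) = 2
        pred = predict_trace(p, [t], 7.0)
        k = gcamp_kernel(p.tau_rise, p.tau_decay, DT)
        expected = np.zeros(70)
        m = min(len(k), 65)
        expected[5 : 5 + m] = 2.0 * k[:m]
        np.testing.assert_allclose(pred, expected, atol=1e-12)
        p_half = default_params(s_pro=[2.0, 0.0], d={0: 0.5})
        np.testing.assert_allclose(predict_trace(p_half, [t], 7.0), pred / 2)

    def test_linear_in_slope(self):
        t = make_trial(touches=[(1, "protraction", 5, 7, -20.0)])
        one = predict_trace(default_params(s_pro=[1.0, 0.0]), [t], 7.0)
        three = predict_trace(default_params(s_pro=[3.0, 0.0]), [t], 7.0)
        np.testing.assert_allclose(three, 3 * one, atol=1e-12)

    def test_missing_session_scaling_raises(self):
        t = make_trial(session_id=3)
        with pytest.raises(ParameterError, match="session"):
            predict_trace(default_params(), [t], 7.0)


class TestFit:
    def test_noiseless_self_consistency(self, small_dataset):
        cfg, trials, _, truth = small_dataset
        p = next(
            truth.params[n] for n, c in truth.classes.items() if c.label == "uSW"
        )
        noiseless = dataclasses.replace(p, sigma2=0.0, d=dict(p.d))
        trace = predict_trace(noiseless, trials, cfg.frame_rate_hz)
        trace = trace - 1e-4  # tiny negative floor so sigma2 is estimable
        res = TouchEncodingModel(trace, trials, cfg.frame_rate_hz).fit(seed=0)
        best = max(res.score.r.values())
        assert best > 0.99

    def test_parameter_recovery_with_noise(self, small_dataset):
        cfg, trials, neurons, truth = small_dataset
        for nr in neurons:
            c = truth.classes[nr.neuron_id]
            if c.label != "bSW":
                continue
            p = truth.params[nr.neuron_id]
            res = TouchEncodingModel(nr.dff, trials, cfg.frame_rate_hz).fit(seed=1)
            q = res.params
            w = c.whisker - 1
            assert abs(q.s_pro[w] - p.s_pro[w]) / p.s_pro[w] < 0.10
            assert abs(q.s_ret[w] - p.s_ret[w]) / p.s_ret[w] < 0.10
            assert abs(q.tau_decay - p.tau_decay) / p.tau_decay < 0.10
            for sid, dv in p.d.items():
                assert abs(q.d[sid] - dv) < 0.10

    def test_pure_noise_scores_near_zero(self, small_dataset):
        cfg, trials, _, _ = small_dataset
        trace = np.random.default_rng(2).normal(0, 0.1, trials[-1].frame_span[1])
        res = TouchEncodingModel(trace, trials, cfg.frame_rate_hz).fit(seed=2)
        assert all(abs(r) < 0.1 for r in res.score.r.values())

    def test_too_few_trials_raises(self):
        trials = [make_trial(trial_id=i) for i in range(3)]
        trace = np.zeros(trials[-1].frame_span[1]) - 0.01
        with pytest.raises(ValueError, match="trials"):
            TouchEncodingModel(trace, trials, 7.0).fit()

    def test_sigma2_estimator(self, rng):
        noise = rng.normal(0.0, 0.2, 100_000)
        assert sigma2_from_trace(noise) == pytest.approx(0.04, rel=0.02)

    def test_cv_not_above_in_sample(self, small_dataset):
        # cross-validated scores should not systematically beat in-sample fit
        cfg, trials, neurons, truth = small_dataset
        from touchcode.encoding import _pearson, _score_touch_type

        diffs = []
        for nr in neurons:
            res = TouchEncodingModel(nr.dff, trials, cfg.frame_rate_hz).fit(seed=3)
            ins = res.in_sample_prediction
            for tt, r_cv in res.score.r.items():
                r_in = _score_touch_type(nr.dff, ins, trials, tt)
                diffs.append(r_in - r_cv)
        assert np.mean(diffs) > -0.01


class TestInteractions:
    def _dataset(self, j, seed):
        cfg = SimConfig(
            n_trials=160, seed=seed, p_touchless=0.3,
            touch_type_mix=(0.25, 0.25, 0.5), j_range=(j, j),
            n_neurons_by_class_and_layer={"L3": {"MW": 1}},
        )
        return cfg, *generate_dataset(cfg)

    def test_suppressive_gain_recovery(self):
        cfg, trials, neurons, truth = self._dataset(0.5, seed=21)
        res = TouchEncodingModel(neurons[0].dff, trials, cfg.frame_rate_hz).fit(seed=0)
        assert abs(res.params.j_w1w2 - 0.5) / 0.5 < 0.2
        assert abs(res.params.j_w2w1 - 0.5) / 0.5 < 0.2

    def test_neutral_gain_recovery(self):
        cfg, trials, neurons, truth = self._dataset(1.0, seed=22)
        res = TouchEncodingModel(neurons[0].dff, trials, cfg.frame_rate_hz).fit(seed=0)
        assert abs(res.params.j_w1w2 - 1.0) < 0.15
        assert abs(res.params.j_w2w1 - 1.0) < 0.15

    def test_no_qualifying_trials_returns_neutral_with_warning(self, small_dataset):
        cfg, trials, _, truth = small_dataset
        p = dataclasses.replace(truth.params[0], d=dict(truth.params[0].d))
        sw_only = [t for t in trials if t.trial_type != "multi"]
        trace = np.zeros(sw_only[-1].frame_span[1]) - 0.01
        with pytest.warns(UserWarning, match="200 ms"):
            out, warning = fit_interaction_terms(p, trace, sw_only, cfg.frame_rate_hz)
        assert out.j_w1w2 == 1.0 and out.j_w2w1 == 1.0 and warning is not None


class TestShuffledNulls:
    def test_shift_destroys_score_and_bins_are_equal(self):
        cfg = SimConfig(
            n_trials=60, seed=31,
            n_neurons_by_class_and_layer={"L3": {"uSW": 4, "non-touch": 4}},
        )
        trials, neurons, truth = generate_dataset(cfg)
        thresholds, null_sets = shuffled_null_scores(
            neurons, trials, cfg.frame_rate_hz, n_bins=4, seed=0
        )
        assert set(thresholds) == {nr.neuron_id for nr in neurons}
        # equal-count bins: 8 neurons in 4 bins of 2, pooling 4 types each
        sizes = {ns.size for ns in null_sets.values()}
        assert sizes == {8}
        # shuffled fits should not reach the strong scores real fits get
        for nid, thr in thresholds.items():
            assert thr["W1P"] < 0.9

    def test_all_zero_traces_score_zero(self):
        cfg = SimConfig(n_trials=40, seed=32,
                        n_neurons_by_class_and_layer={"L3": {"non-touch": 2}})
        trials, neurons, _ = generate_dataset(cfg)
        flat = [
            NeuronRecord(nr.neuron_id, np.zeros_like(nr.dff), nr.depth_um, nr.layer)
            for nr in neurons
        ]
        thresholds, null_sets = shuffled_null_scores(
            flat, trials, cfg.frame_rate_hz, n_bins=2, seed=0
        )
        for ns in null_sets.values():
            np.testing.assert_array_equal(ns, 0.0)


class TestClassification:
    def _score(self, passing):
        r = {t: (0.5 if t in passing else 0.0) for t in ("W1P", "W1R", "W2P", "W2R")}
        thr = {t: 0.2 for t in r}
        return EncodingScore(r=r, threshold=thr)

    def test_single_type_is_unidirectional(self):
        c = classify_neuron(self._score({"W1P"}))
        assert (c.label, c.whisker, c.direction) == ("uSW", 1, "protraction")

    def test_both_directions_one_whisker_is_bidirectional(self):
        c = classify_neuron(self._score({"W1P", "W1R"}))
        assert (c.label, c.whisker) == ("bSW", 1)

    def test_one_direction_each_whisker_is_multiwhisker(self):
        assert classify_neuron(self._score({"W1P", "W2R"})).label == "MW"

    def test_no_pass_is_non_touch(self):
        assert classify_neuron(self._score(set())).label == "non-touch"

    def test_pass_requires_absolute_floor(self):
        r = {t: 0.05 for t in ("W1P", "W1R", "W2P", "W2R")}
        score = EncodingScore(r=r, threshold={t: 0.0 for t in r})
        assert classify_neuron(score).label == "non-touch"


def test_event_rate_counts_separated_crossings():
    fr = 7.0
    trace = np.full(700, -0.05)  # gives sigma ~ 0.05
    trace[::140] = 1.0  # 5 well-separated events
    rate = calcium_event_rate(trace, fr)
    assert rate == pytest.approx(5 / 100.0)
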