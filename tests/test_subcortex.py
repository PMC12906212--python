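"""Subcortical pathway: receptive fields, perceptron, random E/I network,
and cortico-subcortical suppression."""

import numpy as np
import pytest

from shallowbrain.decision import run_trials
from shallowbrain.subcortex import (N_EXC, N_INH, InhibitionMode,
                                    InhibitoryProjection, RNNGains, RNNState,
                                    readout_batch, readout_receptive_fields,
                                    sample_subcortex_rnn, step_subcortex_rnn,
                                    subcortex_ff_preactivation,
                                    train_subcortex_ff)
from shallowbrain.task import (BrightnessPair, CueType, TrialSpec, add_noise,
                               make_test_set, render_cue, render_stimulus)


class TestReceptiveFields:
    def test_constant_blocks(self):
        r = readout_receptive_fields(render_stimulus(BrightnessPair(0.7, 0.3)))
        assert r.left_value == pytest.approx(0.7)
        assert r.right_value == pytest.approx(0.3)

    def test_blind_to_cues(self):
        for cue in CueType:
            r = readout_receptive_fields(render_cue(cue))
            assert r.left_value == 0.0 and r.right_value == 0.0

    def test_noise_averages_over_window(self):
        """The mean over 16 pixels has sd sigma/4."""
        rng = np.random.default_rng(0)
        vals = []
        frame = render_stimulus(BrightnessPair(0.5, 0.5))
        for _ in range(800):
            r = readout_receptive_fields(add_noise(frame, 0.1, rng))
            vals += [r.left_value, r.right_value]
        sd = np.std(np.array(vals) - 0.5)
        assert sd == pytest.approx(0.1 / 4, rel=0.15)


class TestPerceptron:
    def test_side_identification(self, ff_model):
        logits = ff_model.ff_subcortex.logits(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert logits[0].argmax() == 0  # S_L
        assert logits[1].argmax() == 1  # S_R

    def test_training_accuracy_and_determinism(self):
        a = train_subcortex_ff(seed=5)
        b = train_subcortex_ff(seed=5)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_mirror_symmetry_of_decisions(self, ff_model):
        test = make_test_set(100, seed=21)
        ro = np.array([[p.x_left, p.x_right] for p in test.pairs])
        direct = ff_model.ff_subcortex.logits(ro).argmax(axis=1)
        mirrored = ff_model.ff_subcortex.logits(ro[:, ::-1]).argmax(axis=1)
        assert np.all(direct != mirrored)


class TestRandomNetworkSampling:
    @pytest.mark.parametrize("seed", [0, 17])
    def test_densities_and_ranges(self, seed):
        rnn = sample_subcortex_rnn(seed)
        for name, (w, p) in rnn.projections().items():
            n = w.size
            density = (w != 0).mean()
            bound = 4 * np.sqrt(p * (1 - p) / n)
            assert abs(density - p) < bound, name
            assert w.min() >= 0.0 and w.max() <= 1.0, name

    def test_shapes(self):
        rnn = sample_subcortex_rnn(3)
        assert rnn.W_si_sl.shape == (N_INH, N_EXC)
        assert rnn.W_sl_si.shape == (N_EXC, N_INH)
        assert rnn.W_sl_sl.shape == (N_EXC, N_EXC)
        assert rnn.w_sl_x.shape == (N_EXC,)

    def test_reproducible(self):
        a, b = sample_subcortex_rnn(9), sample_subcortex_rnn(9)
        assert np.array_equal(a.W_sl_sl, b.W_sl_sl)

    def test_triplet_export(self):
        t = sample_subcortex_rnn(1).to_triplets()
        assert set(t.columns) == {"pre", "post", "weight", "projection_name"}
        assert (t.weight > 0).all()


class TestSuppression:
    def test_ff_inhibition_clamps_preactivation(self, ff_model):
        inhib = InhibitoryProjection(InhibitionMode.DIRECT_INHIBITION, gain=5.0)
        pre = subcortex_ff_preactivation(
            ff_model.ff_subcortex, np.array([[0.9, 0.1]]), np.array([1.0]),
            inhib, logit_gain=ff_model.gains.subcortical)
        assert np.allclose(pre, 0.0)

    def test_ff_wrong_mode_rejected(self, ff_model):
        with pytest.raises(ValueError):
            subcortex_ff_preactivation(
                ff_model.ff_subcortex, np.array([[0.5, 0.5]]), np.array([0.0]),
                InhibitoryProjection(InhibitionMode.VIA_INTERNEURONS, 5.0))

    @pytest.mark.parametrize("model_fixture", ["ff_model", "pc_model"])
    def test_anti_trials_never_cross_threshold(self, model_fixture, request):
        """Over 100 noiseless antisaccade trials the subcortical decision
        pair stays below the 0.55 threshold for the whole trial."""
        model = request.getfixturevalue(model_fixture)
        test = make_test_set(100, seed=31)
        trials = [TrialSpec.make(CueType.ANTI, p) for p in test.pairs]
        _, traces = run_trials(model, trials, 0.0,
                               rng=np.random.default_rng(0), record=True)
        assert traces["S"].max() < 0.55

    def test_pro_easy_trial_subcortex_beats_cortex(self, ff_model):
        trials = [TrialSpec.make(CueType.PRO, BrightnessPair(0.9, 0.1))]
        _, traces = run_trials(ff_model, trials, 0.0,
                               rng=np.random.default_rng(0), record=True)
        s_cross = np.argmax(traces["S"].max(axis=2)[:, 0] >= 0.55)
        c_cross = np.argmax(traces["C"].max(axis=2)[:, 0] >= 0.55)
        assert traces["S"].max() >= 0.55
        assert s_cross < c_cross

    def test_zero_readout_stays_at_symmetric_point(self, ff_model):
        inhib = InhibitoryProjection(InhibitionMode.DIRECT_INHIBITION, gain=5.0)
        pre = subcortex_ff_preactivation(
            ff_model.ff_subcortex, np.zeros((1, 2)), np.array([0.0]), inhib,
            logit_gain=ff_model.gains.subcortical)
        gap = abs(pre[0, 0] - pre[0, 1])
        # softmax of the residual gap stays below threshold
        assert 1.0 / (1.0 + np.exp(-gap)) < 0.55


class TestRandomNetworkDynamics:
    def test_step_advances_and_outputs_shape(self, pc_model):
        rnn = pc_model.rnn
        state = RNNState.zeros(4)
        inhib = InhibitoryProjection(InhibitionMode.VIA_INTERNEURONS, 5.0)
        readouts = np.tile([0.9, 0.1], (4, 1))
        rng = np.random.default_rng(0)
        for _ in range(30):
            state, out = step_subcortex_rnn(rnn, state, readouts, np.zeros(4),
                                            inhib, pc_model.gains.rnn, rng)
        assert out.shape == (4, 2)
        assert np.all(out[:, 0] > out[:, 1])  # left drive wins
        assert np.all(np.isfinite(state.r_sl))

    def test_interneuron_route_required(self, pc_model):
        with pytest.raises(ValueError):
            step_subcortex_rnn(pc_model.rnn, RNNState.zeros(1),
                               np.zeros((1, 2)), np.zeros(1),
                               InhibitoryProjection(InhibitionMode.DIRECT_INHIBITION, 5.0),
                               pc_model.gains.rnn, np.random.default_rng(0))

    def test_mirror_symmetry_statistical(self):
        """Mirroring the brightness pair flips which population responds
        more, for most random connectivity draws."""
        inhib = InhibitoryProjection(InhibitionMode.VIA_INTERNEURONS, 5.0)
        gains = RNNGains()
        wins = 0
        for seed in range(6):
            rnn = sample_subcortex_rnn(seed)
            flips = []
            for readout in ([0.9, 0.1], [0.1, 0.9]):
                state = RNNState.zeros(1)
                rng = np.random.default_rng(0)
                for _ in range(40):
                    state, out = step_subcortex_rnn(
                        rnn, state, np.array([readout]), np.zeros(1), inhib,
                        gains, rng)
                flips.append(out[0, 0] > out[0, 1])
            wins += flips == [True, False]
        assert wins >= 5

    def test_subcortical_rt_nonincreasing_with_brightness_gap(self, pc_model):
        """Larger brightness differences never slow the subcortical
        decision on average (prosaccade trials)."""
        from scipy.stats import spearmanr

        from shallowbrain.decision import difficulty_analysis

        test = make_test_set(400, seed=41)
        trials = [TrialSpec.make(CueType.PRO, p) for p in test.pairs]
        results, _ = run_trials(pc_model, trials, 0.0, rng=np.random.default_rng(2))
        table = difficulty_analysis(results)
        ok = table["subcortex_wins"] >= 5
        rts = table.loc[ok, "subcortex_rt_mean"].to_numpy()
        rho = spearmanr(np.arange(len(rts)), rts).statistic
        assert rho < 0
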