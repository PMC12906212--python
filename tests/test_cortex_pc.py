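"""Rao-Ballard hierarchy: inference, local learning, reconstruction,
latent readout, and the self-recurrent cue latch."""

import numpy as np
import pytest

from shallowbrain.cortex_pc import (IDX_A, IDX_L, IDX_P, IDX_R, CueNeurons,
                                    LatentClassifier, PCHyper, PCWeights,
                                    classify_latent, init_pc_weights, pc_infer,
                                    pc_learn, reconstruct_from_layer,
                                    sustain_cue, train_latent_classifier)
from shallowbrain.task import (BrightnessPair, CueType, Side, make_test_set,
                               render_cue, render_stimulus)


class TestInference:
    def test_zero_frame_stays_at_origin(self, pc_model):
        st = pc_infer(pc_model.pc_weights, np.zeros((1, 16, 32)))
        assert np.allclose(st.r1, 0.0)
        assert np.allclose(st.r2, 0.0)

    def test_energy_non_increasing_on_random_frames(self, pc_model, rng):
        frames = rng.random((100, 16, 32))
        st = pc_infer(pc_model.pc_weights, frames)
        assert np.all(np.diff(st.energy) <= 1e-9)
        assert st.energy[-1] < st.energy[0]

    def test_one_dimensional_analytic_fixed_point(self):
        """Scalar layers with U1=U2=1 and no decay: the energy
        (x-r1)^2 + (r1-r2)^2 is minimised by the normal-equations solution,
        which iterative inference must reach to 1e-6."""
        w = PCWeights(U1=np.array([[1.0]]), U2=np.array([[1.0]]))
        hyper = PCHyper(inference_rate=0.2, inference_iters=400, prior_decay=0.0)
        x = 0.73
        st = pc_infer(w, np.array([[x]]), hyper)
        # oracle: solve grad E = 0 -> [[2,-1],[-1,1]] r = [x, 0]
        A = np.array([[2.0, -1.0], [-1.0, 1.0]])
        r_star = np.linalg.solve(A, np.array([x, 0.0]))
        assert st.r1[0, 0] == pytest.approx(r_star[0], abs=1e-6)
        assert st.r2[0, 0] == pytest.approx(r_star[1], abs=1e-6)


class TestLearning:
    def test_reconstruction_error_drops_below_ten_percent(self, pc_model):
        h = pc_model.pc_weights.history
        assert h["recon_error_l1"].iloc[-1] < 0.1 * h["recon_error_l1"].iloc[0]

    def test_same_seed_reproduces_weights(self):
        hyper = PCHyper(epochs=5)
        a = pc_learn(hyper=hyper, seed=3)
        b = pc_learn(hyper=hyper, seed=3)
        assert np.array_equal(a.U1, b.U1)
        assert np.array_equal(a.U2, b.U2)

    def test_single_frame_capacity(self):
        """The local rule fitted to one repeated screen reconstructs it to
        visually-exact (per-pixel error < 0.05)."""
        x = render_stimulus(BrightnessPair(0.8, 0.3)).grid.reshape(1, -1)
        w = init_pc_weights(seed=0)
        hyper = PCHyper(inference_iters=60)
        for _ in range(300):
            st = pc_infer(w, x.reshape(1, 16, 32), hyper)
            e0 = x - st.r1 @ w.U1.T
            e1 = st.r1 - st.r2 @ w.U2.T
            w.U1 += hyper.learning_rate * e0.T @ st.r1
            w.U2 += hyper.learning_rate * e1.T @ st.r2
        st = pc_infer(w, x.reshape(1, 16, 32), hyper)
        recon = reconstruct_from_layer(w, st, 1)
        assert np.abs(recon.ravel() - x.ravel()).max() < 0.05


class TestReconstruction:
    def test_shapes_and_layer_validation(self, pc_model):
        st = pc_infer(pc_model.pc_weights, np.zeros((2, 16, 32)))
        for layer in (1, 2):
            assert reconstruct_from_layer(pc_model.pc_weights, st, layer).shape == (2, 16, 32)
        with pytest.raises(ValueError):
            reconstruct_from_layer(pc_model.pc_weights, st, 3)

    def test_cue_bar_recovered_from_layer1(self, pc_model):
        frame = render_cue(CueType.PRO)
        st = pc_infer(pc_model.pc_weights, frame.grid[None])
        recon = reconstruct_from_layer(pc_model.pc_weights, st, 1)[0]
        brightest = set(map(tuple, np.argwhere(
            recon >= np.sort(recon.ravel())[-2])))
        lit = set(map(tuple, np.argwhere(frame.grid > 0)))
        assert brightest == lit

    def test_trained_beats_untrained(self, pc_model):
        frames = np.stack([render_stimulus(p).grid
                           for p in make_test_set(10, seed=5).pairs])
        untrained = init_pc_weights(seed=99)
        for layer in (1, 2):
            errs = {}
            for name, w in (("trained", pc_model.pc_weights), ("untrained", untrained)):
                st = pc_infer(w, frames)
                recon = reconstruct_from_layer(w, st, layer)
                errs[name] = ((recon - frames) ** 2).sum()
            assert errs["trained"] < errs["untrained"]

    def test_reconstructions_correlate_with_input(self, pc_model):
        frames = np.stack([render_stimulus(p).grid
                           for p in make_test_set(20, seed=6).pairs])
        st = pc_infer(pc_model.pc_weights, frames)
        for layer in (1, 2):
            recon = reconstruct_from_layer(pc_model.pc_weights, st, layer)
            r = np.corrcoef(recon.ravel(), frames.ravel())[0, 1]
            assert r > 0.5


class TestLatentReadout:
    def test_cue_and_side_classes(self, pc_model):
        st = pc_infer(pc_model.pc_weights, render_cue(CueType.PRO).grid[None])
        assert classify_latent(pc_model.pc_classifier, st.r2)[0].argmax() == IDX_P
        st = pc_infer(pc_model.pc_weights,
                      render_stimulus(BrightnessPair(0.2, 0.9)).grid[None])
        assert classify_latent(pc_model.pc_classifier, st.r2)[0].argmax() == IDX_R

    def test_zero_latent_finite(self, pc_model):
        s = classify_latent(pc_model.pc_classifier, np.zeros(16))
        assert np.all(np.isfinite(s))

    def test_shape_mismatch(self, pc_model):
        with pytest.raises(ValueError):
            classify_latent(pc_model.pc_classifier, np.zeros(15))

    def test_side_accuracy_above_contract_under_noise(self, pc_model, rng):
        test = make_test_set(300, seed=13)
        grids = np.stack([render_stimulus(p).grid for p in test.pairs])
        truth = np.array([0 if p.brighter is Side.LEFT else 1 for p in test.pairs])
        st = pc_infer(pc_model.pc_weights, grids + rng.normal(0, 0.2, grids.shape))
        scores = classify_latent(pc_model.pc_classifier, st.r2)
        side = scores[:, [IDX_L, IDX_R]].argmax(axis=1)
        assert (side == truth).mean() > 0.75


class TestCueLatch:
    @staticmethod
    def _drive_then_release(w_self, drive_steps=20, release_steps=50):
        neurons = CueNeurons(w_self=w_self)
        for _ in range(drive_steps):
            sustain_cue(neurons, drive_p=1.0, drive_a=0.0)
        peak = neurons.p_rate
        for _ in range(release_steps):
            sustain_cue(neurons, drive_p=0.0, drive_a=0.0)
        return peak, neurons

    def test_sustains_after_drive_removed(self):
        peak, neurons = self._drive_then_release(w_self=1.5)
        assert neurons.p_rate >= 0.5 * peak
        assert neurons.a_rate < 0.05

    def test_never_driven_stays_silent(self):
        neurons = CueNeurons(w_self=1.5)
        for _ in range(100):
            sustain_cue(neurons, 0.0, 0.0)
        assert neurons.p_rate == 0.0 and neurons.a_rate == 0.0

    def test_subcritical_self_weight_decays(self):
        # effective decay constant is tau/(1 - w_self) = 0.5 s; allow 3 s
        peak, neurons = self._drive_then_release(w_self=0.8, release_steps=300)
        assert neurons.p_rate < 0.1 * peak

    def test_bifurcation_boundary_location(self):
        """The sustain/decay boundary sits at w_self = 1 for the
        saturating-rectified latch: scan across it."""
        sustained = []
        for w_self in (0.7, 0.9, 1.1, 1.3):
            peak, neurons = self._drive_then_release(w_self, release_steps=200)
            sustained.append(neurons.p_rate > 0.5 * peak)
        assert sustained == [False, False, True, True]
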