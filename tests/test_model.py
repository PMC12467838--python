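import numpy as np
import pytest

from emgfusion import model as M
from emgfusion import nn
from emgfusion.config import ModelConfig
from emgfusion.io_core import MovementLabel, Recording
from emgfusion.model import (CLASSES, ActuationCommand, ClassProbabilities,
                             CrossAttentionFusion, FRIM, FusionNet,
                             ImageBranch, MultiHeadAttention, SequenceBranch,
                             actuation_policy, frim_forward, train_on_samples)
from emgfusion.synth import generate_trial


def _np_layer_norm(v, eps=1e-5):
    return (v - v.mean(-1, keepdims=True)) / np.sqrt(v.var(-1, keepdims=True) + eps)


class TestFRIM:
    def test_matches_step_by_step_evaluation_on_2x2_case(self):
        """Hand-set weights: the module must equal an explicit Q/K/V ->
        scaled scores -> softmax -> context -> fusion+ReLU -> residual ->
        layer-norm evaluation."""
        rng = np.random.default_rng(0)
        frim = FRIM(2, 1, rng)
        wq = np.array([[0.5, -0.2], [0.1, 0.3]])
        wk = np.array([[0.2, 0.4], [-0.3, 0.1]])
        wv = np.array([[1.0, 0.0], [0.5, -0.5]])
        wf = np.array([[0.7, 0.2], [-0.1, 0.4]])
        bf = np.array([0.05, -0.1])
        frim.attn.w_q.weight.data = wq
        frim.attn.w_k.weight.data = wk
        frim.attn.w_v.weight.data = wv
        frim.fusion.weight.data = wf
        frim.fusion.bias.data = bf

        x = np.array([[0.3, -0.6], [1.2, 0.4]])
        q, k, v = x @ wq, x @ wk, x @ wv
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        context = a @ v
        fused = np.maximum(context @ wf + bf, 0.0)
        expected = _np_layer_norm(fused + x)

        out = frim_forward(x, frim)
        assert np.max(np.abs(out - expected)) < 1e-10
        assert np.allclose(frim.attn.last_weights.sum(-1), 1.0)

    def test_attention_rows_are_stochastic_everywhere(self):
        rng = np.random.default_rng(1)
        mha = MultiHeadAttention(8, 4, rng)
        mha(nn.Tensor(rng.normal(size=(3, 5, 8))))
        w = mha.last_weights
        assert w.shape == (3, 4, 5, 5)
        assert np.all(w >= 0)
        assert np.allclose(w.sum(-1), 1.0)

    def test_single_token_attends_only_to_itself(self):
        rng = np.random.default_rng(2)
        frim = FRIM(4, 2, rng)
        x = rng.normal(size=(1, 4))
        frim_forward(x, frim)
        assert np.allclose(frim.attn.last_weights, 1.0)

    def test_residual_path_survives_zeroed_values_and_fusion(self):
        rng = np.random.default_rng(3)
        frim = FRIM(4, 2, rng)
        frim.attn.w_v.weight.data[:] = 0.0
        frim.fusion.weight.data[:] = 0.0
        frim.fusion.bias.data[:] = 0.0
        x = rng.normal(size=(3, 4))
        assert np.allclose(frim_forward(x, frim), _np_layer_norm(x), atol=1e-12)

    def test_shape_preserved_and_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        frim = FRIM(4, 2, rng)
        assert frim_forward(rng.normal(size=(5, 4)), frim).shape == (5, 4)
        with pytest.raises(ValueError):
            frim_forward(rng.normal(size=(5, 3)), frim)


class TestCrossAttention:
    def test_output_length_is_d_model(self):
        rng = np.random.default_rng(5)
        cross = CrossAttentionFusion(8, 2, rng)
        out = cross(nn.Tensor(rng.normal(size=(3, 8))),
                    nn.Tensor(rng.normal(size=(3, 8))))
        assert out.data.shape == (3, 8)

    def test_identical_inputs_make_directions_agree(self):
        rng = np.random.default_rng(6)
        cross = CrossAttentionFusion(8, 2, rng)
        x = nn.Tensor(rng.normal(size=(2, 8)))
        fused = cross(x, x)
        one_dir = cross.frim(x.reshape(2, 1, 8), x.reshape(2, 1, 8))
        assert np.allclose(fused.data, one_dir.data.reshape(2, 8))

    def test_attention_normalised_in_both_directions(self):
        rng = np.random.default_rng(7)
        cross = CrossAttentionFusion(8, 2, rng)
        cross(nn.Tensor(rng.normal(size=(2, 8))),
              nn.Tensor(rng.normal(size=(2, 8))))
        assert np.allclose(cross.frim.attn.last_weights.sum(-1), 1.0)


class TestBranches:
    @staticmethod
    def _cfg():
        return ModelConfig.reduced(32)

    def test_image_branch_deterministic_and_sized(self):
        cfg = self._cfg()
        branch = ImageBranch(cfg, np.random.default_rng(8)).eval()
        x = nn.Tensor(np.random.default_rng(9).normal(size=(2, 6, 32, 32)))
        a, b = branch(x), branch(x)
        assert a.data.shape == (2, cfg.d_model)
        assert np.array_equal(a.data, b.data)

    def test_image_branch_zero_weights_give_zero_features(self):
        cfg = self._cfg()
        branch = ImageBranch(cfg, np.random.default_rng(10)).eval()
        for p in branch.parameters():
            p.data[:] = 0.0
        out = branch(nn.Tensor(np.ones((1, 6, 32, 32))))
        assert np.allclose(out.data, 0.0)

    def test_image_branch_rejects_wrong_shape(self):
        branch = ImageBranch(self._cfg(), np.random.default_rng(11))
        with pytest.raises(ValueError):
            branch(nn.Tensor(np.zeros((1, 6, 16, 16))))

    def test_sequence_branch_output_dim_independent_of_length(self):
        cfg = self._cfg()
        rng = np.random.default_rng(12)
        sb = SequenceBranch(5, cfg, rng)
        for T in (1, 4, 9):
            out = sb(nn.Tensor(rng.normal(size=(2, T, 5))))
            assert out.data.shape == (2, cfg.d_model)

    def test_sequence_branch_single_step_matches_lstm_oracle(self):
        """One window through a 2-unit LSTM equals the closed-form single
        recurrence step (i,f,g,o gates from packed weights) + projection."""
        cfg = ModelConfig.reduced(32)
        cfg.lstm_hidden = 2
        cfg.d_model = 4
        cfg.n_heads = 1
        rng = np.random.default_rng(13)
        sb = SequenceBranch(3, cfg, rng)
        x = np.random.default_rng(14).normal(size=3)

        def sigmoid(v):
            return 1.0 / (1.0 + np.exp(-v))

        gates = x @ sb.lstm.wx.data + sb.lstm.b.data
        i, f, g, o = np.split(gates, 4)
        c = sigmoid(i) * np.tanh(g)
        h = sigmoid(o) * np.tanh(c)
        expected = h @ sb.proj.weight.data + sb.proj.bias.data

        out = sb(nn.Tensor(x[None, None, :]))
        assert np.max(np.abs(out.data[0] - expected)) < 1e-12


@pytest.fixture(scope="module")
def trained_tiny(tiny_samples, _session_quick_cfg):
    tr, _ = tiny_samples
    return train_on_samples(tr, _session_quick_cfg, "full")


class TestTraining:
    def test_single_class_training_set_rejected(self, tiny_samples, quick_cfg):
        tr, _ = tiny_samples
        only_fsb = [s for s in tr if s.label == 0]
        with pytest.raises(ValueError):
            train_on_samples(only_fsb, quick_cfg)

    def test_same_seed_reproduces_training_exactly(self, tiny_samples, quick_cfg):
        tr, te = tiny_samples
        quick_cfg.train.max_epochs = 3
        a = train_on_samples(tr, quick_cfg, "full")
        b = train_on_samples(tr, quick_cfg, "full")
        assert abs(a.history.train_loss.iloc[-1]
                   - b.history.train_loss.iloc[-1]) < 1e-6
        assert np.array_equal(a.predict_samples(te), b.predict_samples(te))

    def test_overfits_its_own_training_set(self, trained_tiny, tiny_samples):
        tr, _ = tiny_samples
        res = M.evaluate_on_samples(trained_tiny, tr)
        assert res["accuracy"] >= 0.98

    def test_loss_decreases_over_first_epochs_on_separable_data(self):
        """60 well-separated synthetic trials at reduced width: the epoch
        training loss must fall monotonically over the first 5 epochs."""
        from emgfusion.benchmark import benchmark_config
        from emgfusion.synth import generate_dataset

        cfg = benchmark_config(2)
        cfg.simulate.fs = 500.0
        cfg.train.max_epochs = 5
        tr_recs, _ = generate_dataset(12, fs=500.0, seed=2)
        tr = M.prepare_samples(tr_recs, cfg)
        model = train_on_samples(tr, cfg, "full")
        losses = model.history.train_loss.to_numpy()
        assert np.all(np.diff(losses) < 0)


class TestPredict:
    def test_probabilities_form_a_distribution(self, trained_tiny, tiny_samples):
        _, te = tiny_samples
        probs = trained_tiny.predict_samples(te)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_full_pipeline_on_recording(self, trained_tiny):
        rec = generate_trial(MovementLabel.BLS, fs=500.0, seed=555)
        p = trained_tiny.predict(rec)
        assert p.active is True
        assert p.predicted in CLASSES
        assert p.probs.sum() == pytest.approx(1.0)

    def test_no_activity_yields_inactive_result_not_exception(self, trained_tiny):
        quiet = Recording(
            np.random.default_rng(0).normal(scale=1.0, size=(6, 3000)),
            fs=500.0)
        p = trained_tiny.predict(quiet)
        assert p.active is False
        assert p.predicted is None
        assert p.probs.sum() == pytest.approx(1.0)

    def test_save_load_round_trip_preserves_predictions(
            self, trained_tiny, tiny_samples, tmp_path):
        _, te = tiny_samples
        trained_tiny.save(tmp_path / "ckpt")
        loaded = M.TrainedModel.load(tmp_path / "ckpt")
        assert np.array_equal(loaded.predict_samples(te),
                              trained_tiny.predict_samples(te))


class TestActuationPolicy:
    @staticmethod
    def _probs(p_left=0.0, p_right=0.0):
        probs = np.zeros(5)
        probs[CLASSES.index(MovementLabel.LT)] = p_left
        probs[CLASSES.index(MovementLabel.RT)] = p_right
        rest = 1.0 - probs.sum()
        probs[0] = rest
        return ClassProbabilities(probs=probs, predicted=None)

    def test_left_intention_contracts_left_pam(self):
        cmd = actuation_policy(self._probs(p_left=0.9))
        assert cmd == ActuationCommand(left_pam="contract_70", right_pam="none")

    def test_right_intention_dilates_right_pam(self):
        cmd = actuation_policy(self._probs(p_right=0.9))
        assert cmd == ActuationCommand(left_pam="none", right_pam="dilate_30")

    def test_below_threshold_issues_no_command(self):
        cmd = actuation_policy(self._probs(p_left=0.5, p_right=0.5))
        assert cmd == ActuationCommand("none", "none")

    def test_inactive_probabilities_issue_no_command(self):
        p = ClassProbabilities(probs=np.full(5, 0.2), predicted=None,
                               active=False)
        assert actuation_policy(p) == ActuationCommand("none", "none")
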