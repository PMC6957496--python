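"""Classifier construction, training contracts, transfer and ensembling."""

import copy

import numpy as np
import pytest

import equibeat as eb
from equibeat import network as nw
from tests.conftest import tiny_toy_data

TINY_TC = nw.TrainConfig(learning_rate=1e-3, epochs=3, batch_size=8, seed=3)


class TestConstruction:
    def test_published_equine_architecture_builds(self):
        model = nw.build_network(nw.table_eecg_config(), seed=0)
        Xm = np.zeros((2, 2, 500))
        Xt = np.zeros((2, 2000))
        probs = model.predict_proba(Xm, Xt)
        assert probs.shape == (2, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_published_human_architecture_builds(self):
        model = nw.build_network(nw.table_mitbih_config(), seed=0)
        assert model.predict_proba(np.zeros((1, 2, 500)),
                                   np.zeros((1, 2000))).shape == (1, 4)

    def test_softmax_normalization_on_random_inputs(self, tiny_net_config):
        model = nw.build_network(tiny_net_config, seed=1)
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.normal(size=(7, 2, 40)),
                                    rng.normal(size=(7, 80)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_ablation_variant_has_fewer_parameters(self):
        full = nw.build_network(nw.table_eecg_config(), seed=0)
        ablated = nw.build_network(
            nw.table_eecg_config(use_timing_path=False), seed=0)
        assert ablated.num_params < full.num_params

    def test_parameter_count_deterministic(self, tiny_net_config):
        a = nw.build_network(tiny_net_config, seed=0).num_params
        b = nw.build_network(tiny_net_config, seed=99).num_params
        assert a == b

    def test_input_shape_mismatch_raises(self, tiny_net_config):
        model = nw.build_network(tiny_net_config, seed=0)
        with pytest.raises(ValueError, match="morphology"):
            model.predict_proba(np.zeros((1, 2, 99)), np.zeros((1, 80)))
        with pytest.raises(ValueError, match="timing"):
            model.predict_proba(np.zeros((1, 2, 40)), np.zeros((1, 99)))


class TestTraining:
    def test_zero_learning_rate_leaves_weights(self, tiny_net_config):
        Xm, Xt, y = tiny_toy_data(32, seed=0)
        model = nw.build_network(tiny_net_config, seed=1)
        before = [p.value.copy() for _, p in model.parameters()]
        nw.train(model, (Xm, Xt, y), None,
                 nw.TrainConfig(learning_rate=0.0, epochs=1, batch_size=8, seed=0))
        assert all(np.array_equal(b, p.value)
                   for b, (_, p) in zip(before, model.parameters()))

    def test_loss_decreases_on_toy_set(self, tiny_net_config):
        Xm, Xt, y = tiny_toy_data(32, seed=0)
        model = nw.build_network(tiny_net_config, seed=0)
        nw.train(model, (Xm, Xt, y), None,
                 nw.TrainConfig(learning_rate=1e-3, epochs=10, batch_size=8, seed=0))
        hist = model.training_history
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_seeded_training_reproducible(self, tiny_net_config):
        Xm, Xt, y = tiny_toy_data(32, seed=0)
        runs = []
        for _ in range(2):
            model = nw.build_network(tiny_net_config, seed=2)
            nw.train(model, (Xm, Xt, y), (Xm, Xt, y), TINY_TC)
            runs.append(model.training_history)
        assert runs[0] == runs[1]

    def test_smoke_training_reaches_95_percent(self, trained_separable):
        """The parallel network separates the 4 template classes in 20 epochs."""
        model, _ = trained_separable
        assert model.training_history[-1]["train_accuracy"] >= 95.0
        assert model.training_history[-1]["loss"] < model.training_history[0]["loss"]

    def test_predictions_on_separable_set(self, trained_separable):
        model, (Xm, Xt, y) = trained_separable
        probs, pred = nw.predict(model, (Xm, Xt, y))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.mean(pred == y) >= 0.95
        probs2, _ = nw.predict(model, (Xm, Xt, y))
        assert np.array_equal(probs, probs2)


class TestTransfer:
    def _pretrained(self, cfg):
        Xm, Xt, y = tiny_toy_data(32, seed=0)
        model = nw.build_network(cfg, seed=0)
        nw.train(model, (Xm, Xt, y), None,
                 nw.TrainConfig(learning_rate=1e-3, epochs=15, batch_size=8, seed=0))
        return model

    def test_freeze_mode_conv_bytes_identical(self, tiny_net_config):
        model = self._pretrained(tiny_net_config)
        frozen_bytes = model.conv_param_bytes()
        Xm, Xt, y = tiny_toy_data(32, seed=5)
        nw.transfer(model, (Xm, Xt, y), None, "freeze_features", TINY_TC)
        assert model.conv_param_bytes() == frozen_bytes

    def test_freeze_mode_updates_dense_layers(self, tiny_net_config):
        model = self._pretrained(tiny_net_config)
        dense_before = [p.value.copy() for ly in model._dense_layers()
                        for p in ly.params()]
        Xm, Xt, y = tiny_toy_data(32, seed=5)
        nw.transfer(model, (Xm, Xt, y), None, "freeze_features", TINY_TC)
        dense_after = [p.value for ly in model._dense_layers() for p in ly.params()]
        assert any(not np.array_equal(a, b)
                   for a, b in zip(dense_before, dense_after))

    def test_zero_epoch_finetune_is_identity(self, tiny_net_config):
        model = self._pretrained(tiny_net_config)
        clone = copy.deepcopy(model)
        Xm, Xt, y = tiny_toy_data(32, seed=5)
        nw.transfer(clone, (Xm, Xt, y), None, "full_finetune",
                    nw.TrainConfig(epochs=0, seed=0))
        assert all(np.array_equal(a.value, b.value)
                   for (_, a), (_, b) in zip(model.parameters(), clone.parameters()))

    def test_pretraining_beats_random_initialization(self, tiny_net_config):
        """Fine-tuning from a related task >= training from scratch."""
        source = self._pretrained(tiny_net_config)
        Xm, Xt, y = tiny_toy_data(32, seed=5)
        Xmv, Xtv, yv = tiny_toy_data(40, seed=9)
        warm = copy.deepcopy(source)
        tc = nw.TrainConfig(learning_rate=1e-3, epochs=3, batch_size=8, seed=7)
        nw.transfer(warm, (Xm, Xt, y), None, "full_finetune", tc)
        cold = nw.build_network(tiny_net_config, seed=11)
        nw.train(cold, (Xm, Xt, y), None, tc)
        assert nw._accuracy(warm, Xmv, Xtv, yv) >= nw._accuracy(cold, Xmv, Xtv, yv)

    def test_unknown_mode_rejected(self, tiny_net_config):
        model = nw.build_network(tiny_net_config, seed=0)
        with pytest.raises(ValueError):
            nw.transfer(model, tiny_toy_data(8), None, "partial")


class TestEnsemble:
    class _Stub:
        def __init__(self, probs):
            self._p = np.asarray(probs, dtype=float)

        def predict_proba(self, morph, timing):
            return self._p

    def test_identical_models_match_single(self, tiny_net_config):
        Xm, Xt, y = tiny_toy_data(16, seed=0)
        model = nw.build_network(tiny_net_config, seed=4)
        single = nw.predict(model, (Xm, Xt, y))[1]
        ensemble = nw.ensemble_predict([model] * 5, (Xm, Xt, y))
        assert np.array_equal(single, ensemble)

    def test_strict_majority(self):
        n_label, vpc_label = 0, 2
        votes_n = self._Stub([[0.9, 0.0, 0.1, 0.0]])
        votes_v = self._Stub([[0.1, 0.0, 0.9, 0.0]])
        out = nw.ensemble_predict([votes_n, votes_n, votes_v],
                                  (np.zeros((1, 2, 4)), None, None))
        assert out[0] == n_label
        assert nw.ensemble_predict([votes_v, votes_v, votes_n],
                                   (np.zeros((1, 2, 4)), None, None))[0] == vpc_label

    def test_tie_broken_by_mean_probability(self):
        a = self._Stub([[0.8, 0.0, 0.2, 0.0]])  # votes N with confidence .8
        b = self._Stub([[0.4, 0.0, 0.6, 0.0]])  # votes VPC with confidence .6
        out = nw.ensemble_predict([a, b], (np.zeros((1, 2, 4)), None, None))
        assert out[0] == 0  # mean prob N = .6 > mean prob VPC = .4

    def test_empty_model_list_raises(self):
        with pytest.raises(ValueError):
            nw.ensemble_predict([], (np.zeros((1, 2, 4)), None, None))


def test_checkpoint_round_trip(tmp_path, tiny_net_config):
    Xm, Xt, y = tiny_toy_data(16, seed=0)
    model = nw.build_network(tiny_net_config, seed=5)
    nw.train(model, (Xm, Xt, y), None, TINY_TC)
    nw.save_model(model, tmp_path / "ckpt.npz")
    back = nw.load_model(tmp_path / "ckpt.npz")
    p1, _ = nw.predict(model, (Xm, Xt, y))
    p2, _ = nw.predict(back, (Xm, Xt, y))
    assert np.array_equal(p1, p2)
    assert back.config == model.config
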