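import numpy as np
import pytest

from fedtab import (
    NetworkSpec,
    TrainConfig,
    build_model,
    generate_toy,
    load_model,
    predict_proba,
    save_model,
    train_local,
)
from fedtab.data_model import ConfigError, FedtabError
from fedtab.local_model import LocalModel

from conftest import make_table


class TestBuildModel:
    def test_same_seed_identical_weights(self):
        spec = NetworkSpec(input_dim=5)
        a = build_model(spec, seed=3)
        b = build_model(spec, seed=3)
        for (Wa, ba), (Wb, bb) in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)
            np.testing.assert_array_equal(ba, bb)
        assert not a.trained

    def test_layer_shape_bookkeeping(self):
        spec = NetworkSpec(input_dim=25, hidden_sizes=(64, 32, 16), fc_size=8)
        model = build_model(spec, seed=0)
        shapes = [W.shape for W, _ in model.weights]
        assert shapes == [(25, 64), (64, 32), (32, 16), (16, 8), (8, 2)]

    def test_non_binary_head_rejected(self):
        with pytest.raises(ConfigError):
            NetworkSpec(input_dim=5, output_units=3)


class TestPredictProba:
    def test_rows_are_probability_vectors(self):
        model = build_model(NetworkSpec(input_dim=4), seed=1)
        X = np.random.default_rng(0).normal(size=(30, 4))
        p = predict_proba(model, X)
        assert p.shape == (30, 2)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_half_half(self):
        model = build_model(NetworkSpec(input_dim=3), seed=0)
        model.weights = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
        p = predict_proba(model, np.random.default_rng(1).normal(size=(7, 3)))
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_manual_forward_pass_oracle(self):
        # 2 features -> 1 relu unit -> 1 relu unit -> 2 softmax logits
        spec = NetworkSpec(input_dim=2, hidden_sizes=(1,), fc_size=1)
        model = build_model(spec, seed=0)
        model.weights = [
            (np.array([[1.0], [-2.0]]), np.array([0.5])),
            (np.array([[2.0]]), np.array([-0.25])),
            (np.array([[1.0, -1.0]]), np.array([0.1, 0.2])),
        ]
        x = np.array([[0.3, -0.4]])
        h1 = max(0.3 * 1.0 + (-0.4) * (-2.0) + 0.5, 0.0)  # 1.6
        h2 = max(2.0 * h1 - 0.25, 0.0)  # 2.95
        logits = np.array([h2 * 1.0 + 0.1, h2 * (-1.0) + 0.2])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(predict_proba(model, x)[0], expected, atol=1e-12)

    def test_arity_mismatch_errors(self):
        model = build_model(NetworkSpec(input_dim=4), seed=0)
        with pytest.raises(FedtabError):
            predict_proba(model, np.zeros((3, 5)))

    def test_sigmoid_head_rows_still_normalised(self):
        spec = NetworkSpec(input_dim=3, output_activation="sigmoid")
        model = build_model(spec, seed=2)
        p = predict_proba(model, np.random.default_rng(2).normal(size=(11, 3)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def _split_toy(n=500, d=5, separation=6.0, seed=0):
    table = generate_toy(n, d, separation, seed=seed)
    n_tr = int(0.8 * n)
    return table.take(range(n_tr)), table.take(range(n_tr, n))


class TestTrainLocal:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_blobs_high_train_accuracy(self, seed):
        tr, va = _split_toy(seed=seed)
        model = build_model(NetworkSpec(input_dim=5), seed=seed)
        model, hist = train_local(
            model, tr, va, TrainConfig(epochs=30, patience=None, seed=seed)
        )
        assert hist.train_acc[-1] >= 0.99
        assert model.trained

    def test_early_stopping_restores_best_and_stops_on_patience(self):
        # tiny adversarial validation set: after the model fits the blobs the
        # val loss on mislabelled points only worsens, forcing an early stop
        tr, _ = _split_toy(n=300, separation=6.0)
        va = _split_toy(n=40, separation=6.0, seed=9)[1]
        va = make_table(va.features, 1 - va.labels, names=va.feature_names)
        cfg = TrainConfig(epochs=60, patience=5, seed=0)
        model = build_model(NetworkSpec(input_dim=5), seed=0)
        model, hist = train_local(model, tr, va, cfg)
        assert hist.stopped_epoch < cfg.epochs
        assert hist.stopped_epoch == hist.best_epoch + cfg.patience
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)

    def test_history_lengths_consistent(self):
        tr, va = _split_toy(n=200)
        model = build_model(NetworkSpec(input_dim=5), seed=1)
        _, hist = train_local(model, tr, va, TrainConfig(epochs=8, patience=None))
        assert (
            len(hist.train_loss)
            == len(hist.train_acc)
            == len(hist.val_loss)
            == len(hist.val_acc)
            == hist.stopped_epoch
            == 8
        )

    def test_fixed_seed_bit_identical_history(self):
        tr, va = _split_toy(n=200)
        cfg = TrainConfig(epochs=5, patience=None, seed=42)
        m1, h1 = train_local(build_model(NetworkSpec(input_dim=5), 7), tr, va, cfg)
        m2, h2 = train_local(build_model(NetworkSpec(input_dim=5), 7), tr, va, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        for (W1, b1), (W2, b2) in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(W1, W2)

    def test_smoothed_train_loss_trend_nonincreasing(self):
        tr, va = _split_toy(n=400)
        model = build_model(NetworkSpec(input_dim=5), seed=3)
        _, hist = train_local(model, tr, va, TrainConfig(epochs=25, patience=None))
        smooth = np.convolve(hist.train_loss, np.ones(5) / 5, mode="valid")
        assert smooth[-1] <= smooth[0]

    def test_empty_train_errors(self):
        tr, va = _split_toy(n=100)
        empty = tr.take([])
        model = build_model(NetworkSpec(input_dim=5), seed=0)
        with pytest.raises(FedtabError):
            train_local(model, empty, va, TrainConfig(epochs=1))


class TestPersistence:
    def test_round_trip_identity_on_probe(self, tmp_path):
        tr, va = _split_toy(n=150)
        model = build_model(NetworkSpec(input_dim=5), seed=0)
        model, _ = train_local(model, tr, va, TrainConfig(epochs=3, patience=None))
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        probe = va.features
        np.testing.assert_allclose(
            predict_proba(model, probe), predict_proba(back, probe), atol=1e-12
        )
        assert back.spec == model.spec

    def test_mismatched_spec_errors(self, tmp_path):
        model = build_model(NetworkSpec(input_dim=4), seed=0)
        path = tmp_path / "m.json"
        save_model(model, path)
        with pytest.raises(FedtabError):
            load_model(path, expected_spec=NetworkSpec(input_dim=9))

    def test_corrupt_file_errors(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(FedtabError):
            load_model(path)

    def test_two_clients_independent_files(self, tmp_path):
        tr, va = _split_toy(n=150)
        probes = va.features
        models = []
        for ci in range(2):
            m = build_model(NetworkSpec(input_dim=5), seed=ci)
            m, _ = train_local(m, tr, va, TrainConfig(epochs=2, patience=None, seed=ci))
            save_model(m, tmp_path / f"client_{ci}.json")
            models.append(m)
        for ci in range(2):
            assert (tmp_path / f"client_{ci}.json").exists()
            back = load_model(tmp_path / f"client_{ci}.json")
            np.testing.assert_allclose(
                predict_proba(back, probes), predict_proba(models[ci], probes)
            )
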