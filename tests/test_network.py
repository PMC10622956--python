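"""Architecture table, parameter counts, training behaviour."""

import math

import numpy as np
import pytest

from ecaselect import _nn
from ecaselect.network import (
    ConfigurationError,
    Hyperparameters,
    TrainedModel,
    _Runtime,
    build_eca_deepnet,
    count_parameters,
    elu,
    train_model,
)
from ecaselect.preprocess import SampleSet

from conftest import SMALL_FILTERS, SMALL_KERNEL, SMALL_POOL, fast_hp, small_spec

# The canonical architecture table for a 22 x 1,000 four-class input:
# layer -> (output shape, trainable parameters).
CANONICAL_TABLE = {
    "CA-Layer": ((22, 1000, 1), 506),
    "Conv-Time": ((32, 991, 22), 320),
    "Conv-Spat": ((32, 991, 1), 22528),
    "BatchNorm-1": ((32, 991, 1), 64),
    "Pool-1": ((32, 330, 1), 0),
    "ECA-1": ((32, 330, 1), 4),
    "Conv-2": ((64, 321, 1), 20480),
    "BatchNorm-2": ((64, 321, 1), 128),
    "Pool-2": ((64, 107, 1), 0),
    "ECA-2": ((64, 107, 1), 4),
    "Conv-3": ((128, 98, 1), 81920),
    "BatchNorm-3": ((128, 98, 1), 256),
    "Pool-3": ((128, 32, 1), 0),
    "ECA-3": ((128, 32, 1), 6),
    "Conv-4": ((256, 23, 1), 327680),
    "BatchNorm-4": ((256, 23, 1), 512),
    "Pool-4": ((256, 7, 1), 0),
    "ECA-4": ((256, 7, 1), 6),
    "Conv-Classifier": ((4, 1, 1), 7172),
}


@pytest.fixture(scope="module")
def canonical_spec():
    return build_eca_deepnet(22, 1000, 4)


class TestEluFunction:
    @pytest.mark.parametrize(
        "x, expected", [(0.0, 0.0), (2.0, 2.0), (-1.0, math.exp(-1) - 1.0)]
    )
    def test_values(self, x, expected):
        assert elu(x) == pytest.approx(expected)


class TestArchitectureTable:
    def test_shape_trace(self, canonical_spec):
        for name, (shape, _) in CANONICAL_TABLE.items():
            assert canonical_spec.layer(name).output_shape == shape, name

    def test_parameter_counts(self, canonical_spec):
        for name, (_, params) in CANONICAL_TABLE.items():
            assert count_parameters(canonical_spec, name) == params, name

    def test_total_equals_sum_and_runtime_enumeration(self, canonical_spec):
        expected = sum(p for _, p in CANONICAL_TABLE.values())
        assert canonical_spec.total_parameters == expected
        rt = _Runtime(canonical_spec, np.random.default_rng(0), 0.5)
        assert rt.n_parameters() == expected

    def test_classifier_output_is_class_vector(self, canonical_spec):
        assert canonical_spec.layer("LogSoftmax").output_shape == (4,)

    def test_temporal_length_chain(self):
        # conv: L - 10 + 1, pool: floor(L / 3), applied through four blocks
        lengths = [1000]
        l = 1000
        for _ in range(4):
            l = l - 10 + 1
            lengths.append(l)
            l = l // 3
            lengths.append(l)
        assert lengths[1:] == [991, 330, 321, 107, 98, 32, 23, 7]

    def test_removing_ca_layer_changes_count_by_c2_plus_c(self):
        for c in (8, 22):
            with_ca = build_eca_deepnet(c, 1000, 4)
            without = build_eca_deepnet(c, 1000, 4, include_ca_layer=False)
            assert with_ca.total_parameters - without.total_parameters == c * c + c

    def test_unknown_layer_lookup(self, canonical_spec):
        with pytest.raises(KeyError):
            count_parameters(canonical_spec, "Conv-5")

    def test_too_short_input_names_offending_layer(self):
        with pytest.raises(ConfigurationError, match="Conv-4|Pool"):
            build_eca_deepnet(22, 380, 4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            build_eca_deepnet(1, 1000, 4)
        with pytest.raises(ConfigurationError):
            build_eca_deepnet(22, 50, 4)

    def test_spec_json_round_trip(self, canonical_spec):
        again = type(canonical_spec).from_json(canonical_spec.to_json())
        assert again == canonical_spec


class TestForwardPass:
    def test_zero_input_finite_and_normalized(self):
        spec = small_spec()
        rt = _Runtime(spec, np.random.default_rng(0), 0.5)
        logits = rt.forward(np.zeros((3, 8, 250)), training=False)
        assert np.all(np.isfinite(logits))
        probs = np.exp(_nn.log_softmax(logits))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_gradients_match_finite_differences(self):
        spec = build_eca_deepnet(
            5, 150, 3, filters=SMALL_FILTERS, temporal_kernel=SMALL_KERNEL, pool_size=SMALL_POOL
        )
        rt = _Runtime(spec, np.random.default_rng(1), 0.0)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 5, 150))
        y = np.array([0, 1, 2])

        def loss():
            return _nn.nll_loss_and_grad(rt.forward(x, True), y)[0]

        _, dlogits = _nn.nll_loss_and_grad(rt.forward(x, True), y)
        for p in rt.params():
            p.grad[...] = 0.0
        rt.backward(dlogits)
        for p in rt.params():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - grad[i]) <= 1e-5 * max(1.0, abs(num)), p.name


class TestHyperparameters:
    def test_defaults_valid(self):
        hp = Hyperparameters()
        assert hp.optimizer == "AdamW" and hp.seed == 20200220

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dropout_rate=0.95),
            dict(optimizer="SGD"),
            dict(learning_rate=1.0),
            dict(batch_size=10),
            dict(weight_decay=0.5),
            dict(epochs=0),
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparameters(**kwargs)


def _toy_two_class(n_per_class=20, channels=5, t=150, seed=0):
    """Linearly separable toy problem: class 1 has a large DC offset on one
    channel, class 0 does not."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2 * n_per_class, channels, t))
    y = np.repeat([0, 1], n_per_class)
    x[y == 1, 2, :] += 3.0
    order = rng.permutation(2 * n_per_class)
    return SampleSet(x[order], y[order], np.arange(2 * n_per_class)[order], [f"ch{i}" for i in range(channels)])


class TestTraining:
    def test_deterministic_given_seed(self, small_split):
        train_ss, _ = small_split
        spec = small_spec(train_ss.n_channels, train_ss.n_times, 4)
        hp = fast_hp(epochs=2)
        m1 = train_model(train_ss, hp, spec=spec)
        m2 = train_model(train_ss, hp, spec=spec)
        assert m1.history[-1]["train_loss"] == m2.history[-1]["train_loss"]
        assert len(m1.history) == 2

    def test_separable_toy_reaches_high_accuracy(self):
        ss = _toy_two_class()
        spec = build_eca_deepnet(
            5, 150, 2, filters=SMALL_FILTERS, temporal_kernel=SMALL_KERNEL, pool_size=SMALL_POOL
        )
        hp = fast_hp(epochs=30, batch_size=8)
        model = train_model(ss, hp, spec=spec)
        assert model.history[-1]["train_acc"] > 0.9

    def test_learnable_four_class_beats_chance(self, small_trained, small_split):
        _, eval_ss = small_split
        from ecaselect.selection import evaluate

        assert evaluate(small_trained, eval_ss) > 0.25

    def test_losses_finite_and_history_complete(self, small_trained):
        assert len(small_trained.history) == small_trained.hyperparameters.epochs
        assert all(np.isfinite(h["train_loss"]) for h in small_trained.history)

    def test_single_class_rejected(self):
        ss = _toy_two_class(n_per_class=4)
        ss = SampleSet(ss.samples, np.zeros(len(ss), dtype=int), ss.trial_ids, ss.channel_names)
        with pytest.raises(ValueError):
            train_model(ss, fast_hp(epochs=1))

    def test_early_stopping_restores_best_state(self, small_split):
        train_ss, eval_ss = small_split
        spec = small_spec(train_ss.n_channels, train_ss.n_times, 4)
        hp = fast_hp(epochs=6, patience=2)
        model = train_model(train_ss, hp, spec=spec, val_samples=eval_ss)
        assert "val_loss" in model.history[0]
        assert len(model.history) <= 6

    def test_checkpoint_round_trip(self, small_trained, small_split, tmp_path):
        _, eval_ss = small_split
        path = tmp_path / "model.ckpt"
        small_trained.save(path)
        again = TrainedModel.load(path)
        x = eval_ss.samples[:5]
        assert np.allclose(again.predict_logits(x), small_trained.predict_logits(x))

    def test_history_csv(self, small_trained, tmp_path):
        path = tmp_path / "history.csv"
        small_trained.save_history_csv(path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("epoch,train_loss,train_acc")


@pytest.mark.parametrize("name", ["AdamW", "Adagrad", "Adadelta"])
def test_all_optimizers_reduce_toy_loss(name):
    ss = _toy_two_class(n_per_class=8)
    spec = build_eca_deepnet(
        5, 150, 2, filters=SMALL_FILTERS, temporal_kernel=SMALL_KERNEL, pool_size=SMALL_POOL
    )
    lr = {"AdamW": 1e-3, "Adagrad": 1e-2, "Adadelta": 1e-1}[name]
    hp = fast_hp(epochs=5, optimizer=name, learning_rate=lr, batch_size=8)
    model = train_model(ss, hp, spec=spec)
    assert model.history[-1]["train_loss"] < model.history[0]["train_loss"]
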