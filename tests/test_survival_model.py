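"""Architecture assembly, numpy backend correctness, training, and search."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from survimage import nn
from survimage.survival_model import (
    ALL_INPUTS,
    HYPERPARAMETER_SPACE,
    ModelConfig,
    MultimodalNet,
    TrainSettings,
    assemble_architecture,
    search_hyperparameters,
    train,
)


class TestModelConfig:
    def test_out_of_grid_value_rejected(self):
        with pytest.raises(ValueError, match="conv_brite_filters_1"):
            ModelConfig(conv_brite_filters_1=33)

    def test_no_inputs_rejected(self):
        with pytest.raises(ValueError, match="input"):
            ModelConfig(enabled_inputs=())


class TestAssembleArchitecture:
    def test_four_inputs_two_branches_two_scalars(self):
        d = assemble_architecture(ModelConfig(), 32)
        assert set(d.branches) == {"image_brite", "image_pathway"}
        assert d.scalar_inputs == ("age", "stage")

    def test_single_image_variant(self):
        d = assemble_architecture(
            ModelConfig(enabled_inputs=("image_brite",)), 32
        )
        assert set(d.branches) == {"image_brite"} and d.scalar_inputs == ()

    def test_deterministic_description(self):
        c = ModelConfig(dense_1_units=128)
        d1 = assemble_architecture(c, 16)
        d2 = assemble_architecture(c, 16)
        assert d1.branches == d2.branches and d1.n_params == d2.n_params

    def test_branch_symmetry_in_parameter_count(self):
        c1 = ModelConfig(
            conv_brite_filters_1=64, conv_brite_filters_2=96, dense_brite_units=256,
            conv_pathway_filters_1=40, conv_pathway_filters_2=112, dense_pathway_units=144,
        )
        c2 = ModelConfig(
            conv_brite_filters_1=40, conv_brite_filters_2=112, dense_brite_units=144,
            conv_pathway_filters_1=64, conv_pathway_filters_2=96, dense_pathway_units=256,
        )
        assert (
            assemble_architecture(c1, 16).n_params
            == assemble_architecture(c2, 16).n_params
        )

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="image_side"):
            assemble_architecture(ModelConfig(), 3)


class TestBackendGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences away from
        ReLU/pool kinks (median relative error ~1e-8)."""
        net = MultimodalNet(assemble_architecture(ModelConfig(), 8), seed=0)
        for seq in (*net.branches.values(), net.head):
            for layer in seq.layers:
                if isinstance(layer, nn.Dropout):
                    layer.rate = 0.0
        inputs = {
            "image_brite": rng.random((6, 8, 8)),
            "image_pathway": rng.random((6, 8, 8)),
            "age": rng.normal(size=6),
            "stage": rng.normal(size=6),
        }
        y = np.array([0, 1, 0, 1, 1, 0], dtype=float)

        def loss():
            return nn.bce_loss(net.forward(inputs, training=True), y)

        probs = net.forward(inputs, training=True)
        net.backward((probs - y) / len(y))
        analytic = {
            (id(l), n): l.grads[n].copy() for l, n in net.parameters()
        }
        errors = []
        for layer, name in net.parameters():
            flat = layer.params[name].ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                eps = 1e-6
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = analytic[(id(layer), name)].ravel()[idx]
                errors.append(abs(num - ana) / max(1e-6, abs(num) + abs(ana)))
        assert np.median(errors) < 1e-5


class TestTrain:
    def _separable_toy(self, rng, n=60, side=8):
        y = np.array([0, 1] * (n // 2), dtype=float)
        img = rng.random((n, side, side)) * 0.2
        img[y == 1, 2:4, 2:4] += 0.6  # 4 signal pixels
        img[y == 1, 5, 2:6] += 0.6  # 4 more
        return np.clip(img, 0, 1), y

    def test_separable_toy_reaches_training_auc_one(self, rng):
        img, y = self._separable_toy(rng)
        config = ModelConfig(enabled_inputs=("image_brite",))
        predictor = train(
            assemble_architecture(config, 8),
            {"image_brite": img, "labels": y},
            TrainSettings(epochs=100, seed=0),
        )
        scores = predictor.predict({"image_brite": img})
        assert roc_auc_score(y, scores) == 1.0
        assert np.all((scores > 0) & (scores < 1))

    def test_shape_mismatch_rejected_before_training(self, rng):
        img, y = self._separable_toy(rng)
        config = ModelConfig(enabled_inputs=("image_brite",))
        with pytest.raises(ValueError, match="expected shape"):
            train(
                assemble_architecture(config, 8),
                {"image_brite": img[:, :4, :4], "labels": y},
                TrainSettings(epochs=2, seed=0),
            )

    def test_reproducible_given_seed(self, rng):
        img, y = self._separable_toy(rng, n=40)
        config = ModelConfig(enabled_inputs=("image_brite",))
        scores = []
        for _ in range(2):
            p = train(
                assemble_architecture(config, 8),
                {"image_brite": img, "labels": y},
                TrainSettings(epochs=10, seed=3),
            )
            scores.append(p.predict({"image_brite": img}))
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_label_permutation_null_auc_near_half(self):
        """Mean test AUC over 10 seeds stays in 0.5 +- 0.15 when labels
        carry no signal."""
        rng = np.random.default_rng(99)
        n = 80
        img = rng.random((n, 6, 6))
        config = ModelConfig(enabled_inputs=("image_brite",))
        aucs = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            y = local.permutation(np.array([0, 1] * (n // 2), dtype=float))
            train_idx, test_idx = np.arange(0, 60), np.arange(60, 80)
            p = train(
                assemble_architecture(config, 6),
                {"image_brite": img[train_idx], "labels": y[train_idx]},
                TrainSettings(epochs=15, seed=seed),
            )
            scores = p.predict({"image_brite": img[test_idx]})
            if len(np.unique(y[test_idx])) == 2:
                aucs.append(roc_auc_score(y[test_idx], scores))
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestSearch:
    def test_constant_objective_returns_in_space_config(self):
        result = search_hyperparameters(lambda c: 0.5, n_trials=5, seed=0)
        for trial in result.trials:
            for name, options in HYPERPARAMETER_SPACE.items():
                assert getattr(trial.config, name) in options

    def test_recovers_best_option_on_small_axis(self):
        objective = lambda c: 1.0 if c.dense_2_units == 64 else 0.0
        result = search_hyperparameters(objective, n_trials=30, seed=1)
        assert result.best_config.dense_2_units == 64

    def test_deterministic_trial_sequence(self):
        def objective(c):
            return c.learning_rate * 100 + c.dropout_1

        r1 = search_hyperparameters(objective, n_trials=15, seed=7)
        r2 = search_hyperparameters(objective, n_trials=15, seed=7)
        assert [t.config for t in r1.trials] == [t.config for t in r2.trials]

    def test_best_so_far_monotone_and_failures_tolerated(self):
        calls = {"n": 0}

        def flaky(c):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise RuntimeError("diverged")
            return calls["n"] / 100.0

        result = search_hyperparameters(flaky, n_trials=12, seed=2)
        best = -np.inf
        for t in result.trials:
            if t.score is not None:
                best = max(best, t.score)
                assert result.best_score >= t.score
        assert any(t.error for t in result.trials)

    def test_all_trials_failing_raises(self):
        def broken(c):
            raise RuntimeError("no")

        with pytest.raises(RuntimeError, match="all .* trials failed"):
            search_hyperparameters(broken, n_trials=3, seed=0)

    def test_random_sampler_fallback(self):
        result = search_hyperparameters(
            lambda c: 0.1, n_trials=6, seed=0, sampler="random"
        )
        assert len(result.trials) == 6
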