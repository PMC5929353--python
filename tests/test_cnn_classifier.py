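import numpy as np
import pytest

import reference
from braggscreen import cnn_classifier as cnn
from braggscreen.io_formats import Label
from conftest import make_table


class TestShapeChain:
    def test_default_chain_matches_published_anchors(self):
        arch = cnn.CNNArchitecture()
        chain = cnn.shape_chain(arch)
        assert chain == [(4, 180), (8, 45), (16, 11), (32, 3)]
        assert arch.n_features == 288

    def test_small_input_collapses(self):
        with pytest.raises(ValueError, match="collapsed"):
            cnn.shape_chain(cnn.CNNArchitecture(input_size=4))

    def test_three_stage_variant(self):
        arch = cnn.CNNArchitecture(input_size=48, channels_per_stage=(4, 8, 16))
        assert cnn.shape_chain(arch) == [(4, 12), (8, 3), (16, 1)]
        assert arch.n_features == 16

    def test_arch_json_round_trip(self):
        arch = cnn.CNNArchitecture(input_size=48, channels_per_stage=(4, 8))
        assert cnn.CNNArchitecture.from_json(arch.to_json()) == arch


@pytest.fixture
def tiny():
    arch = cnn.CNNArchitecture(input_size=12, channels_per_stage=(4, 8))
    weights = cnn.init_weights(arch, np.random.default_rng(0))
    return arch, weights


class TestForward:
    def test_zero_weights_uniform_probs(self, tiny, rng):
        arch, weights = tiny
        for i in range(len(weights.conv)):
            weights.conv[i][:] = 0.0
        weights.fc_w[:] = 0.0
        x = rng.normal(size=(3, 12, 12))
        _, logits, probs = cnn.forward(weights, arch, x, mode="eval")
        np.testing.assert_allclose(logits, 0.0)
        np.testing.assert_allclose(probs, 1.0 / 3.0)

    def test_conv_matches_naive_oracle(self, rng):
        x = rng.normal(size=(1, 2, 6, 6))
        kernels = rng.normal(size=(3, 2, 3, 3))
        out, _ = cnn._conv_forward(x, kernels, stride=2)
        want = reference.conv2d_naive(x[0], kernels, stride=2)
        np.testing.assert_allclose(out[0], want, atol=1e-12)

    def test_pool_matches_naive_oracle(self, rng):
        x = rng.normal(size=(1, 2, 7, 7))
        out, _ = cnn._pool_forward(x, 2)
        want = reference.maxpool_naive(x[0], 2)
        np.testing.assert_allclose(out[0], want)

    def test_probs_sum_to_one(self, tiny, rng):
        arch, weights = tiny
        _, _, probs = cnn.forward(weights, arch, rng.normal(size=(4, 12, 12)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_size_rejected(self, tiny, rng):
        arch, weights = tiny
        with pytest.raises(ValueError, match="expected"):
            cnn.forward(weights, arch, rng.normal(size=(2, 10, 10)))

    def test_eval_deterministic(self, tiny, rng):
        arch, weights = tiny
        x = rng.normal(size=(2, 12, 12))
        a = cnn.forward(weights, arch, x, mode="eval")[2]
        b = cnn.forward(weights, arch, x, mode="eval")[2]
        np.testing.assert_array_equal(a, b)


class TestSoftmax:
    def test_paper_example_vector(self):
        logits = np.log(np.array([[0.6, 0.3, 0.1]]))
        np.testing.assert_allclose(cnn.softmax(logits), [[0.6, 0.3, 0.1]], atol=1e-12)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            cnn.softmax(logits), cnn.softmax(logits + 123.4), atol=1e-6
        )


class TestDecideLabel:
    def test_paper_example_is_hit(self):
        binary, three = cnn.decide_label([0.6, 0.3, 0.1])
        assert binary == Label.HIT and three == Label.HIT

    def test_certain_miss(self):
        binary, three = cnn.decide_label([0.0, 0.0, 1.0])
        assert binary == Label.MISS and three == Label.MISS

    def test_aggregate_below_miss(self):
        binary, three = cnn.decide_label([0.2, 0.25, 0.55])
        assert binary == Label.MISS and three == Label.MISS

    def test_tie_retains_frame(self):
        binary, _ = cnn.decide_label([0.25, 0.25, 0.5])
        assert binary == Label.HIT

    def test_three_class_tie_order(self):
        _, three = cnn.decide_label([0.4, 0.4, 0.2])
        assert three == Label.HIT

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            cnn.decide_label([0.5, 0.5])


class TestCrossEntropy:
    def test_perfect_prediction(self):
        probs = np.eye(3)
        assert cnn.cross_entropy_loss(probs, [0, 1, 2]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction(self):
        probs = np.full((4, 3), 1.0 / 3.0)
        assert cnn.cross_entropy_loss(probs, [0, 2, 1, 0]) == pytest.approx(np.log(3))

    def test_hand_arithmetic(self):
        probs = np.array([[0.5, 0.3, 0.2], [0.25, 0.5, 0.25]])
        want = (np.log(2) + np.log(4)) / 2
        assert cnn.cross_entropy_loss(probs, [0, 0]) == pytest.approx(want)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cnn.cross_entropy_loss(np.zeros((0, 3)), [])


class TestBalancedBatches:
    def test_batch_of_64_splits_21_21_22(self, three_class_table):
        rng = np.random.default_rng(0)
        batches = cnn.make_balanced_batches(three_class_table, 64, rng, n_batches=5)
        for batch in batches:
            counts = np.bincount(
                [int(three_class_table.label_of(fid)) for fid in batch], minlength=3
            )
            assert sorted(counts.tolist()) == [21, 21, 22]

    def test_batch_of_three_one_each(self, three_class_table):
        rng = np.random.default_rng(1)
        (batch,) = cnn.make_balanced_batches(three_class_table, 3, rng)
        labels = {int(three_class_table.label_of(fid)) for fid in batch}
        assert labels == {0, 1, 2}

    def test_small_class_resampled(self):
        table = make_table([0] * 5 + [1] * 40 + [2] * 40)
        rng = np.random.default_rng(2)
        batches = cnn.make_balanced_batches(table, 30, rng, n_batches=20)
        for batch in batches:
            counts = np.bincount(
                [int(table.label_of(fid)) for fid in batch], minlength=3
            )
            assert counts.max() - counts.min() <= 1

    def test_absent_class_rejected(self):
        table = make_table([0] * 10 + [2] * 10)
        with pytest.raises(ValueError, match="absent"):
            cnn.make_balanced_batches(table, 6, np.random.default_rng(0))

    def test_deterministic(self, three_class_table):
        a = cnn.make_balanced_batches(
            three_class_table, 12, np.random.default_rng(7), n_batches=3
        )
        b = cnn.make_balanced_batches(
            three_class_table, 12, np.random.default_rng(7), n_batches=3
        )
        assert a == b


class TestLrSchedule:
    def test_endpoints(self):
        config = cnn.TrainConfig()
        assert cnn.lr_schedule(config, 0) == pytest.approx(0.1)
        assert cnn.lr_schedule(config, 119) == pytest.approx(0.0001)

    def test_geometric_midpoint(self):
        config = cnn.TrainConfig()
        mid = np.sqrt(0.1 * 0.0001)
        assert cnn.lr_schedule(config, 60) < mid < cnn.lr_schedule(config, 59)

    def test_strictly_decreasing(self):
        config = cnn.TrainConfig(epochs=30)
        etas = [cnn.lr_schedule(config, e) for e in range(30)]
        assert all(a > b for a, b in zip(etas, etas[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            cnn.lr_schedule(cnn.TrainConfig(), 120)


class TestSgdStep:
    def test_zero_lr_no_change(self, tiny):
        arch, weights = tiny
        before = weights.fc_w.copy()
        cnn.sgd_step(weights, {"fc_w": np.ones_like(weights.fc_w)}, lr=0.0)
        np.testing.assert_array_equal(weights.fc_w, before)

    def test_scalar_update(self, tiny):
        arch, weights = tiny
        weights.fc_b[:] = 1.0
        cnn.sgd_step(weights, {"fc_b": np.full(3, 2.0)}, lr=0.1)
        np.testing.assert_allclose(weights.fc_b, 0.8)

    def test_quadratic_convergence(self, tiny):
        # minimize (w - 3)^2 via its gradient through the sgd_step machinery
        arch, weights = tiny
        weights.fc_b[:] = 1.0
        for _ in range(200):
            grad = 2.0 * (weights.fc_b - 3.0)
            cnn.sgd_step(weights, {"fc_b": grad}, lr=0.1)
        assert np.all(np.abs(weights.fc_b - 3.0) < 1e-6)

    def test_nonfinite_gradient_rejected(self, tiny):
        arch, weights = tiny
        bad = np.full_like(weights.fc_b, np.nan)
        with pytest.raises(FloatingPointError):
            cnn.sgd_step(weights, {"fc_b": bad}, lr=0.1)


class TestGradients:
    def test_fc_and_conv_match_finite_differences(self, tiny, rng):
        arch, weights = tiny
        x = rng.normal(size=(5, 12, 12))
        targets = [0, 1, 2, 0, 1]
        _, grads, _, _ = cnn.loss_and_grads(weights, arch, x, targets, mode="train")

        def loss_with(w):
            _, _, probs = cnn.forward(w, arch, x, mode="train")
            return cnn.cross_entropy_loss(probs, targets)

        eps = 1e-6
        checks = [("fc_w", (1, 3)), ("fc_b", (2,)), ("conv0", (0, 0, 1, 1)),
                  ("gamma1", (3,)), ("beta0", (2,))]
        for name, idx in checks:
            wp = weights.copy()
            wp.learnables()[name][idx] += eps
            wm = weights.copy()
            wm.learnables()[name][idx] -= eps
            numeric = (loss_with(wp) - loss_with(wm)) / (2 * eps)
            analytic = grads[name][idx]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8), name


class TestTraining:
    def test_easy_problem_learned(self, easy_problem, easy_trained):
        history = easy_trained["history"]
        assert history["train_acc"].iloc[-1] >= 0.95

    def test_learning_curve_decreases(self, easy_trained):
        losses = easy_trained["history"]["train_loss"]
        assert np.median(losses[0:5]) > np.median(losses[15:20])

    def test_heldout_binary_accuracy(self, easy_problem, easy_trained):
        preds = cnn.predict(
            easy_trained["weights"], easy_problem["arch"],
            easy_problem["test_x"], easy_problem["test_ids"],
        )
        truth = easy_problem["test_table"]
        correct = sum(
            (truth.label_of(fid) == Label.MISS) == (binary == "Miss")
            for fid, binary in zip(preds["frame_id"], preds["binary"])
        )
        assert correct / len(preds) >= 0.9

    def test_zero_lr_leaves_weights_at_init(self, easy_problem):
        config = cnn.TrainConfig(
            batch_size=16, batches_per_epoch=3, epochs=2,
            lr_start=0.0, lr_end=0.0, seed=5,
        )
        weights, history = cnn.train(
            easy_problem["train_x"][:90], easy_problem["train_ids"][:90],
            easy_problem["train_table"].select(easy_problem["train_ids"][:90]),
            easy_problem["arch"], config,
        )
        fresh = cnn.init_weights(easy_problem["arch"], np.random.default_rng(5))
        for name, arr in weights.learnables().items():
            np.testing.assert_array_equal(arr, fresh.learnables()[name])
        assert abs(history["train_acc"].mean() - 1 / 3) < 0.25

    def test_deterministic_given_seed(self, easy_problem):
        config = cnn.TrainConfig(
            batch_size=16, batches_per_epoch=3, epochs=3,
            lr_start=0.05, lr_end=0.01, seed=11,
        )
        args = (
            easy_problem["train_x"][:90], easy_problem["train_ids"][:90],
            easy_problem["train_table"].select(easy_problem["train_ids"][:90]),
            easy_problem["arch"], config,
        )
        w1, h1 = cnn.train(*args)
        w2, h2 = cnn.train(*args)
        assert h1.equals(h2)
        np.testing.assert_array_equal(w1.fc_w, w2.fc_w)

    def test_missing_frames_rejected(self, easy_problem):
        config = cnn.TrainConfig(batch_size=4, batches_per_epoch=1, epochs=1)
        with pytest.raises(ValueError, match="missing"):
            cnn.train(
                easy_problem["train_x"][:10], easy_problem["train_ids"][:10],
                easy_problem["train_table"], easy_problem["arch"], config,
            )


class TestPredict:
    def test_duplicate_frames_identical(self, tiny, rng):
        arch, weights = tiny
        x = rng.normal(size=(12, 12))
        out = cnn.predict(weights, arch, np.stack([x, x]), ["a", "b"])
        assert out.loc[0, "p_hit"] == out.loc[1, "p_hit"]
        assert out.loc[0, "three_class"] == out.loc[1, "three_class"]

    def test_order_independent(self, tiny, rng):
        arch, weights = tiny
        x = rng.normal(size=(7, 12, 12))
        ids = [f"f{i}" for i in range(7)]
        fwd = cnn.predict(weights, arch, x, ids).set_index("frame_id")
        rev = cnn.predict(weights, arch, x[::-1], ids[::-1]).set_index("frame_id")
        for fid in ids:
            assert fwd.loc[fid, "p_miss"] == pytest.approx(
                rev.loc[fid, "p_miss"], abs=1e-12
            )

    def test_batch_boundaries_consistent(self, tiny, rng):
        arch, weights = tiny
        x = rng.normal(size=(5, 12, 12))
        a = cnn.predict(weights, arch, x, batch_size=2)
        b = cnn.predict(weights, arch, x, batch_size=64)
        np.testing.assert_allclose(a["p_hit"], b["p_hit"], atol=1e-12)


class TestWeightsIO:
    def test_round_trip(self, tiny, tmp_path, rng):
        arch, weights = tiny
        path = tmp_path / "model.npz"
        cnn.save_weights(path, weights, arch)
        back, back_arch = cnn.load_weights(path)
        assert back_arch == arch
        x = rng.normal(size=(2, 12, 12))
        np.testing.assert_array_equal(
            cnn.forward(weights, arch, x)[2], cnn.forward(back, back_arch, x)[2]
        )

    def test_version_checked(self, tiny, tmp_path):
        arch, weights = tiny
        path = tmp_path / "model.npz"
        cnn.save_weights(path, weights, arch)
        data = dict(np.load(path, allow_pickle=False))
        data["format_version"] = np.array(99)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="version"):
            cnn.load_weights(path)
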