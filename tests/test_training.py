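"""Training protocol: splits, weights, loss, sampling, early stopping."""

import numpy as np
import pytest

from arunet.exceptions import DataError, ParameterError
from arunet.network import build_model
from arunet.training import (
    LabeledExample,
    TrainConfig,
    balanced_batches,
    class_weights,
    split_dataset,
    train,
    weighted_cce,
)


def tiny_examples(per_class, classes=("Normal", "Glioma", "Meningioma"), size=16, seed=0):
    from arunet.synthetic import PhantomSpec, generate_examples

    spec = PhantomSpec(image_size=size)
    ex = generate_examples(spec, per_class=per_class, seed=seed, classes=classes)
    return [LabeledExample(e.image, e.mask, e.class_label) for e in ex]


class TestSplitDataset:
    def test_single_class_600_200_200(self):
        examples = [LabeledExample(np.zeros((2, 2), np.uint8), np.zeros((2, 2), np.uint8), "A")
                    for _ in range(1000)]
        tr, va, te = split_dataset(examples, seed=1, label_of=lambda e: e.image_class)
        assert (len(tr), len(va), len(te)) == (600, 200, 200)

    def test_partition_is_disjoint_and_exhaustive(self):
        examples = tiny_examples(per_class=5)
        tr, va, te = split_dataset(examples, seed=2)
        ids = [id(e) for part in (tr, va, te) for e in part]
        assert len(ids) == len(set(ids)) == len(examples)

    def test_stratified_per_class(self):
        examples = tiny_examples(per_class=10)
        tr, va, te = split_dataset(examples, seed=3)
        for part, expected in ((tr, 6), (va, 2), (te, 2)):
            labels = [e.image_class for e in part]
            assert all(labels.count(c) == expected for c in set(labels))

    def test_seed_determinism(self):
        examples = tiny_examples(per_class=5)
        a = split_dataset(examples, seed=4)
        b = split_dataset(examples, seed=4)
        c = split_dataset(examples, seed=5)
        assert [id(e) for e in a[0]] == [id(e) for e in b[0]]
        assert [id(e) for e in a[0]] != [id(e) for e in c[0]]

    def test_class_too_small_rejected(self):
        examples = tiny_examples(per_class=2)
        with pytest.raises(DataError):
            split_dataset(examples, seed=0)


class TestClassWeights:
    def test_equal_counts_unit_weights(self):
        assert np.allclose(class_weights([10, 10, 10]), 1.0)

    def test_inverse_frequency_example(self):
        w = class_weights([100, 50])
        assert np.allclose(w, [2 / 3, 4 / 3])

    def test_mean_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 1000, size=rng.integers(2, 8))
            assert class_weights(counts).mean() == pytest.approx(1.0)

    def test_zero_count_rejected_with_guidance(self):
        with pytest.raises(DataError, match="drop"):
            class_weights([10, 0, 5])


class TestWeightedCce:
    def test_perfect_one_hot_gives_zero(self):
        probs = np.zeros((2, 2, 3))
        target = np.array([[0, 1], [2, 1]])
        for i in range(2):
            for j in range(2):
                probs[i, j, target[i, j]] = 1.0
        assert weighted_cce(probs, target) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_give_log_c(self):
        c = 6
        probs = np.full((4, 4, c), 1.0 / c)
        target = np.random.default_rng(1).integers(0, c, size=(4, 4))
        assert weighted_cce(probs, target) == pytest.approx(np.log(c), abs=1e-9)
        assert weighted_cce(probs, target) == pytest.approx(1.7918, abs=1e-4)

    def test_linear_in_weights(self):
        probs = np.full((3, 3, 2), 0.5)
        target = np.zeros((3, 3), dtype=int)  # only class 0 represented
        base = weighted_cce(probs, target, np.array([1.0, 1.0]))
        doubled = weighted_cce(probs, target, np.array([2.0, 1.0]))
        assert doubled == pytest.approx(2 * base)

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(4, 4, 5))
        target = rng.integers(0, 5, size=(4, 4))
        assert weighted_cce(logits, target, np.ones(5)) == \
            pytest.approx(weighted_cce(logits, target))

    def test_agrees_with_autograd_loss(self):
        from arunet.nn.tensor import Tensor, weighted_softmax_cross_entropy

        rng = np.random.default_rng(3)
        logits = rng.normal(size=(2, 4, 3, 3))  # N, C, H, W
        target = rng.integers(0, 4, size=(2, 3, 3))
        w = rng.uniform(0.5, 2.0, size=4)
        fused = weighted_softmax_cross_entropy(Tensor(logits), target, w).item()
        plain = weighted_cce(np.moveaxis(logits, 1, -1), target, w)
        assert fused == pytest.approx(plain, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            weighted_cce(np.zeros((2, 2, 3)), np.zeros((3, 3), dtype=int))


class TestBalancedBatches:
    def test_one_of_each_class_when_b_equals_c(self):
        labels = ["a"] * 10 + ["b"] * 3 + ["c"] * 5
        for batch in balanced_batches(labels, batch_size=3, seed=0):
            assert sorted(labels[i] for i in batch) == ["a", "b", "c"]

    def test_epoch_class_frequencies_near_equal(self):
        labels = ["a"] * 20 + ["b"] * 4 + ["c"] * 4
        seen = {"a": 0, "b": 0, "c": 0}
        batches = list(balanced_batches(labels, batch_size=6, seed=1))
        for batch in batches:
            for i in batch:
                seen[labels[i]] += 1
        freqs = list(seen.values())
        assert max(freqs) - min(freqs) <= 2  # one batch's per-class quantum

    def test_seed_determinism(self):
        labels = ["a"] * 8 + ["b"] * 8
        a = list(balanced_batches(labels, 4, seed=2))
        b = list(balanced_batches(labels, 4, seed=2))
        assert a == b

    def test_batch_smaller_than_class_count_rejected(self):
        with pytest.raises(ParameterError):
            list(balanced_batches(["a", "b", "c"], batch_size=2, seed=0))


class TestTrainLoop:
    def test_plateaued_model_stops_after_patience(self):
        # a near-zero learning rate freezes validation loss, so the first
        # epoch is the last improvement and training stops at 1 + patience
        examples = tiny_examples(per_class=4, size=16, seed=5)
        model = build_model("unet", depth=2, base_width=2, n_classes=6, seed=5)
        cfg = TrainConfig(learning_rate=1e-12, batch_size=4, max_epochs=10,
                          patience=2, seed=5)
        result = train(model, examples, examples[:3], cfg)
        assert result.history.stop_reason == "early_stopping"
        assert len(result.history.epochs) == 1 + cfg.patience

    def test_best_checkpoint_attains_max_recorded_wf1(self):
        examples = tiny_examples(per_class=4, size=16, seed=6)
        model = build_model("unet_res", depth=2, base_width=4, n_classes=6, seed=6)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=4,
                          patience=4, seed=6)
        result = train(model, examples, examples[:3], cfg)
        wf1s = [e["val_weighted_f1"] for e in result.history.epochs]
        assert result.best_weighted_f1 == pytest.approx(max(wf1s))
        assert result.history.epochs[result.best_epoch - 1]["val_weighted_f1"] == \
            pytest.approx(max(wf1s))

    def test_identical_seeds_identical_histories(self, tmp_path):
        histories = []
        for run_dir in ("a", "b"):
            examples = tiny_examples(per_class=4, size=16, seed=7)
            model = build_model("unet", depth=2, base_width=2, n_classes=6, seed=7)
            cfg = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=3,
                              patience=3, seed=7)
            result = train(model, examples, examples[:3], cfg)
            path = tmp_path / f"{run_dir}.csv"
            result.history.to_csv(path)
            histories.append(path.read_bytes())
        assert histories[0] == histories[1]

    def test_training_loss_descends_on_separable_phantoms(self):
        examples = tiny_examples(per_class=6, classes=("Normal", "Glioma"),
                                 size=16, seed=8)
        model = build_model("arunet", depth=2, base_width=4, n_classes=6, seed=8)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=10,
                          patience=10, seed=8)
        result = train(model, examples, examples[:3], cfg)
        losses = [e["train_loss"] for e in result.history.epochs]
        assert losses[-1] < losses[0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(learning_rate=0.0).validate()
        with pytest.raises(ParameterError):
            TrainConfig(batch_size=2).validate(n_classes_present=6)
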