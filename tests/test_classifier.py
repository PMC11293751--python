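import numpy as np
import pytest

from tumorseg.classifier import (
    LABEL_TO_INT,
    TrainConfig,
    crossvalidate,
    dataset_to_arrays,
    predict,
    stratified_folds,
    train,
)
from tumorseg.core_io import DatasetItem, GrayImage, LabeledDataset, ValidationError
from tumorseg.nn.network import NetworkSpec, build_network


def _blob_arrays(n, rng, size=64):
    """Linearly separable fixture: class 1 carries a bright square."""
    xs, ys = [], []
    for i in range(n):
        img = rng.random((size, size), dtype=np.float32) * 0.3
        if i % 2 == 1:
            r, c = rng.integers(8, size - 20, size=2)
            img[r : r + 14, c : c + 14] += 0.6
            ys.append(1)
        else:
            ys.append(0)
        xs.append(np.clip(img, 0, 1)[None])
    return np.stack(xs), np.asarray(ys)


def _blob_dataset(n, rng, size=64):
    x, y = _blob_arrays(n, rng, size)
    items = [
        DatasetItem(
            label="abnormal" if yi == 1 else "normal",
            image=GrayImage(pixels=xi[0].astype(np.float64)),
        )
        for xi, yi in zip(x, y)
    ]
    return LabeledDataset(items=items)


SMALL_SPEC = NetworkSpec.default().scaled(0.25, input_shape=(64, 64, 1))


class TestTrain:
    def test_zero_epochs_noop(self, rng):
        x, y = _blob_arrays(8, rng)
        model = build_network(SMALL_SPEC, seed=0)
        before = [p.value.copy() for p in model.params()]
        history = train(model, x, y, TrainConfig(epochs=0, seed=0))
        assert history == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_separable_blobs_learned(self, rng):
        x, y = _blob_arrays(40, rng)
        model = build_network(SMALL_SPEC, seed=1)
        history = train(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=0))
        assert len(history) == 3
        labels, _ = predict(model, x)
        assert (labels == y).mean() >= 0.95

    def test_loss_decreases(self, rng):
        x, y = _blob_arrays(32, rng)
        model = build_network(SMALL_SPEC, seed=2)
        history = train(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=0))
        assert history[-1]["loss"] < history[0]["loss"]

    def test_same_seed_same_first_epoch_loss(self, rng):
        x, y = _blob_arrays(16, rng)
        h1 = train(build_network(SMALL_SPEC, seed=5), x, y,
                   TrainConfig(epochs=1, batch_size=8, seed=3))
        h2 = train(build_network(SMALL_SPEC, seed=5), x, y,
                   TrainConfig(epochs=1, batch_size=8, seed=3))
        assert h1[0]["loss"] == h2[0]["loss"]

    def test_single_class_rejected(self, rng):
        x = rng.random((6, 1, 64, 64), dtype=np.float32)
        y = np.zeros(6, dtype=np.int64)
        with pytest.raises(ValidationError):
            train(build_network(SMALL_SPEC, seed=0), x, y, TrainConfig(epochs=1))


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        model = build_network(SMALL_SPEC, seed=0)
        x = rng.random((5, 1, 64, 64), dtype=np.float32)
        labels, probs = predict(model, x)
        assert labels.shape == (5,)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_rows_identical_outputs(self, rng):
        model = build_network(SMALL_SPEC, seed=0)
        row = rng.random((1, 1, 64, 64), dtype=np.float32)
        x = np.concatenate([row, row])
        _, probs = predict(model, x)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_shape_mismatch_rejected(self, rng):
        model = build_network(SMALL_SPEC, seed=0)
        with pytest.raises(ValidationError):
            predict(model, rng.random((2, 3, 64, 64), dtype=np.float32))


class TestStratifiedFolds:
    def test_partition(self, rng):
        y = np.array([0] * 40 + [1] * 60)
        folds = stratified_folds(y, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 100
        assert len(np.unique(all_idx)) == 100
        for f in folds:
            assert len(f) == 20

    def test_class_ratio_within_one(self):
        y = np.array([0] * 33 + [1] * 67)
        folds = stratified_folds(y, 5, seed=1)
        for f in folds:
            n_pos = int((y[f] == 1).sum())
            assert abs(n_pos - 67 / 5) <= 1

    def test_too_small_class_rejected(self):
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        with pytest.raises(ValidationError):
            stratified_folds(y, 4, seed=0)


class TestCrossvalidate:
    def test_summary_mean_sd_hand_check(self):
        # fold accuracies {0.9, 1.0}: mean 0.95, sample SD 0.0707...
        from tumorseg.classifier import CrossValResult, FoldResult
        from tumorseg.metrics import ConfusionCounts, confusion_metrics

        c1 = ConfusionCounts(tp=9, tn=9, fp=1, fn=1)   # accuracy 0.9
        c2 = ConfusionCounts(tp=10, tn=10, fp=0, fn=0)  # accuracy 1.0
        res = CrossValResult(
            folds=(
                FoldResult(0, c1, confusion_metrics(c1)),
                FoldResult(1, c2, confusion_metrics(c2)),
            )
        )
        s = res.summary()["accuracy"]
        assert s["mean"] == pytest.approx(0.95)
        assert s["sd"] == pytest.approx(np.std([0.9, 1.0], ddof=1))

    def test_constant_folds_zero_sd(self):
        from tumorseg.classifier import CrossValResult, FoldResult
        from tumorseg.metrics import ConfusionCounts, confusion_metrics

        c = ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
        res = CrossValResult(
            folds=tuple(FoldResult(i, c, confusion_metrics(c)) for i in range(5))
        )
        s = res.summary()["accuracy"]
        assert s["mean"] == 1.0 and s["sd"] == 0.0

    def test_end_to_end_small(self, rng):
        ds = _blob_dataset(30, rng)
        cfg = TrainConfig(epochs=2, batch_size=8, folds=3, seed=0)
        res = crossvalidate(ds, cfg, SMALL_SPEC)
        assert len(res.folds) == 3
        total_validated = sum(f.counts.total for f in res.folds)
        assert total_validated == 30


class TestDatasetToArrays:
    def test_shapes_and_labels(self, rng):
        ds = _blob_dataset(6, rng)
        x, y = dataset_to_arrays(ds)
        assert x.shape == (6, 1, 64, 64)
        assert set(np.unique(y)) <= {0, 1}
        assert all(LABEL_TO_INT[item.label] == yi for item, yi in zip(ds.items, y))
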