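"""Training, inference and cross-validated evaluation of the slice classifier.

Labels are encoded ``normal = 0``, ``abnormal = 1``; "positive" means
abnormal throughout. Cross-validation is stratified by class and, when
augmentation is requested, augmentation is applied to the training folds
only, after the split, so transformed near-duplicates never leak into a
validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tumorseg.augment import AugmentConfig, augment_dataset
from tumorseg.core_io import LabeledDataset, ValidationError
from tumorseg.metrics import ConfusionCounts, MetricsReport, confusion_metrics
from tumorseg.nn.network import Network, NetworkSpec, build_network, count_parameters
from tumorseg.nn.optim import make_optimizer

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CrossValResult",
    "dataset_to_arrays",
    "train",
    "predict",
    "crossvalidate",
]

LABEL_TO_INT = {"normal": 0, "abnormal": 1}

#: per-optimizer hyperparameter defaults (learning rate 0.001 throughout)
OPTIMIZER_DEFAULTS = {
    "sgdm": {"momentum": 0.9},
    "adam": {"beta1": 0.9, "beta2": 0.999, "eps": 1e-7},
    "adamax": {"beta1": 0.9, "beta2": 0.999, "eps": 1e-7},
    "adagrad": {"eps": 1e-7},
    "adadelta": {"rho": 0.95, "eps": 1e-7},
    "rmsprop": {"rho": 0.9, "eps": 1e-7},
    "nadam": {"beta1": 0.9, "beta2": 0.999, "eps": 1e-7},
}


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 30
    folds: int = 5
    seed: int = 0
    hyper: dict = field(default_factory=dict)  # optimizer-specific overrides

    def make_optimizer(self):
        name = self.optimizer.lower()
        if name not in OPTIMIZER_DEFAULTS:
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        kw = dict(OPTIMIZER_DEFAULTS[name])
        kw.update(self.hyper)
        return make_optimizer(name, lr=self.learning_rate, **kw)


@dataclass(frozen=True)
class FoldResult:
    fold: int
    counts: ConfusionCounts
    report: MetricsReport


@dataclass(frozen=True)
class CrossValResult:
    folds: tuple[FoldResult, ...]

    def summary(self) -> dict:
        """Mean and sample standard deviation of each metric across folds."""
        out = {}
        for name in ("tpr", "tnr", "ppv", "f_score", "auc", "accuracy"):
            vals = [getattr(f.report, name) for f in self.folds]
            vals = [v for v in vals if v is not None]
            if not vals:
                out[name] = {"mean": None, "sd": None}
                continue
            arr = np.asarray(vals, dtype=np.float64)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            out[name] = {"mean": float(arr.mean()), "sd": sd}
        return out


def dataset_to_arrays(ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into ``(N, 1, H, W)`` float32 images and int labels."""
    xs, ys = [], []
    for item in ds.items:
        img = item.load_image()
        xs.append(img.pixels.astype(np.float32)[None])
        ys.append(LABEL_TO_INT[item.label])
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def train(
    model: Network,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> list[dict]:
    """Mini-batch training; returns one history entry per epoch.

    Zero epochs is a no-op returning an empty history. Epoch-level shuffling
    is seeded from ``cfg.seed``, so repeated runs are reproducible.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if x.shape[0] == 0:
        raise ValidationError("cannot train on an empty dataset")
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    opt = cfg.make_optimizer()
    rng = np.random.default_rng(cfg.seed)
    params = model.params()
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, probs = model.loss_and_grad(x[idx], y[idx])
            opt.step(params)
            losses.append(loss * idx.size)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"epoch": epoch, "loss": float(np.sum(losses) / n), "accuracy": correct / n}
        )
    if cfg.epochs > 0:
        model.calibrate_batchnorm(x, batch_size=cfg.batch_size)
    return history


def predict(model: Network, x: np.ndarray, batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Labels (argmax) and class probabilities for a batch of images."""
    if x.ndim != 4 or x.shape[1] != model.spec.input_shape[2]:
        raise ValidationError(
            f"expected images of shape (N, {model.spec.input_shape[2]}, H, W), got {x.shape}"
        )
    probs = np.concatenate(
        [model.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    )
    return probs.argmax(axis=1), probs


def stratified_folds(y: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified K-fold validation indices.

    Each class is shuffled and dealt round-robin, so fold class counts
    differ by at most one item per class.
    """
    if k < 2:
        raise ValidationError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValidationError(
                f"class {cls} has {idx.size} items, fewer than {k} folds"
            )
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.asarray(f)) for f in folds]


def crossvalidate(
    ds: LabeledDataset,
    cfg: TrainConfig | None = None,
    spec: NetworkSpec | None = None,
    augment_cfg: AugmentConfig | None = None,
) -> CrossValResult:
    """Stratified K-fold cross-validation of a freshly built model per fold.

    When ``augment_cfg`` is given, each training fold is augmented after the
    split; validation folds always see original images only.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    spec = spec if spec is not None else NetworkSpec.default()
    y_all = np.asarray([LABEL_TO_INT[item.label] for item in ds.items])
    folds = stratified_folds(y_all, cfg.folds, seed=cfg.seed)
    results: list[FoldResult] = []
    for fold_idx, val_idx in enumerate(folds):
        val_set = set(val_idx.tolist())
        train_items = [item for i, item in enumerate(ds.items) if i not in val_set]
        train_ds = LabeledDataset(items=train_items)
        if augment_cfg is not None:
            train_ds = augment_dataset(train_ds, augment_cfg)
        x_tr, y_tr = dataset_to_arrays(train_ds)
        x_va, y_va = dataset_to_arrays(
            LabeledDataset(items=[ds.items[i] for i in val_idx])
        )
        model = build_network(spec, seed=cfg.seed + fold_idx)
        train(model, x_tr, y_tr, cfg)
        labels, _ = predict(model, x_va)
        tp = int(((labels == 1) & (y_va == 1)).sum())
        tn = int(((labels == 0) & (y_va == 0)).sum())
        fp = int(((labels == 1) & (y_va == 0)).sum())
        fn = int(((labels == 0) & (y_va == 1)).sum())
        counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        results.append(
            FoldResult(fold=fold_idx, counts=counts, report=confusion_metrics(counts))
        )
    return CrossValResult(folds=tuple(results))
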