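"""Training, evaluation and ablation experiments for the patch classifier.

Training minimises the 4-way cross-entropy with Adam under a step
learning-rate policy (base rate 0.001, decayed by a fixed factor every few
epochs).  The train side holds original patches plus their differential
copies; the test side holds originals only.  Evaluation reports the 4x4
confusion matrix, overall accuracy and macro-averaged one-vs-rest
sensitivity and specificity.

The ablation runner sweeps structure components — depth, filter counts,
kernel size, batch normalisation, patch size, and the skip connection — with
fixed seeds and emits one tidy result row per grid point.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .diffaug import DatasetSplit, DifferentialPatch, build_split
from .errors import DataError, DivergenceError, ParameterError
from .model import (
    ArchitectureSpec,
    ModelState,
    build_network,
    count_flops,
    count_params,
    experiment_spec,
    normalize_inputs,
    softmax_head,
)
from .patches import Patch, PatchConfig, extract_dataset_patches
from .synth import CLASS_LABELS, default_class_params, generate_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Adam + step-decay schedule.

    ``learning_rate`` is the base rate (default 0.001); it is multiplied by
    ``lr_decay`` every ``lr_step_epochs`` epochs, so the per-epoch rate is
    positive and non-increasing.  ``warmup_steps`` linearly ramps the rate
    from 0 over the first optimisation steps — with Adam and the very large
    fully connected fan-in the first full-rate steps otherwise swing the
    logits hard enough to leave the second convolution's ReLU permanently
    dead.  ``target_accuracy`` optionally stops training early once the
    per-epoch test accuracy reaches the target.
    """

    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    lr_decay: float = 0.5
    lr_step_epochs: int = 5
    warmup_steps: int = 100
    seed: int = 0
    target_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not 0 < self.lr_decay <= 1:
            raise ParameterError(f"lr_decay must be in (0, 1], got {self.lr_decay}")
        if self.epochs < 0 or self.batch_size < 1 or self.lr_step_epochs < 1:
            raise ParameterError("epochs >= 0, batch_size >= 1, lr_step_epochs >= 1 required")
        if self.warmup_steps < 0:
            raise ParameterError(f"warmup_steps must be >= 0, got {self.warmup_steps}")

    def lr_at_epoch(self, epoch: int) -> float:
        """Post-warmup base rate for an epoch (non-increasing in the epoch)."""
        return self.learning_rate * self.lr_decay ** (epoch // self.lr_step_epochs)

    def lr_at_step(self, epoch: int, step: int) -> float:
        base = self.lr_at_epoch(epoch)
        if self.warmup_steps and step < self.warmup_steps:
            return base * (step + 1) / self.warmup_steps
        return base


@dataclass
class TrainingHistory:
    """Per-step losses/accuracies, per-epoch test accuracy, final model."""

    step_loss: list[float] = field(default_factory=list)
    step_accuracy: list[float] = field(default_factory=list)
    epoch_test_accuracy: list[float] = field(default_factory=list)
    model: ModelState | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": range(len(self.step_loss)),
                             "loss": self.step_loss, "train_accuracy": self.step_accuracy})


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix (rows = true, cols = predicted) and macro metrics."""

    confusion: np.ndarray
    accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    classes: tuple[str, ...] = CLASS_LABELS

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "classes": list(self.classes),
        }


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= corr * m / (np.sqrt(v) + self.eps)


def _split_arrays(items: Sequence[Patch | DifferentialPatch]) -> tuple[np.ndarray, np.ndarray]:
    bad = [p.class_label for p in items if p.class_label not in CLASS_LABELS]
    if bad:
        raise DataError(f"labels outside the four classes: {sorted(set(bad))}")
    x = normalize_inputs([p.pixels for p in items])[..., None]
    y = np.array([CLASS_LABELS.index(p.class_label) for p in items], dtype=np.int64)
    return x, y


def train(
    model: ModelState,
    split: DatasetSplit,
    config: TrainConfig,
    quiet: bool = False,
) -> TrainingHistory:
    """Fit ``model`` on the split's train side (originals + differentials).

    Fully seeded (shuffling from ``config.seed``; weights from the model's
    own build seed).  Per-epoch test accuracy is recorded when the split has
    a test side.  Raises DivergenceError with the offending step index if the
    loss goes non-finite.
    """
    history = TrainingHistory(model=model)
    if config.epochs == 0:
        return history

    train_items = list(split.train)
    if not train_items:
        raise DataError("training set is empty")
    x_train, y_train = _split_arrays(train_items)
    x_test = y_test = None
    if split.test:
        x_test, y_test = _split_arrays(split.test)

    optimizer = _Adam(model.parameters())
    rng = np.random.default_rng(config.seed)
    n = len(x_train)
    step = 0
    t0 = time.monotonic()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            lr = config.lr_at_step(epoch, step)
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward_logits(xb, train=True)
            probs = softmax_head(logits)
            eps = 1e-12
            loss = float(-np.log(np.clip(probs[np.arange(len(yb)), yb], eps, None)).mean())
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at step {step}")
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.backward((dlogits / len(yb)).astype(np.float32))
            optimizer.step(model.parameters(), model.gradients(), lr)
            history.step_loss.append(loss)
            history.step_accuracy.append(float((probs.argmax(1) == yb).mean()))
            step += 1
        if x_test is not None:
            acc = float((_predict_classes(model, x_test) == y_test).mean())
            history.epoch_test_accuracy.append(acc)
            if not quiet:
                logger.info(
                    "epoch %d/%d lr=%.2e loss=%.4f test_acc=%.4f (%.1fs)",
                    epoch + 1, config.epochs, lr, loss, acc, time.monotonic() - t0,
                )
            if config.target_accuracy is not None and acc >= config.target_accuracy:
                break
    return history


def _predict_classes(model: ModelState, x: np.ndarray) -> np.ndarray:
    # argmax breaks ties toward the lowest class index
    return model.predict_proba(x).argmax(axis=1)


def evaluate(model: ModelState, test_patches: Sequence[Patch]) -> EvaluationReport:
    """Confusion matrix, accuracy, and macro one-vs-rest sensitivity/specificity."""
    if not test_patches:
        raise DataError("test set is empty")
    x, y = _split_arrays(test_patches)
    pred = _predict_classes(model, x)
    return report_from_predictions(y, pred)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    k = len(CLASS_LABELS)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    sens, spec = [], []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
    return EvaluationReport(
        confusion=cm,
        accuracy=accuracy,
        macro_sensitivity=float(np.mean(sens)),
        macro_specificity=float(np.mean(spec)),
    )


# ---------------------------------------------------------------------------
# Default synthetic experiment assembly
# ---------------------------------------------------------------------------

def default_experiment_split(
    seed: int = 0,
    patches_per_class: int = 500,
    window: int = 28,
    image_size: tuple[int, int] = (256, 256),
    images_per_class: int = 4,
    train_fraction: float = 0.5,
) -> DatasetSplit:
    """Synthetic images -> capped patch extraction -> augmented stratified split.

    Defaults mirror the study conditions: four grades with class means
    70/85/150/165, about 500 patches per class cut by a 28-pixel moving
    window, half the originals plus all their differentials for training and
    the other half for testing.
    """
    images = generate_dataset(
        default_class_params(), images_per_class, image_size[0], image_size[1], seed=seed
    )
    config = PatchConfig(window=window, stride=max(1, window // 2))
    patches = extract_dataset_patches(images, config, per_class_cap=patches_per_class, seed=seed)
    return build_split(patches, train_fraction=train_fraction, seed=seed)


# ---------------------------------------------------------------------------
# Ablation experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationPoint:
    """One structure-component configuration to train and score."""

    name: str
    conv_filters: tuple[int, ...] = (16, 32)
    kernel: int = 3
    batchnorm: bool = False
    window: int = 28
    skip_enabled: bool = True

    def spec(self) -> ArchitectureSpec:
        return experiment_spec(
            window=self.window,
            conv_filters=self.conv_filters,
            kernel=self.kernel,
            batchnorm=self.batchnorm,
            skip_enabled=self.skip_enabled,
        )


def run_ablation(
    grid: Sequence[AblationPoint],
    config: TrainConfig,
    seeds: Sequence[int] = (0,),
    split_provider: Callable[[int, int], DatasetSplit] | None = None,
) -> pd.DataFrame:
    """Train/score every grid point at every seed; one tidy row per run.

    ``split_provider(window, seed)`` supplies the dataset for a given patch
    size (defaults to :func:`default_experiment_split`).  Invalid grid points
    (e.g. shapes that do not propagate) are skipped with a logged reason.
    """
    if split_provider is None:
        split_provider = lambda window, seed: default_experiment_split(seed=seed, window=window)

    rows = []
    split_cache: dict[tuple[int, int], DatasetSplit] = {}
    for point in grid:
        try:
            spec = point.spec()
            complexity = count_params(spec)
        except Exception as exc:  # noqa: BLE001 - skip-and-continue contract
            logger.warning("skipping grid point %s: %s", point.name, exc)
            continue
        for seed in seeds:
            key = (point.window, seed)
            if key not in split_cache:
                split_cache[key] = split_provider(point.window, seed)
            split = split_cache[key]
            model = build_network(spec, seed=seed)
            train(model, split, replace(config, seed=seed), quiet=True)
            report = evaluate(model, split.test)
            rows.append(
                {
                    "name": point.name,
                    "conv_filters": "x".join(map(str, point.conv_filters)),
                    "kernel": point.kernel,
                    "batchnorm": point.batchnorm,
                    "window": point.window,
                    "skip": point.skip_enabled,
                    "seed": seed,
                    "accuracy": report.accuracy,
                    "macro_sensitivity": report.macro_sensitivity,
                    "macro_specificity": report.macro_specificity,
                    "params": complexity.total_params,
                    "flops": count_flops(spec).total_flops,
                }
            )
    return pd.DataFrame(rows)
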