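"""Mini-batch training with Adam, seeded reproducibility and plateau stopping.

The training pipeline per step: draw a shuffled mini-batch, augment each
image (brightness, contrast, random crop to the architecture's train size,
flips) or center-crop when augmentation is off, standardize per image,
forward, loss, backpropagate, Adam update.  Test-set evaluation during
training uses the deterministic center-crop path only — test images are
never augmented.  The protocol deliberately has no validation set: training
stops when the training-loss trace plateaus (window-mean relative
improvement below a tolerance) or at the step budget.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentationConfig, augment, center_crop
from .errors import ConfigurationError, TrainingDivergenceError
from .io import DatasetSplit, resize_image, standardize_image
from .nn import Adam, ArchitectureSpec, Network, cross_entropy, mse
from .samples import ImageSample


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    ``label_scale`` divides regression targets during training (and is
    undone at prediction time) so that targets of very different natural
    scales — leaf counts vs ages in hours — train at comparable loss
    magnitudes.
    """

    learning_rate: float = 1e-3
    batch_size: int = 16
    max_steps: int = 2000
    plateau_window: int = 500
    plateau_tolerance: float = 0.01
    seed: int = 0
    augmentation: Optional[AugmentationConfig] = field(default_factory=AugmentationConfig)
    eval_every: int = 100
    label_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.plateau_window < 2:
            raise ConfigurationError("plateau_window must be >= 2")
        if not 0.0 <= self.plateau_tolerance < 1.0:
            raise ConfigurationError("plateau_tolerance must be in [0, 1)")
        if self.label_scale <= 0:
            raise ConfigurationError("label_scale must be > 0")


@dataclass
class TrainingTrace:
    """Per-step training loss plus sparse test loss (every ``eval_every``)."""

    steps: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_steps: list[int] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        test_at = dict(zip(self.test_steps, self.test_loss))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "train_loss", "test_loss"])
            for s, tl in zip(self.steps, self.train_loss):
                writer.writerow([s, f"{tl:.6g}", f"{test_at[s]:.6g}" if s in test_at else ""])


def plateau_reached(trace: TrainingTrace, window: int, tolerance: float) -> bool:
    """True when the mean train loss of the last window improves on the
    previous window's mean by a relative factor below ``tolerance``."""
    losses = trace.train_loss
    if len(losses) < 2 * window:
        return False
    last = float(np.mean(losses[-window:]))
    prev = float(np.mean(losses[-2 * window : -window]))
    if prev <= 0.0:
        return True
    return (prev - last) / prev < tolerance


def _prepare_train_images(samples: Sequence[ImageSample], spec: ArchitectureSpec) -> np.ndarray:
    n, m = spec.input_size
    return np.stack([resize_image(s.image, n, m) for s in samples]).astype(np.float32)


def _labels_array(samples: Sequence[ImageSample], task: str, label_scale: float) -> np.ndarray:
    if task == "classification":
        return np.array([int(s.label) for s in samples], dtype=np.int64)
    return np.array([float(s.label) / label_scale for s in samples], dtype=np.float32)


def prepare_eval_batch(samples_or_images, spec: ArchitectureSpec) -> np.ndarray:
    """Deterministic test-time pipeline: resize, center crop, standardize."""
    n, m = spec.input_size
    ch, cw = spec.train_input_size
    out = []
    for s in samples_or_images:
        img = s.image if isinstance(s, ImageSample) else s
        img = resize_image(img, n, m)
        out.append(standardize_image(center_crop(img, ch, cw)))
    return np.stack(out).astype(np.float32)


def _eval_loss(net: Network, samples: Sequence[ImageSample], labels: np.ndarray) -> float:
    preds = net.forward(prepare_eval_batch(samples, net.spec), training=False)
    if net.spec.task == "classification":
        return cross_entropy(preds, labels)
    return mse(preds[:, 0], labels)


def train(
    spec: ArchitectureSpec, split: DatasetSplit, config: TrainingConfig
) -> tuple[Network, TrainingTrace]:
    """Train a network on the split's train set; returns it with the trace.

    Xavier-initialized parameters are updated by Adam on shuffled
    mini-batches of augmented, standardized images.  Bit-reproducible under
    a fixed seed on a fixed BLAS/thread configuration.  Raises
    :class:`TrainingDivergenceError` if the loss becomes non-finite.
    """
    if not split.train:
        raise ConfigurationError("split.train is empty")
    rng = np.random.default_rng(config.seed)
    net = Network(spec, rng)
    trace = TrainingTrace()
    if config.max_steps == 0:
        return net, trace

    opt = Adam(net.params(), learning_rate=config.learning_rate)
    images = _prepare_train_images(split.train, spec)
    labels = _labels_array(split.train, spec.task, config.label_scale)
    test_labels = (
        _labels_array(split.test, spec.task, config.label_scale) if split.test else None
    )
    ch, cw = spec.train_input_size
    n_train = len(split.train)
    order = rng.permutation(n_train)
    cursor = 0

    for step in range(1, config.max_steps + 1):
        idx = []
        for _ in range(min(config.batch_size, n_train)):
            if cursor >= n_train:
                order = rng.permutation(n_train)
                cursor = 0
            idx.append(order[cursor])
            cursor += 1
        batch = np.empty((len(idx), ch, cw, 3), dtype=np.float32)
        for row, i in enumerate(idx):
            img = images[i]
            if config.augmentation is not None:
                carrier = ImageSample(image=img, label=0.0, label_kind="count", id="batch")
                img = augment(carrier, config.augmentation, rng).image
                if img.shape[:2] != (ch, cw):
                    img = center_crop(img, ch, cw)
            else:
                img = center_crop(img, ch, cw)
            batch[row] = standardize_image(img)
        y = labels[idx]

        preds = net.forward(batch, training=True, rng=rng)
        if spec.task == "classification":
            step_loss = cross_entropy(preds, y)
            dout = preds.copy()
            dout[np.arange(len(y)), y] -= 1.0
            dout /= len(y)
        else:
            step_loss = mse(preds[:, 0], y)
            dout = (2.0 / preds.size) * (preds - y[:, None])
        if not np.isfinite(step_loss):
            raise TrainingDivergenceError(step, step_loss)

        net.zero_grads()
        net.backward(dout)
        opt.step()

        trace.steps.append(step)
        trace.train_loss.append(float(step_loss))
        if test_labels is not None and config.eval_every > 0 and step % config.eval_every == 0:
            trace.test_steps.append(step)
            trace.test_loss.append(_eval_loss(net, split.test, test_labels))

        if step >= 2 * config.plateau_window and plateau_reached(
            trace, config.plateau_window, config.plateau_tolerance
        ):
            break

    return net, trace
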