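"""Metrics, reports, the lighting-robustness protocol and filter grids.

The headline leaf-counting metric is the mean absolute difference (MAD)
between the unrounded regressor output and the true count, reported with
its population standard deviation.  Classification reports exact-match
accuracy.  Signed-error histograms use unrounded errors so bins are
granular.  The robustness protocol perturbs the brightness and contrast of
test images — with parameters outside the training augmentation envelope —
before the ordinary center-crop / standardize / forward path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentationConfig, random_brightness, random_contrast
from .errors import ConfigurationError
from .nn import Network
from .samples import ImageSample
from .training import prepare_eval_batch


def mean_abs_difference(
    predictions: Sequence[float], truths: Sequence[float]
) -> tuple[float, float]:
    """Mean and population standard deviation of |pred - truth|.

    Predictions are not rounded; the dispersion divides by n.
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise ConfigurationError(
            f"predictions and truths must be equal-length 1-d sequences, got {p.shape} vs {t.shape}"
        )
    abs_err = np.abs(p - t)
    return float(abs_err.mean()), float(abs_err.std())


def classification_accuracy(
    predicted_classes: Sequence[int], true_classes: Sequence[int]
) -> float:
    """Fraction of exact matches; undefined (an error) on empty input."""
    p = np.asarray(predicted_classes)
    t = np.asarray(true_classes)
    if p.size == 0:
        raise ConfigurationError("accuracy is undefined for empty inputs")
    if p.shape != t.shape:
        raise ConfigurationError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean(p == t))


def error_histogram(
    per_sample_errors: Sequence[float], n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of signed errors over [min, max].

    Returns (bin_edges, counts); the last bin is right-inclusive, so the
    counts always sum to n.
    """
    errors = np.asarray(per_sample_errors, dtype=np.float64)
    if errors.size == 0:
        raise ConfigurationError("cannot histogram an empty error sequence")
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    counts, edges = np.histogram(errors, bins=n_bins)
    return edges, counts


@dataclass
class EvaluationReport:
    """Dataset-level evaluation result for one model."""

    task: str
    n_test: int
    mean_abs_diff: float
    sd_abs_diff: float
    accuracy: Optional[float] = None
    per_sample_errors: np.ndarray = field(default_factory=lambda: np.zeros(0))
    histogram: Optional[tuple[np.ndarray, np.ndarray]] = None

    def to_json(self) -> str:
        d = {
            "task": self.task,
            "n_test": self.n_test,
            "mean_abs_diff": self.mean_abs_diff,
            "sd_abs_diff": self.sd_abs_diff,
            "accuracy": self.accuracy,
            "per_sample_errors": np.asarray(self.per_sample_errors).tolist(),
        }
        if self.histogram is not None:
            d["histogram"] = {
                "bin_edges": np.asarray(self.histogram[0]).tolist(),
                "counts": np.asarray(self.histogram[1]).tolist(),
            }
        return json.dumps(d, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def predict(
    net: Network,
    samples: Sequence[ImageSample],
    batch_size: int = 64,
    label_scale: float = 1.0,
) -> np.ndarray:
    """Predictions for a list of samples, in input order.

    Regression returns a 1-d array on the label's natural scale;
    classification returns an (n, C) array of class probabilities.
    """
    outputs = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        preds = net.forward(prepare_eval_batch(chunk, net.spec), training=False)
        outputs.append(preds)
    stacked = np.concatenate(outputs, axis=0)
    if net.spec.task == "regression":
        return stacked[:, 0] * label_scale
    return stacked


def evaluate_model(
    net: Network,
    samples: Sequence[ImageSample],
    label_scale: float = 1.0,
    n_bins: int = 20,
) -> EvaluationReport:
    """Clean evaluation: center-crop path, MAD (+accuracy for classifiers)."""
    if not samples:
        raise ConfigurationError("cannot evaluate on an empty sample list")
    preds = predict(net, samples, label_scale=label_scale)
    if net.spec.task == "classification":
        truths = np.array([int(s.label) for s in samples])
        hard = preds.argmax(axis=1)
        errors = (hard - truths).astype(np.float64)
        mad, sd = mean_abs_difference(hard, truths)
        acc = classification_accuracy(hard, truths)
    else:
        truths = np.array([float(s.label) for s in samples])
        errors = preds - truths
        mad, sd = mean_abs_difference(preds, truths)
        acc = None
    return EvaluationReport(
        task=net.spec.task,
        n_test=len(samples),
        mean_abs_diff=mad,
        sd_abs_diff=sd,
        accuracy=acc,
        per_sample_errors=errors,
        histogram=error_histogram(errors, n_bins),
    )


def robustness_eval(
    net: Network,
    samples: Sequence[ImageSample],
    distortion: AugmentationConfig,
    seed: int,
    label_scale: float = 1.0,
) -> EvaluationReport:
    """Evaluate under photometric distortion of the test images.

    Each test image receives one seeded random brightness shift followed by
    one contrast adjustment (the distortion envelope may exceed the one
    seen in training — that is the point), then the standard deterministic
    path.  A zero-distortion configuration reproduces the clean report.
    """
    if not samples:
        raise ConfigurationError("cannot evaluate on an empty sample list")
    rng = np.random.default_rng(seed)
    distorted = []
    for s in samples:
        img = random_brightness(s.image, distortion.brightness_max_delta, rng)
        img = random_contrast(img, distortion.contrast_lower, distortion.contrast_upper, rng)
        distorted.append(s.with_image(img))
    return evaluate_model(net, distorted, label_scale=label_scale)


def visualize_filters(net: Network, layer_index: int = 0) -> np.ndarray:
    """Tile the first convolutional layer's filters into an RGB grid image.

    Each filter is min-max normalized to 0-255 independently; a filter with
    zero range renders mid-gray.  The grid is ceil(sqrt(k)) rows by
    ceil(k / rows) columns, blank tiles mid-gray.  Only a 3-input-channel
    (first) convolutional layer can be visualized; deeper layers operate on
    abstract feature maps and are rejected.
    """
    from .nn.layers import Conv2D

    if not 0 <= layer_index < len(net.layers):
        raise ConfigurationError(f"layer index {layer_index} out of range")
    layer = net.layers[layer_index]
    if not isinstance(layer, Conv2D):
        raise ConfigurationError(f"layer {layer_index} is not convolutional")
    if layer.cin != 3:
        raise ConfigurationError(
            f"layer {layer_index} has {layer.cin} input channels; only the first "
            "(RGB-input) convolutional layer can be visualized"
        )
    w = layer.W  # (kh, kw, 3, k)
    kh, kw, _, k = w.shape
    rows = math.ceil(math.sqrt(k))
    cols = math.ceil(k / rows)
    grid = np.full((rows * kh, cols * kw, 3), 128, dtype=np.uint8)
    for f in range(k):
        tile = w[:, :, :, f].astype(np.float64)
        lo, hi = tile.min(), tile.max()
        if hi - lo < 1e-12:
            norm = np.full_like(tile, 127.5)
        else:
            norm = (tile - lo) / (hi - lo) * 255.0
        r, c = divmod(f, cols)
        grid[r * kh : (r + 1) * kh, c * kw : (c + 1) * kw] = np.round(norm).astype(np.uint8)
    return grid
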