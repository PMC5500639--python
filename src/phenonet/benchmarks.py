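"""Scaled-down synthetic benchmark studies.

Each study generates a fully labelled synthetic rosette dataset, trains a
reduced-capacity network of the corresponding canonical layout at a
reduced image size, and measures the task metric on a held-out 20% split.
They exist so the whole pipeline — generation, loading, augmentation,
training, evaluation, robustness — can be exercised end to end on a single
CPU in minutes; the reduced problem sizes (a few hundred 64-pixel images,
8-16 filters per layer) are the package's own desk-scale study conditions,
not a reproduction of any external benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .architectures import canonical_spec
from .augment import AugmentationConfig, robustness_config
from .evaluation import EvaluationReport, evaluate_model, predict, robustness_eval
from .io import DatasetSplit, split_train_test
from .nn import ArchitectureSpec, Network, conv, dropout, fully_connected, output, pool
from .samples import ImageSample
from .synthetic import RenderConfig, generate_dataset
from .training import TrainingConfig, TrainingTrace, train


def _seed_for(seed: int, tag: int) -> int:
    """Derive a stream-specific 31-bit seed from one master seed."""
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def reduced_count_spec(image_size: int = 64, filters: Sequence[int] = (8, 8, 16, 16, 16)) -> ArchitectureSpec:
    """The leaf-counting layout (five conv+pool stages, tanh, one output)
    at a reduced input size and filter schedule."""
    layers = []
    for k, f in zip((5, 5, 3, 3, 3), filters):
        layers += [conv(k, f, "tanh"), pool(3, 2)]
    layers.append(output(1))
    return ArchitectureSpec(
        name=f"count_{image_size}",
        input_size=(image_size, image_size),
        layers=tuple(layers),
        task="regression",
        outputs=1,
        crop_fraction=0.25,
    )


def reduced_class_spec(
    image_size: int = 64, filters: Sequence[int] = (8, 16, 16, 16), n_classes: int = 5
) -> ArchitectureSpec:
    """Mutant-classifier layout (conv 5x5 stages, ReLU, dropout-regularized
    classifier head, softmax) at reduced capacity."""
    layers = []
    for f in filters:
        layers += [conv(5, f, "relu"), pool(3, 2)]
    layers += [fully_connected(64, "relu"), dropout(0.5), output(n_classes)]
    return ArchitectureSpec(
        name=f"class_{image_size}",
        input_size=(image_size, image_size),
        layers=tuple(layers),
        task="classification",
        outputs=n_classes,
        crop_fraction=0.25,
    )


def reduced_age_spec(image_size: int = 64, filters: Sequence[int] = (16, 32)) -> ArchitectureSpec:
    """Age-regression layout (two 3x3 conv+pool stages, ReLU, one hidden
    fully connected layer) at reduced capacity."""
    layers = []
    for f in filters:
        layers += [conv(3, f, "relu"), pool(3, 2)]
    layers += [fully_connected(128, "relu"), output(1)]
    return ArchitectureSpec(
        name=f"age_{image_size}",
        input_size=(image_size, image_size),
        layers=tuple(layers),
        task="regression",
        outputs=1,
        crop_fraction=0.25,
    )


@dataclass
class StudyResult:
    """Everything a study produced: data split, model, trace and report."""

    net: Network
    trace: TrainingTrace
    split: DatasetSplit
    report: EvaluationReport
    label_scale: float


def memorization_study(seed: int = 0, n: int = 8, max_steps: int = 2000) -> TrainingTrace:
    """Fit the full-size leaf-counting architecture (filter schedule reduced
    to 8 per layer) to a handful of samples with augmentation off.

    A network of sufficient capacity drives the training loss arbitrarily
    low on a tiny set; the returned trace documents the descent.  Plateau
    stopping is disabled (tolerance 0) so the trace runs to ``max_steps``
    unless the loss stops improving entirely.
    """
    spec = canonical_spec("A2", filters=[8] * 5)
    samples = generate_dataset(
        n, "count", "arabidopsis_like", RenderConfig(image_size=128, seed=0), seed=_seed_for(seed, 1)
    )
    # every sample goes to train: memorization is the point, there is
    # nothing to hold out
    split = DatasetSplit(train=samples, test=[], seed=0, train_fraction=1.0)
    config = TrainingConfig(
        learning_rate=3e-3,
        batch_size=min(8, n),
        max_steps=max_steps,
        plateau_window=500,
        plateau_tolerance=0.0,
        seed=_seed_for(seed, 3),
        augmentation=None,
        eval_every=0,
        label_scale=1.0,
    )
    _, trace = train(spec, split, config)
    return trace


def leaf_count_study(
    seed: int = 0,
    n: int = 400,
    image_size: int = 64,
    max_steps: int = 4000,
    augmentation: Optional[AugmentationConfig] = None,
) -> StudyResult:
    """Train the reduced leaf counter on synthetic rosettes (counts 5-20)
    and report the test-split MAD.  Trains with the standard augmentation
    envelope by default."""
    if augmentation is None:
        augmentation = AugmentationConfig()  # training envelope
    samples = generate_dataset(
        n, "count", "arabidopsis_like", RenderConfig(image_size=image_size, seed=0),
        seed=_seed_for(seed, 11),
    )
    split = split_train_test(samples, 0.8, seed=_seed_for(seed, 12))
    spec = reduced_count_spec(image_size)
    label_scale = 10.0
    config = TrainingConfig(
        learning_rate=1e-3,
        batch_size=16,
        max_steps=max_steps,
        plateau_window=500,
        plateau_tolerance=0.005,
        seed=_seed_for(seed, 13),
        augmentation=augmentation,
        eval_every=200,
        label_scale=label_scale,
    )
    net, trace = train(spec, split, config)
    report = evaluate_model(net, split.test, label_scale=label_scale)
    return StudyResult(net, trace, split, report, label_scale)


def classification_study(
    seed: int = 0, n: int = 300, image_size: int = 64, max_steps: int = 3000
) -> StudyResult:
    """Train the reduced five-class morphology classifier and report
    test accuracy (chance is 1/5)."""
    samples = generate_dataset(
        n, "class", "arabidopsis_like", RenderConfig(image_size=image_size, seed=0),
        seed=_seed_for(seed, 21),
    )
    split = split_train_test(samples, 0.8, seed=_seed_for(seed, 22))
    spec = reduced_class_spec(image_size)
    config = TrainingConfig(
        learning_rate=1e-3,
        batch_size=16,
        max_steps=max_steps,
        plateau_window=400,
        plateau_tolerance=0.005,
        seed=_seed_for(seed, 23),
        augmentation=AugmentationConfig(),
        eval_every=200,
    )
    net, trace = train(spec, split, config)
    report = evaluate_model(net, split.test)
    return StudyResult(net, trace, split, report, 1.0)


def age_study(
    seed: int = 0, n: int = 300, image_size: int = 64, max_steps: int = 3000
) -> tuple[StudyResult, float]:
    """Train the reduced age regressor (leaf size encodes age) and return
    the study plus the Pearson correlation of predicted vs true test ages."""
    samples = generate_dataset(
        n, "age", "arabidopsis_like", RenderConfig(image_size=image_size, seed=0),
        seed=_seed_for(seed, 31),
    )
    split = split_train_test(samples, 0.8, seed=_seed_for(seed, 32))
    spec = reduced_age_spec(image_size)
    label_scale = 100.0
    # age loss plateaus shallowly; a tight tolerance avoids stopping
    # before the size->age mapping is fully resolved
    config = TrainingConfig(
        learning_rate=1e-3,
        batch_size=16,
        max_steps=max_steps,
        plateau_window=400,
        plateau_tolerance=0.001,
        seed=_seed_for(seed, 33),
        augmentation=AugmentationConfig(),
        eval_every=200,
        label_scale=label_scale,
    )
    net, trace = train(spec, split, config)
    report = evaluate_model(net, split.test, label_scale=label_scale)
    preds = predict(net, split.test, label_scale=label_scale)
    truths = np.array([float(s.label) for s in split.test])
    corr = float(np.corrcoef(preds, truths)[0, 1])
    return StudyResult(net, trace, split, report, label_scale), corr


def robustness_study(
    result: StudyResult, seeds: Sequence[int] = (0, 1, 2, 3, 4)
) -> dict[str, float]:
    """Side-by-side MADs: clean, in-envelope distortion, out-of-envelope.

    The out-of-envelope configuration (brightness delta 75, contrast
    0.5-2.1) strictly exceeds the training envelope (63, 0.2-1.8) on the
    bright/high-contrast side; distorted MADs are averaged over distortion
    seeds.  A model robust to scene lighting keeps all three close.
    """
    clean = result.report.mean_abs_diff
    in_env = AugmentationConfig(
        brightness_max_delta=63.0, contrast_lower=0.2, contrast_upper=1.8,
        crop_fraction=0.0, horizontal_flip=False, vertical_flip=False,
    )
    out_env = robustness_config()
    in_mads, out_mads = [], []
    for s in seeds:
        in_mads.append(
            robustness_eval(result.net, result.split.test, in_env, seed=s,
                            label_scale=result.label_scale).mean_abs_diff
        )
        out_mads.append(
            robustness_eval(result.net, result.split.test, out_env, seed=s,
                            label_scale=result.label_scale).mean_abs_diff
        )
    return {
        "clean_mad": float(clean),
        "in_envelope_mad": float(np.mean(in_mads)),
        "out_of_envelope_mad": float(np.mean(out_mads)),
    }
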