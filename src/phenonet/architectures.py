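"""The five canonical phenotyping architectures as constructors.

One constructor per architecture-table column: three leaf-counting
regressors (A1 for single-accession Arabidopsis, A2 for multi-accession
Arabidopsis, A3 for tobacco), a five-class mutant classifier and an age
regressor.  Filter counts per convolutional layer are not fixed by the
published table; the default schedule (32, 64, 64, ...) is era-typical
capacity for datasets of ~100-200 images and is configurable per layer.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .errors import ConfigurationError
from .nn import ArchitectureSpec, conv, dropout, fully_connected, output, pool

TASK_IDS = ("A1", "A2", "A3", "mutant", "age")

_DEFAULT_FILTERS = (32, 64, 64, 64, 64, 64)


def _conv_stack(kernels: Sequence[int], filters: Sequence[int], activation: str):
    layers = []
    for k, f in zip(kernels, filters):
        layers.append(conv(k, f, activation))
        layers.append(pool(3, 2))
    return layers


def canonical_spec(
    task_id: str,
    filters: Optional[Sequence[int]] = None,
    compact_classifier: bool = False,
) -> ArchitectureSpec:
    """Build one of the five canonical architectures.

    ``filters`` overrides the per-conv-layer filter schedule (a shorter
    sequence is cycled).  ``compact_classifier`` switches the mutant
    classifier from three fully connected 4096-unit layers (the tabulated
    stack) to the two-layer variant described in prose.
    """
    if task_id not in TASK_IDS:
        raise ConfigurationError(f"unknown architecture id {task_id!r}; expected one of {TASK_IDS}")

    def sched(n: int) -> list[int]:
        base = list(filters) if filters is not None else list(_DEFAULT_FILTERS)
        return [base[i % len(base)] for i in range(n)]

    if task_id == "A2":
        layers = _conv_stack([5, 5, 3, 3, 3], sched(5), "tanh") + [output(1)]
        return ArchitectureSpec(
            name="A2", input_size=(128, 128), layers=tuple(layers),
            task="regression", outputs=1, crop_fraction=0.25,
        )
    if task_id in ("A1", "A3"):
        layers = _conv_stack([5, 5, 3, 3, 3, 3], sched(6), "tanh")
        if task_id == "A1":
            layers.append(fully_connected(1024, "tanh"))
        layers.append(output(1))
        return ArchitectureSpec(
            name=task_id, input_size=(256, 256), layers=tuple(layers),
            task="regression", outputs=1, crop_fraction=0.10,
        )
    if task_id == "mutant":
        layers = _conv_stack([5, 5, 5, 5], sched(4), "relu")
        n_fc = 2 if compact_classifier else 3
        for i in range(n_fc):
            layers.append(fully_connected(4096, "relu"))
            if i < 2:  # the tabulated stack carries two DropOut layers
                layers.append(dropout(0.5))
        layers.append(output(5))
        return ArchitectureSpec(
            name="mutant", input_size=(128, 128), layers=tuple(layers),
            task="classification", outputs=5, crop_fraction=0.25,
        )
    # age regression
    layers = _conv_stack([3, 3], sched(2), "relu") + [fully_connected(2048, "relu"), output(1)]
    return ArchitectureSpec(
        name="age", input_size=(128, 128), layers=tuple(layers),
        task="regression", outputs=1, crop_fraction=0.25,
    )
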