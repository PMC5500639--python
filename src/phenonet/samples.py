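"""The labelled-image container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: admissible label kinds; exactly one per dataset
LABEL_KINDS = ("count", "class", "age", "box")


@dataclass
class ImageSample:
    """One RGB image plus its phenotype label.

    ``image`` is a height x width x 3 array on the 0-255 scale (uint8 as
    loaded; float32 after augmentation).  ``label`` is a leaf count (float),
    a class index (int), an age in hours (float) or a pixel bounding box
    ``(x_min, y_min, x_max, y_max)`` with 0-based, min-inclusive /
    max-exclusive coordinates.  ``phenotype`` carries full synthetic ground
    truth when the sample was rendered rather than loaded.
    """

    image: np.ndarray
    label: Any
    label_kind: str
    id: str
    phenotype: Any = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"unknown label kind {self.label_kind!r}; expected one of {LABEL_KINDS}")
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got shape {img.shape}")
        if img.shape[0] < 1 or img.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if self.label_kind == "box":
            x0, y0, x1, y1 = self.label
            h, w = img.shape[:2]
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(
                    f"box ({x0}, {y0}, {x1}, {y1}) invalid for a {w}x{h} image: "
                    "need x_min < x_max, y_min < y_max within bounds"
                )

    def with_image(self, image: np.ndarray) -> "ImageSample":
        """Copy of this sample with a new pixel array and untouched label."""
        return replace(self, image=image)
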