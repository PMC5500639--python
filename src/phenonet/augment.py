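"""Training-time image distortions: brightness, contrast, crop, flip.

The training envelope (brightness delta 63, contrast factors 0.2-1.8) and
the deliberately wider robustness-test envelope (delta 75, contrast
0.5-2.1) are exposed as ready-made configurations.  All photometric
outputs are clipped back to the 0-255 scale; standardization happens
afterwards, at pipeline time.

Composition order is brightness, contrast, crop, flip — photometric before
geometric.  Crop fractions are linear: a fraction f removes f of each side
length, so 25% of 128 leaves a 96-pixel crop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .samples import ImageSample


@dataclass(frozen=True)
class AugmentationConfig:
    brightness_max_delta: float = 63.0
    contrast_lower: float = 0.2
    contrast_upper: float = 1.8
    crop_fraction: float = 0.25
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def __post_init__(self) -> None:
        if self.brightness_max_delta < 0:
            raise ConfigurationError("brightness_max_delta must be >= 0")
        if self.contrast_lower <= 0:
            raise ConfigurationError("contrast_lower must be > 0")
        if self.contrast_upper < self.contrast_lower:
            raise ConfigurationError("contrast_upper must be >= contrast_lower")
        if not 0.0 <= self.crop_fraction < 1.0:
            raise ConfigurationError("crop_fraction must be in [0, 1)")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """A configuration under which ``augment`` is an exact no-op."""
        return cls(
            brightness_max_delta=0.0,
            contrast_lower=1.0,
            contrast_upper=1.0,
            crop_fraction=0.0,
            horizontal_flip=False,
            vertical_flip=False,
        )


def training_config() -> AugmentationConfig:
    """The default training envelope."""
    return AugmentationConfig()


def robustness_config() -> AugmentationConfig:
    """Out-of-envelope distortions for the lighting-robustness test.

    Photometric only: the robustness protocol perturbs brightness and
    contrast of test images, then follows the ordinary center-crop path.
    """
    return AugmentationConfig(
        brightness_max_delta=75.0,
        contrast_lower=0.5,
        contrast_upper=2.1,
        crop_fraction=0.0,
        horizontal_flip=False,
        vertical_flip=False,
    )


def crop_size(size: int, fraction: float) -> int:
    """Side length after removing a linear ``fraction``: floor(size*(1-f))."""
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError(f"crop fraction must be in [0, 1), got {fraction}")
    return int(np.floor(size * (1.0 - fraction)))


def random_brightness(
    image: np.ndarray, max_delta: float, rng: np.random.Generator
) -> np.ndarray:
    """Add one Uniform(-max_delta, +max_delta) offset to every pixel."""
    if max_delta < 0:
        raise ConfigurationError(f"max_delta must be >= 0, got {max_delta}")
    delta = rng.uniform(-max_delta, max_delta)
    return np.clip(np.asarray(image, dtype=np.float32) + np.float32(delta), 0.0, 255.0)


def random_contrast(
    image: np.ndarray, lower: float, upper: float, rng: np.random.Generator
) -> np.ndarray:
    """Scale each channel about its own mean by one Uniform(lower, upper) factor."""
    if lower <= 0:
        raise ConfigurationError(f"contrast lower bound must be > 0, got {lower}")
    if upper < lower:
        raise ConfigurationError("contrast upper bound must be >= lower bound")
    factor = np.float32(rng.uniform(lower, upper))
    x = np.asarray(image, dtype=np.float32)
    if factor == 1.0:  # exact identity; avoids float round-trip through the mean
        return np.clip(x, 0.0, 255.0)
    mean = x.mean(axis=(0, 1), keepdims=True)
    return np.clip((x - mean) * factor + mean, 0.0, 255.0)


def _check_crop(h: int, w: int, out_h: int, out_w: int) -> None:
    if out_h < 1 or out_w < 1:
        raise ConfigurationError(f"crop size must be positive, got {out_h}x{out_w}")
    if out_h > h or out_w > w:
        raise ConfigurationError(f"crop {out_h}x{out_w} larger than image {h}x{w}")


def random_crop(
    image: np.ndarray, out_h: int, out_w: int, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous out_h x out_w window at a uniformly random valid offset."""
    x = np.asarray(image)
    h, w = x.shape[:2]
    _check_crop(h, w, out_h, out_w)
    i = int(rng.integers(0, h - out_h + 1))
    j = int(rng.integers(0, w - out_w + 1))
    return x[i : i + out_h, j : j + out_w]


def center_crop(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Deterministic central window: offset floor((in - out)/2) per axis."""
    x = np.asarray(image)
    h, w = x.shape[:2]
    _check_crop(h, w, out_h, out_w)
    i = (h - out_h) // 2
    j = (w - out_w) // 2
    return x[i : i + out_h, j : j + out_w]


def random_flip(
    image: np.ndarray, horizontal: bool, vertical: bool, rng: np.random.Generator
) -> np.ndarray:
    """Mirror each enabled axis independently with probability 1/2."""
    x = np.asarray(image)
    if horizontal and rng.random() < 0.5:
        x = x[:, ::-1]
    if vertical and rng.random() < 0.5:
        x = x[::-1, :]
    return np.ascontiguousarray(x)


def augment(
    sample: ImageSample, config: AugmentationConfig, rng: np.random.Generator
) -> ImageSample:
    """Apply brightness -> contrast -> crop -> flip; the label never changes."""
    x = np.asarray(sample.image, dtype=np.float32)
    x = random_brightness(x, config.brightness_max_delta, rng)
    x = random_contrast(x, config.contrast_lower, config.contrast_upper, rng)
    h, w = x.shape[:2]
    x = random_crop(x, crop_size(h, config.crop_fraction), crop_size(w, config.crop_fraction), rng)
    x = random_flip(x, config.horizontal_flip, config.vertical_flip, rng)
    return sample.with_image(x)
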