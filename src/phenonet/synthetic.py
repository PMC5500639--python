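"""Procedural top-down rosette renderer with exact ground truth.

The generator emulates the structure of individual-plant rosette benchmarks:
a single plant centred on a soil-like background, leaves placed at
successive multiples of the golden phyllotaxis angle (~137.5 degrees), leaf
size increasing with plant age, and leaf outline shape determined by a
morphology class.  Every label (leaf count, age in hours, class) is known by
construction, so counting, classification and age-regression pipelines can
be exercised end to end without any external download.

Leaves are filled serrated-ellipse polygons on short petiole segments.
Petioles are rendered brown (red channel >= green) so that the
green-dominant mask — pixels where G is strictly the largest channel —
contains leaf blades only; connected components of that mask are an exact
counting oracle whenever blades do not overlap.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .errors import CapacityError, ConfigurationError
from .samples import ImageSample

ARABIDOPSIS_COUNT_RANGE = (5, 20)
TOBACCO_COUNT_RANGE = (2, 13)
AGE_RANGE_HOURS = (392.0, 620.0)
GOLDEN_ANGLE_DEG = 137.5

ACCESSION_STYLES = ("arabidopsis_like", "tobacco_like")
TASKS = ("count", "class", "age")

#: stable class names; lexicographic order == index order by construction
CLASS_NAMES = ("mutant_a", "mutant_b", "mutant_c", "mutant_d", "mutant_e")

# per-class offsets applied to (blade aspect ratio, petiole fraction,
# serration depth), scaled by RenderConfig.class_margin; at margin 0 all
# classes collapse onto the base morphology and render identically
_BASE_ASPECT = 0.46
_BASE_PETIOLE = 0.30
_CLASS_OFFSETS = (
    (0.00, 0.00, 0.00),
    (-0.18, 0.00, 0.00),
    (0.22, -0.08, 0.00),
    (0.00, 0.14, 0.20),
    (-0.08, 0.06, 0.38),
)


@dataclass(frozen=True)
class RosettePhenotype:
    """Ground-truth description of one plant."""

    leaf_count: int
    age_hours: float
    class_index: int = 0
    accession_style: str = "arabidopsis_like"

    def __post_init__(self) -> None:
        if self.leaf_count < 1:
            raise ConfigurationError(f"leaf_count must be >= 1, got {self.leaf_count}")
        if self.class_index < 0:
            raise ConfigurationError(f"class_index must be >= 0, got {self.class_index}")
        if self.accession_style not in ACCESSION_STYLES:
            raise ConfigurationError(
                f"unknown accession style {self.accession_style!r}; expected one of {ACCESSION_STYLES}"
            )


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters.

    ``leaf_length_px`` is the (min, max) leaf length in pixels reached at
    the youngest / oldest age of the default age range; ``None`` scales the
    default range with the image size.  ``class_margin`` scales the
    inter-class morphology offsets; 0 makes all classes identical.
    """

    image_size: int = 64
    background_style: str = "soil_texture"
    leaf_length_px: Optional[tuple[float, float]] = None
    phyllotaxis_angle_deg: float = GOLDEN_ANGLE_DEG
    noise_sd: float = 3.0
    class_margin: float = 1.0
    n_classes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_style not in ("plain", "soil_texture"):
            raise ConfigurationError(
                f"unknown background style {self.background_style!r}; expected 'plain' or 'soil_texture'"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 1 <= self.n_classes <= len(CLASS_NAMES):
            raise ConfigurationError(f"n_classes must be in [1, {len(CLASS_NAMES)}]")

    def leaf_length_range(self) -> tuple[float, float]:
        if self.leaf_length_px is not None:
            lo, hi = self.leaf_length_px
        else:
            lo, hi = 0.17 * self.image_size, 0.28 * self.image_size
        if not 0 < lo <= hi:
            raise ConfigurationError(f"invalid leaf length range ({lo}, {hi})")
        return float(lo), float(hi)


def _class_params(class_index: int, margin: float) -> tuple[float, float, float]:
    da, dp, ds = _CLASS_OFFSETS[class_index % len(_CLASS_OFFSETS)]
    aspect = float(np.clip(_BASE_ASPECT + margin * da, 0.15, 0.85))
    petiole = float(np.clip(_BASE_PETIOLE + margin * dp, 0.12, 0.55))
    serration = float(np.clip(margin * ds, 0.0, 0.6))
    return aspect, petiole, serration


def _mature_leaf_length(age_hours: float, config: RenderConfig) -> float:
    lo, hi = config.leaf_length_range()
    a0, a1 = AGE_RANGE_HOURS
    age01 = float(np.clip((age_hours - a0) / (a1 - a0), 0.0, 1.0))
    return lo + (hi - lo) * age01


def _blade_polygon(a: float, b: float, serration: float, n_points: int = 48) -> np.ndarray:
    """Leaf blade outline in local coordinates (radial axis = +x)."""
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    # serration carves 9 shallow teeth into the margin; depth 0 -> ellipse
    notch = 1.0 - 0.5 * serration * (1.0 + np.cos(9.0 * t))
    x = a * np.cos(t) * notch
    y = b * np.sin(t) * notch
    return np.stack([x, y], axis=1)


def _background(config: RenderConfig, rng: np.random.Generator) -> np.ndarray:
    size = config.image_size
    base = np.array([112.0, 86.0, 62.0], dtype=np.float32)  # soil brown, R > G
    canvas = np.broadcast_to(base, (size, size, 3)).copy()
    if config.background_style == "soil_texture":
        coarse = rng.normal(0.0, 14.0, size=(8, 8, 3)).astype(np.float32)
        patch = np.stack(
            [
                np.asarray(
                    Image.fromarray(coarse[:, :, c], mode="F").resize((size, size), Image.BILINEAR)
                )
                for c in range(3)
            ],
            axis=2,
        )
        speckle = rng.normal(0.0, 6.0, size=(size, size, 1)).astype(np.float32)
        canvas += patch + speckle
        # keep the background out of the green-dominant mask
        canvas[:, :, 1] = np.minimum(canvas[:, :, 1], canvas[:, :, 0] - 2.0)
    return np.clip(canvas, 0.0, 255.0)


def render_rosette(
    phenotype: RosettePhenotype,
    config: RenderConfig,
    rng: Optional[np.random.Generator] = None,
) -> ImageSample:
    """Render one rosette; deterministic in (phenotype, config, seed).

    Raises :class:`CapacityError` when the leaf count cannot be placed at
    the minimum leaf size within the frame.
    """
    size = config.image_size
    if size < 32:
        raise ConfigurationError(f"image_size must be >= 32, got {size}")
    lo_len, hi_len = config.leaf_length_range()
    # outermost blade tip reaches 1.5x the leaf length (petiole + blade +
    # radial spread), plus up to 15% length jitter
    if 1.75 * hi_len > size / 2:
        raise CapacityError(
            f"leaf length up to {hi_len:.1f}px does not fit a {size}px frame"
        )
    # angular capacity of the rosette ring at the minimum leaf size
    capacity = int(math.pi * lo_len)
    if phenotype.leaf_count > max(capacity, 3):
        raise CapacityError(
            f"cannot place {phenotype.leaf_count} leaves at minimum leaf size "
            f"{lo_len:.1f}px in a {size}px frame (capacity ~{max(capacity, 3)})"
        )

    if rng is None:
        rng = np.random.default_rng(config.seed)

    canvas = _background(config, rng)
    img = Image.fromarray(canvas.astype(np.uint8))
    draw = ImageDraw.Draw(img)
    cx = cy = size / 2.0

    aspect, petiole_frac, serration = _class_params(phenotype.class_index, config.class_margin)
    length = _mature_leaf_length(phenotype.age_hours, config)
    count = phenotype.leaf_count

    leaves = []
    for i in range(count):
        # leaf 0 is the oldest (largest, outermost); younger leaves shrink
        # and sit closer to the center, so the rosette forms a spiral of
        # rings and angularly close leaves land at different radii
        scale = 1.0 if count == 1 else 1.0 - 0.45 * (i / (count - 1))
        jitter = float(np.clip(1.0 + 0.06 * rng.standard_normal(), 0.85, 1.15))
        li = length * scale * jitter
        spread = 0.5 * length * ((scale - 0.55) / 0.45 if count > 1 else 1.0)
        angle = math.radians(i * config.phyllotaxis_angle_deg + rng.uniform(-4.0, 4.0))
        g = 118 + int(rng.integers(-12, 13))
        r = 42 + int(rng.integers(-10, 11))
        b = 34 + int(rng.integers(-10, 11))
        g = max(g, max(r, b) + 25)  # G strictly dominant on the blade
        leaves.append((li, spread, angle, (r, g, b)))

    petiole_width = max(1, round(size / 48))
    for li, spread, angle, _ in leaves:
        p_len = petiole_frac * li + spread
        x0 = cx + 1.0 * math.cos(angle)
        y0 = cy + 1.0 * math.sin(angle)
        x1 = cx + p_len * math.cos(angle)
        y1 = cy + p_len * math.sin(angle)
        draw.line([(x0, y0), (x1, y1)], fill=(96, 88, 54), width=petiole_width)

    for li, spread, angle, color in leaves:
        p_len = petiole_frac * li + spread
        blade_len = (1.0 - petiole_frac) * li
        a = blade_len / 2.0
        b_half = aspect * a
        local = _blade_polygon(a, b_half, serration)
        d = p_len + a
        ca, sa = math.cos(angle), math.sin(angle)
        xs = cx + (d + local[:, 0]) * ca - local[:, 1] * sa
        ys = cy + (d + local[:, 0]) * sa + local[:, 1] * ca
        draw.polygon(list(zip(xs.tolist(), ys.tolist())), fill=color)

    out = np.asarray(img, dtype=np.float32)
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=out.shape).astype(np.float32)
    out = np.clip(out, 0.0, 255.0).astype(np.uint8)

    return ImageSample(
        image=out,
        label=float(phenotype.leaf_count),
        label_kind="count",
        id="rosette",
        phenotype=phenotype,
    )


def green_dominant_mask(image: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels whose green channel strictly dominates."""
    img = np.asarray(image, dtype=np.int32)
    return (img[:, :, 1] > img[:, :, 0]) & (img[:, :, 1] > img[:, :, 2])


def _correlated_ages(
    counts: np.ndarray, count_range: tuple[int, int], correlation: float, rng: np.random.Generator
) -> np.ndarray:
    """Ages positively correlated with counts (plants gain leaves with age).

    A mixing weight w is chosen so that the linear correlation between the
    normalized count and the age is ``correlation`` exactly when both mixed
    terms share the same variance; counts being discrete makes the realized
    correlation approximate.
    """
    if not 0.0 <= correlation < 1.0:
        raise ConfigurationError("age/count correlation must be in [0, 1)")
    lo, hi = count_range
    c01 = (counts - lo) / max(hi - lo, 1)
    w = correlation / (correlation + math.sqrt(1.0 - correlation**2)) if correlation > 0 else 0.0
    age01 = w * c01 + (1.0 - w) * rng.uniform(0.0, 1.0, size=counts.shape)
    a0, a1 = AGE_RANGE_HOURS
    return a0 + (a1 - a0) * np.clip(age01, 0.0, 1.0)


def generate_dataset(
    n: int,
    task: str,
    style: str,
    config: RenderConfig,
    seed: int,
    age_count_correlation: float = 0.6,
) -> list[ImageSample]:
    """Generate ``n`` labelled rosette samples for one task.

    Counts are drawn balanced over the style's admissible range (each value
    appears floor(n/span) or ceil(n/span) times, shuffled), which guarantees
    wide label coverage at moderate n; ages are drawn conditionally on the
    count with positive correlation; classes are uniform.  The whole dataset
    is a pure function of (n, task, style, config, seed).
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}; expected one of {TASKS}")
    if style not in ACCESSION_STYLES:
        raise ConfigurationError(f"unknown style {style!r}; expected one of {ACCESSION_STYLES}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0F]))
    lo, hi = ARABIDOPSIS_COUNT_RANGE if style == "arabidopsis_like" else TOBACCO_COUNT_RANGE
    values = np.arange(lo, hi + 1)
    if n >= len(values):
        reps = int(np.ceil(n / len(values)))
        counts = rng.permuted(np.tile(values, reps))[:n]
    else:
        counts = rng.choice(values, size=n, replace=False)
    ages = _correlated_ages(counts, (lo, hi), age_count_correlation, rng)
    classes = rng.integers(0, config.n_classes, size=n)

    children = np.random.SeedSequence([seed, 0xA5]).spawn(n)
    samples: list[ImageSample] = []
    for i in range(n):
        phen = RosettePhenotype(
            leaf_count=int(counts[i]),
            age_hours=float(ages[i]),
            class_index=int(classes[i]),
            accession_style=style,
        )
        sample = render_rosette(phen, config, rng=np.random.default_rng(children[i]))
        if task == "count":
            label: object = float(phen.leaf_count)
        elif task == "class":
            label = int(phen.class_index)
        else:
            label = float(phen.age_hours)
        samples.append(
            dataclasses.replace(sample, id=f"plant_{i:04d}", label=label, label_kind=task)
        )
    return samples


def save_dataset(samples: Sequence[ImageSample], out_dir: str | Path) -> Path:
    """Persist samples in an IPPN-style folder layout.

    Writes ``<id>_rgb.png`` per sample plus ``Leaf_counts.csv``,
    ``Ages.csv`` and ``Classes.csv`` (``filename,value`` rows, no header),
    readable by :func:`phenonet.io.load_ippn_dataset` unchanged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    count_rows, age_rows, class_rows = [], [], []
    for sample in samples:
        fname = f"{sample.id}_rgb.png"
        Image.fromarray(np.asarray(sample.image, dtype=np.uint8)).save(out / fname)
        phen = sample.phenotype
        if phen is not None:
            count_rows.append(f"{fname},{phen.leaf_count}")
            age_rows.append(f"{fname},{phen.age_hours:.1f}")
            class_rows.append(f"{fname},{CLASS_NAMES[phen.class_index]}")
    if count_rows:
        (out / "Leaf_counts.csv").write_text("\n".join(count_rows) + "\n")
        (out / "Ages.csv").write_text("\n".join(age_rows) + "\n")
        (out / "Classes.csv").write_text("\n".join(class_rows) + "\n")
    return out
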