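"""Dataset loading, per-image standardization and train/test splitting.

Supports the IPPN-style individual-plant layout (one PNG/JPEG per plant
plus a ``filename,value`` CSV of leaf counts, ages or class names), Pascal
VOC XML bounding-box annotations, and reproducible seeded splits.  Images
are kept at native resolution here; resizing to a network's input size
happens at pipeline time so one dataset can feed several architectures.
"""

from __future__ import annotations

import csv
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import ConfigurationError, DataError
from .samples import ImageSample


def _read_rgb(path: Path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


def resize_image(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize to (height, width); no-op when already that size."""
    arr = np.asarray(image)
    if arr.shape[:2] == (height, width):
        return arr
    pil = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))
    return np.asarray(pil.resize((width, height), Image.BILINEAR), dtype=np.uint8)


def _looks_like_header(row: Sequence[str]) -> bool:
    return len(row) >= 1 and row[0].strip().lower() in ("filename", "file", "image", "name")


def load_ippn_dataset(image_dir: str | Path, label_csv: str | Path, task: str) -> list[ImageSample]:
    """Load an IPPN-style folder: images plus a ``filename,value`` CSV.

    ``task`` selects the label kind: ``count`` and ``age`` parse the value
    as a real number; ``class`` maps class names to indices in stable
    lexicographic order.  A header row is detected and skipped.
    """
    if task not in ("count", "class", "age"):
        raise ConfigurationError(f"unknown task {task!r}; expected 'count', 'class' or 'age'")
    image_dir = Path(image_dir)
    label_csv = Path(label_csv)
    if not label_csv.exists():
        raise DataError(f"label CSV not found: {label_csv}")

    with open(label_csv, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(cell.strip() for cell in row)]
    if rows and _looks_like_header(rows[0]):
        rows = rows[1:]
    if not rows:
        return []

    parsed: list[tuple[str, str]] = []
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise DataError(f"{label_csv.name} row {i}: expected 'filename,value', got {row!r}")
        parsed.append((row[0].strip(), row[1].strip()))

    if task == "class":
        class_names = sorted({value for _, value in parsed})
        class_to_index = {name: idx for idx, name in enumerate(class_names)}

    samples: list[ImageSample] = []
    for i, (fname, value) in enumerate(parsed):
        path = image_dir / fname
        if not path.exists():
            raise DataError(f"image file listed in {label_csv.name} is missing: {fname}")
        if task == "class":
            label: object = class_to_index[value]
        else:
            try:
                label = float(value)
            except ValueError as exc:
                raise DataError(
                    f"{label_csv.name} row {i}: non-numeric {task} label {value!r}"
                ) from exc
        samples.append(
            ImageSample(image=_read_rgb(path), label=label, label_kind=task, id=Path(fname).stem)
        )
    return samples


def load_voc_boxes(annotation_dir: str | Path, image_dir: str | Path) -> list[ImageSample]:
    """Load Pascal VOC XML annotations, one sample per file.

    VOC boxes are 1-based and max-inclusive; they are converted to the
    internal 0-based, min-inclusive / max-exclusive pixel convention.
    Files with several objects keep the first and emit a warning.
    """
    annotation_dir = Path(annotation_dir)
    image_dir = Path(image_dir)
    samples: list[ImageSample] = []
    for xml_path in sorted(annotation_dir.glob("*.xml")):
        try:
            root = ET.parse(xml_path).getroot()
        except ET.ParseError as exc:
            raise DataError(f"malformed VOC XML {xml_path.name}: {exc}") from exc
        fname = root.findtext("filename")
        if not fname:
            raise DataError(f"VOC XML {xml_path.name} has no <filename> element")
        objects = root.findall("object")
        if not objects:
            raise DataError(f"VOC XML {xml_path.name} contains no <object>")
        if len(objects) > 1:
            warnings.warn(
                f"{xml_path.name}: {len(objects)} objects annotated, keeping the first",
                stacklevel=2,
            )
        bnd = objects[0].find("bndbox")
        if bnd is None:
            raise DataError(f"VOC XML {xml_path.name}: first object has no <bndbox>")
        try:
            xmin = int(float(bnd.findtext("xmin")))
            ymin = int(float(bnd.findtext("ymin")))
            xmax = int(float(bnd.findtext("xmax")))
            ymax = int(float(bnd.findtext("ymax")))
        except (TypeError, ValueError) as exc:
            raise DataError(f"VOC XML {xml_path.name}: non-numeric bndbox") from exc
        if xmin >= xmax or ymin >= ymax:
            raise DataError(
                f"VOC XML {xml_path.name}: degenerate box ({xmin}, {ymin}, {xmax}, {ymax})"
            )
        path = image_dir / fname
        if not path.exists():
            raise DataError(f"image referenced by {xml_path.name} is missing: {fname}")
        image = _read_rgb(path)
        # VOC 1-based inclusive -> 0-based min-inclusive/max-exclusive
        box = (xmin - 1, ymin - 1, xmax, ymax)
        samples.append(
            ImageSample(image=image, label=box, label_kind="box", id=xml_path.stem)
        )
    return samples


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Subtract the image's own mean and divide by its standard deviation.

    The divisor is floored at ``1/sqrt(n_elements)`` so constant images map
    to zeros instead of dividing by zero; the moments are taken jointly
    over all pixels and channels.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.size == 0:
        raise ConfigurationError("cannot standardize an empty image")
    mu = x.mean()
    sd = x.std()
    floor = 1.0 / np.sqrt(x.size)
    return (x - mu) / max(sd, floor)


@dataclass
class DatasetSplit:
    """A seeded train/test partition of one dataset."""

    train: list[ImageSample]
    test: list[ImageSample]
    seed: int
    train_fraction: float


def split_train_test(
    samples: Sequence[ImageSample], train_fraction: float, seed: int
) -> DatasetSplit:
    """Uniformly random split; first floor(fraction * N) of a seeded
    permutation go to train.  Deterministic under a fixed seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(samples)
    if n < 2:
        raise ConfigurationError(f"need at least 2 samples to split, got {n}")
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1:
        raise ConfigurationError(
            f"train_fraction {train_fraction} of {n} samples leaves an empty train set"
        )
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return DatasetSplit(train=train, test=test, seed=seed, train_fraction=train_fraction)
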