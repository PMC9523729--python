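"""Reading and writing images, YOLO-darknet labels, and dataset manifests.

Coordinate convention: 0-based, origin at the top-left corner, x rightward,
y downward.  A box spans the half-open pixel ranges
``[x_min, x_min + width) x [y_min, y_min + height)``.  Normalized YOLO
centers are converted to pixels with round-half-up and clipped to the image.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image


class LabelParseError(ValueError):
    """A YOLO label line could not be parsed."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BoundingBox:
    """One labeled object location in pixel coordinates.

    Attributes
    ----------
    class_id : int
        Non-negative class index into the dataset's class-name list.
    x_min, y_min : int
        Top-left corner, 0-based pixels.
    width, height : int
        Box extent; both strictly positive.
    """

    class_id: int
    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"negative class_id {self.class_id}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box extent must be positive, got {self.width}x{self.height}"
            )

    @property
    def x_max(self) -> int:
        """Exclusive right edge."""
        return self.x_min + self.width

    @property
    def y_max(self) -> int:
        """Exclusive bottom edge."""
        return self.y_min + self.height

    @property
    def area(self) -> int:
        return self.width * self.height

    def fits_in(self, image_width: int, image_height: int) -> bool:
        return (
            self.x_min >= 0
            and self.y_min >= 0
            and self.x_max <= image_width
            and self.y_max <= image_height
        )


@dataclass
class LabeledImage:
    """An image with its bounding boxes.

    ``pixels`` may be held in memory or backed by a file path; path-backed
    images are loaded on access so large augmented datasets can be streamed
    to disk without keeping every raster resident.
    """

    image_id: str
    boxes: list[BoundingBox] = field(default_factory=list)
    _pixels: np.ndarray | None = None
    path: Path | None = None

    @property
    def pixels(self) -> np.ndarray:
        if self._pixels is not None:
            return self._pixels
        if self.path is None:
            raise ValueError(f"image {self.image_id!r} has no pixels or path")
        return read_image(self.path)

    @pixels.setter
    def pixels(self, value: np.ndarray) -> None:
        self._pixels = value

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        if self._pixels is not None:
            return self._pixels.shape[:2]
        with Image.open(self.path) as im:
            return im.height, im.width

    def validate(self) -> None:
        h, w = self.shape
        for box in self.boxes:
            if not box.fits_in(w, h):
                raise ValueError(
                    f"box {box} outside {w}x{h} image {self.image_id!r}"
                )


@dataclass
class DatasetManifest:
    """A labeled dataset: images plus class names, with object bookkeeping.

    ``n_images`` and ``n_objects`` are recomputed from the contents, so the
    count invariants (n_images == len(images), n_objects == total boxes)
    hold by construction.
    """

    role: str
    images: list[LabeledImage] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    _ROLES = ("train", "valid", "test")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def n_objects(self) -> int:
        return sum(len(img.boxes) for img in self.images)

    def __iter__(self) -> Iterator[LabeledImage]:
        return iter(self.images)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG as an 8-bit H x W x 3 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected HxWx3 raster, got shape {pixels.shape}")
    Image.fromarray(np.ascontiguousarray(pixels, dtype=np.uint8)).save(path)


def read_yolo_labels(
    label_text: str, image_width: int, image_height: int
) -> list[BoundingBox]:
    """Parse YOLO-darknet label text into pixel-space boxes.

    Each non-empty line is ``class cx cy w h`` with the last four fields
    normalized to [0, 1].  Pixel corners use round-half-up; boxes that
    overshoot the image by rounding are clipped, with a minimum extent of
    one pixel.
    """
    boxes: list[BoundingBox] = []
    for lineno, raw in enumerate(label_text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise LabelParseError(
                f"line {lineno}: expected 5 fields, got {len(fields)}"
            )
        try:
            class_id = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise LabelParseError(f"line {lineno}: non-numeric field") from exc
        if class_id < 0:
            raise LabelParseError(f"line {lineno}: negative class id {class_id}")
        for name, value in zip("cx cy w h".split(), (cx, cy, w, h)):
            if not 0.0 <= value <= 1.0:
                raise LabelParseError(
                    f"line {lineno}: {name}={value} outside [0, 1]"
                )
        x_min = _round_half_up((cx - w / 2) * image_width)
        y_min = _round_half_up((cy - h / 2) * image_height)
        bw = _round_half_up(w * image_width)
        bh = _round_half_up(h * image_height)
        # clip rounding overshoot; degenerate rounding keeps one pixel
        x_min = min(max(x_min, 0), image_width - 1)
        y_min = min(max(y_min, 0), image_height - 1)
        bw = max(1, min(bw, image_width - x_min))
        bh = max(1, min(bh, image_height - y_min))
        boxes.append(BoundingBox(class_id, x_min, y_min, bw, bh))
    return boxes


def write_yolo_labels(
    boxes: Sequence[BoundingBox], image_width: int, image_height: int
) -> str:
    """Serialize boxes to YOLO-darknet text (normalized, 6 decimal places)."""
    lines = []
    for box in boxes:
        if not box.fits_in(image_width, image_height):
            raise ValueError(
                f"box {box} outside {image_width}x{image_height} image"
            )
        cx = (box.x_min + box.width / 2) / image_width
        cy = (box.y_min + box.height / 2) / image_height
        w = box.width / image_width
        h = box.height / image_height
        lines.append(f"{box.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    return "\n".join(lines)


def write_dataset(manifest: DatasetManifest, directory: str | os.PathLike) -> Path:
    """Write a dataset directory in darknet layout.

    Emits ``images/<id>.png`` with a sibling ``<id>.txt`` label file per
    image, a ``names.txt`` class-name file, and an ``images.txt`` list of
    relative image paths.  ``read_dataset`` is its inverse.
    """
    directory = Path(directory)
    image_dir = directory / "images"
    image_dir.mkdir(parents=True, exist_ok=True)

    list_lines = []
    for img in manifest.images:
        pixels = img.pixels
        h, w = pixels.shape[:2]
        stem = img.image_id
        img_path = image_dir / f"{stem}.png"
        try:
            write_image(img_path, pixels)
            (image_dir / f"{stem}.txt").write_text(
                write_yolo_labels(img.boxes, w, h) + "\n", newline="\n"
            )
        except OSError as exc:
            raise OSError(f"failed writing {img_path}: {exc}") from exc
        list_lines.append(f"images/{stem}.png")

    (directory / "names.txt").write_text(
        "".join(f"{name}\n" for name in manifest.class_names), newline="\n"
    )
    (directory / "images.txt").write_text(
        "".join(f"{p}\n" for p in list_lines), newline="\n"
    )
    (directory / "role.txt").write_text(manifest.role + "\n", newline="\n")
    return directory


def read_dataset(directory: str | os.PathLike, lazy: bool = True) -> DatasetManifest:
    """Read back a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    class_names = directory.joinpath("names.txt").read_text().splitlines()
    role_file = directory / "role.txt"
    role = role_file.read_text().strip() if role_file.exists() else "train"

    images: list[LabeledImage] = []
    for rel in directory.joinpath("images.txt").read_text().splitlines():
        if not rel.strip():
            continue
        img_path = directory / rel
        if not img_path.exists():
            raise FileNotFoundError(f"listed image missing: {img_path}")
        with Image.open(img_path) as im:
            w, h = im.width, im.height
        label_path = img_path.with_suffix(".txt")
        label_text = label_path.read_text() if label_path.exists() else ""
        boxes = read_yolo_labels(label_text, w, h)
        img = LabeledImage(image_id=img_path.stem, boxes=boxes, path=img_path)
        if not lazy:
            img.pixels = read_image(img_path)
        images.append(img)
    return DatasetManifest(role=role, images=images, class_names=class_names)
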