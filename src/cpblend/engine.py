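"""Copy-Paste-Blend core: paste object masks onto backgrounds and augment
whole datasets by an integer factor.

The operator copies an object via its mask, pastes it at a chosen (or
rejection-sampled) location on a background leaf image, blends it with the
background, and appends the tight bounding box of the pasted matte to the
image's annotations.  Augmenting a source set of N_ii images by a factor k
produces exactly k * N_ii images; the object count of the output is
k * N_oi plus the number of successful pastes.

Blend modes
-----------
hard
    out = patch where alpha > 0 else background (binary cut-out).
feathered (default)
    alpha is Gaussian-softened (sigma = ``feather_radius``, kernel truncated
    at 3 sigma) and composited linearly; suppresses the hard paste outline
    that human reviewers flag first.
seamless
    gradient-domain (Poisson) compositing of the patch into the background
    over the matte support; only pixels inside the support are replaced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .annotations import BoundingBox, DatasetManifest, LabeledImage, write_dataset
from .masks import MaskPool, ObjectMask, transform_object_mask

logger = logging.getLogger(__name__)

BlendMode = Literal["hard", "feathered", "seamless"]

#: attempts allowed per rejection-sampled placement before giving up
MAX_PLACEMENT_ATTEMPTS = 100


@dataclass(frozen=True)
class PlacementSpec:
    """One paste: which mask goes where, with what transform and blend."""

    image_id: str
    x: int
    y: int
    mask_id: str = "random"
    scale: float = 1.0
    rotation: float = 0.0
    flip_horizontal: bool = False
    blend_mode: BlendMode = "feathered"


@dataclass
class AugmentationPolicy:
    """Batch augmentation parameters.

    ``factor`` is the dataset multiplication k; each source image yields k
    output images (copy 1 keeps the original content, all copies receive
    fresh pastes).  Per-paste jitter ranges diversify object appearance;
    ``max_overlap_iou`` bounds the IoU a sampled paste box may have with any
    existing or already-sampled box.
    """

    factor: int = 4
    pastes_per_image: tuple[int, int] = (1, 6)
    scale_jitter: tuple[float, float] = (0.7, 1.3)
    rotation_jitter: tuple[float, float] = (-180.0, 180.0)
    flip_probability: float = 0.5
    blend_mode: BlendMode = "feathered"
    feather_radius: float = 1.0
    max_overlap_iou: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError(f"factor must be >= 1, got {self.factor}")
        lo, hi = self.pastes_per_image
        if lo > hi or lo < 0:
            raise ValueError(f"bad pastes_per_image range [{lo}, {hi}]")
        if not 0.0 <= self.max_overlap_iou <= 1.0:
            raise ValueError("max_overlap_iou must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationPolicy":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown policy keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("pastes_per_image", "scale_jitter", "rotation_jitter"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _feathered_alpha(alpha: np.ndarray, radius: float, margin: int) -> np.ndarray:
    """Pad the matte by `margin` and soften with a Gaussian of sigma=radius."""
    padded = np.pad(alpha, margin)
    if radius <= 0:
        return padded
    return ndimage.gaussian_filter(padded, sigma=radius, truncate=3.0)


def _poisson_blend_window(
    bg: np.ndarray, patch: np.ndarray, support: np.ndarray
) -> np.ndarray:
    """Solve the gradient-domain composite over `support` inside a window.

    Dirichlet boundary values come from the background; guidance gradients
    come from the patch.  Only pixels inside the support are modified.
    """
    h, w = support.shape
    idx = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(support)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    if n == 0:
        return bg

    rows, cols, vals = [], [], []
    b = np.zeros((n, 3), dtype=np.float64)
    bgf = bg.astype(np.float64)
    pf = patch.astype(np.float64)
    for k in range(n):
        y, x = ys[k], xs[k]
        deg = 0
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                continue
            deg += 1
            b[k] += pf[y, x] - pf[ny, nx]  # guidance gradient
            if support[ny, nx]:
                rows.append(k)
                cols.append(idx[ny, nx])
                vals.append(-1.0)
            else:
                b[k] += bgf[ny, nx]  # boundary condition
        rows.append(k)
        cols.append(k)
        vals.append(float(deg))

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    out = bg.copy()
    sol = spsolve(A.tocsc(), b)
    sol = np.atleast_2d(sol)
    out[ys, xs] = np.clip(np.rint(sol), 0, 255).astype(np.uint8)
    return out


def paste_object(
    background: LabeledImage,
    mask: ObjectMask,
    placement: PlacementSpec,
    feather_radius: float = 1.0,
) -> tuple[LabeledImage, BoundingBox]:
    """Paste one object and return (new image, its bounding box).

    The input image is not modified.  The emitted box is exactly the tight
    rectangle of the transformed matte placed at ``(placement.x, placement.y)``.
    Background pixels outside the blend neighbourhood are bit-identical to
    the input.
    """
    tmask = transform_object_mask(
        mask,
        scale=placement.scale,
        rotation=placement.rotation,
        flip_horizontal=placement.flip_horizontal,
    )
    if not (tmask.alpha > 0).any():
        raise ValueError("no foreground")
    th, tw = tmask.shape
    pixels = background.pixels
    H, W = pixels.shape[:2]
    x, y = placement.x, placement.y
    if x < 0 or y < 0 or x + tw > W or y + th > H:
        raise ValueError(
            f"placement ({x},{y}) of {tw}x{th} mask outside {W}x{H} image"
        )

    out = pixels.copy()
    mode = placement.blend_mode
    if mode == "hard":
        support = tmask.alpha > 0
        window = out[y : y + th, x : x + tw]
        window[support] = tmask.patch[support]
    elif mode == "feathered":
        margin = int(np.ceil(3.0 * max(feather_radius, 0.0)))
        soft = _feathered_alpha(tmask.alpha, feather_radius, margin)
        y0, x0 = max(0, y - margin), max(0, x - margin)
        y1, x1 = min(H, y + th + margin), min(W, x + tw + margin)
        # crop the soft matte to the in-image part of the padded window
        soft = soft[
            y0 - (y - margin) : soft.shape[0] - ((y + th + margin) - y1),
            x0 - (x - margin) : soft.shape[1] - ((x + tw + margin) - x1),
        ]
        patch_pad = np.pad(
            tmask.patch.astype(np.float64), ((margin, margin), (margin, margin), (0, 0)),
            mode="edge",
        )
        patch_pad = patch_pad[
            y0 - (y - margin) : patch_pad.shape[0] - ((y + th + margin) - y1),
            x0 - (x - margin) : patch_pad.shape[1] - ((x + tw + margin) - x1),
        ]
        window = out[y0:y1, x0:x1].astype(np.float64)
        blended = soft[..., None] * patch_pad + (1.0 - soft[..., None]) * window
        out[y0:y1, x0:x1] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    elif mode == "seamless":
        support = tmask.alpha > 0.5
        if not support.any():
            support = tmask.alpha > 0
        out[y : y + th, x : x + tw] = _poisson_blend_window(
            out[y : y + th, x : x + tw], tmask.patch, support
        )
    else:
        raise ValueError(f"unknown blend mode {mode!r}")

    box = BoundingBox(tmask.class_id, x, y, tw, th)
    new_image = LabeledImage(
        image_id=background.image_id,
        boxes=list(background.boxes) + [box],
        _pixels=out,
    )
    return new_image, box


def _box_iou(a: BoundingBox, b: BoundingBox) -> float:
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def sample_placements(
    background: LabeledImage,
    n: int,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    pool: MaskPool,
) -> list[PlacementSpec]:
    """Rejection-sample up to ``n`` non-overlapping placements.

    Each candidate draws a mask and jitter, transforms it to know its exact
    extent, and proposes a uniform position; the candidate is kept iff its
    box has IoU <= ``policy.max_overlap_iou`` with every existing and
    already-accepted box.  At most 100 attempts per placement; delivering
    fewer than ``n`` is a logged outcome, not an error.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if len(pool) == 0:
        raise ValueError("empty mask pool")
    H, W = background.shape
    accepted: list[PlacementSpec] = []
    blocking: list[BoundingBox] = list(background.boxes)

    for _ in range(n):
        placed = False
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            mask_idx = int(rng.integers(len(pool)))
            mask = pool[mask_idx]
            scale = float(rng.uniform(*policy.scale_jitter))
            rotation = float(rng.uniform(*policy.rotation_jitter))
            flip = bool(rng.random() < policy.flip_probability)
            try:
                tmask = transform_object_mask(
                    mask, scale=scale, rotation=rotation, flip_horizontal=flip
                )
            except ValueError:
                continue
            th, tw = tmask.shape
            if tw > W or th > H:
                continue
            x = int(rng.integers(0, W - tw + 1))
            y = int(rng.integers(0, H - th + 1))
            cand = BoundingBox(tmask.class_id, x, y, tw, th)
            if any(_box_iou(cand, other) > policy.max_overlap_iou for other in blocking):
                continue
            mask_id = mask.source_id or f"#{mask_idx}"
            accepted.append(
                PlacementSpec(
                    image_id=background.image_id,
                    x=x,
                    y=y,
                    mask_id=mask_id,
                    scale=scale,
                    rotation=rotation,
                    flip_horizontal=flip,
                    blend_mode=policy.blend_mode,
                )
            )
            blocking.append(cand)
            placed = True
            break
        if not placed:
            logger.info(
                "image %s: placement shortfall (%d of %d placed)",
                background.image_id,
                len(accepted),
                n,
            )
            break
    return accepted


def _substream(seed: int, image_id: str, copy_index: int) -> np.random.Generator:
    """Stable per-(image, copy) random stream, independent of iteration order."""
    digest = hashlib.sha256(f"{seed}:{image_id}:{copy_index}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def _resolve_mask(pool: MaskPool, mask_id: str, rng: np.random.Generator) -> ObjectMask:
    if mask_id == "random":
        return pool[int(rng.integers(len(pool)))]
    if mask_id.startswith("#"):
        return pool[int(mask_id[1:])]
    return pool.get(mask_id)


def augment_dataset(
    source: DatasetManifest,
    pool: MaskPool,
    policy: AugmentationPolicy,
    placements: Sequence[PlacementSpec] | None = None,
    out_dir: str | os.PathLike | None = None,
) -> DatasetManifest:
    """Augment a dataset by ``policy.factor``.

    Produces exactly ``factor * n_images`` output images.  Copy 1 of each
    image keeps the original content (plus fresh pastes); copies 2..k are
    independently re-pasted variants.  When ``placements`` is given, those
    explicit pastes are applied to copy 1 of the named images instead of
    sampling.  When ``out_dir`` is set, images are streamed to disk as they
    are produced and the returned manifest is path-backed (memory stays flat
    for large runs); a JSON-lines generation log is written next to them.

    Deterministic: per-image substreams are derived by hashing
    ``(policy.seed, image_id, copy_index)``, so identical inputs and seed
    give byte-identical output datasets.
    """
    if len(pool) == 0:
        raise ValueError("empty mask pool")
    known_classes = len(source.class_names)
    for m in pool.masks:
        if known_classes and m.class_id >= known_classes:
            raise ValueError(
                f"mask {m.source_id!r} class {m.class_id} not in dataset classes"
            )
    explicit: dict[str, list[PlacementSpec]] = {}
    if placements:
        known_ids = {img.image_id for img in source.images}
        for p in placements:
            if p.image_id not in known_ids:
                raise ValueError(f"placement references unknown image {p.image_id!r}")
            if p.mask_id != "random" and not p.mask_id.startswith("#"):
                pool.get(p.mask_id)  # raises KeyError on unknown mask
            explicit.setdefault(p.image_id, []).append(p)

    out_path = Path(out_dir) if out_dir is not None else None
    image_dir = None
    log_records = []
    if out_path is not None:
        image_dir = out_path / "images"
        image_dir.mkdir(parents=True, exist_ok=True)

    out_images: list[LabeledImage] = []
    n_pastes_total = 0
    for src in source.images:
        for copy_index in range(1, policy.factor + 1):
            rng = _substream(policy.seed, src.image_id, copy_index)
            current = LabeledImage(
                image_id=f"{src.image_id}-c{copy_index}",
                boxes=list(src.boxes),
                _pixels=src.pixels.copy(),
            )
            if copy_index == 1 and src.image_id in explicit:
                chosen = explicit[src.image_id]
            else:
                lo, hi = policy.pastes_per_image
                n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
                chosen = sample_placements(src, n, policy, rng, pool)
            realized = []
            for p in chosen:
                mask = _resolve_mask(pool, p.mask_id, rng)
                current, box = paste_object(
                    current, mask, p, feather_radius=policy.feather_radius
                )
                realized.append({"mask": p.mask_id, "x": p.x, "y": p.y})
                n_pastes_total += 1
            if image_dir is not None:
                from .annotations import write_image, write_yolo_labels

                px = current.pixels
                h, w = px.shape[:2]
                fp = image_dir / f"{current.image_id}.png"
                write_image(fp, px)
                (image_dir / f"{current.image_id}.txt").write_text(
                    write_yolo_labels(current.boxes, w, h) + "\n", newline="\n"
                )
                current = LabeledImage(
                    image_id=current.image_id, boxes=current.boxes, path=fp
                )
                log_records.append(
                    {"image": current.image_id, "placements": realized}
                )
            out_images.append(current)

    result = DatasetManifest(
        role=source.role, images=out_images, class_names=list(source.class_names)
    )
    if out_path is not None:
        (out_path / "names.txt").write_text(
            "".join(f"{n}\n" for n in source.class_names), newline="\n"
        )
        (out_path / "images.txt").write_text(
            "".join(f"images/{img.image_id}.png\n" for img in out_images),
            newline="\n",
        )
        (out_path / "role.txt").write_text(source.role + "\n", newline="\n")
        with open(out_path / "generation_log.jsonl", "w", newline="\n") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    assert result.n_images == policy.factor * source.n_images
    return result


def read_placements_csv(text: str) -> list[PlacementSpec]:
    """Parse a placements file: CSV with header
    ``image_id,x,y,mask_id,scale,rotation,flip,blend_mode``."""
    import csv
    import io

    reader = csv.DictReader(io.StringIO(text))
    required = {"image_id", "x", "y", "mask_id", "scale", "rotation", "flip", "blend_mode"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(
            f"placements CSV must have header columns {sorted(required)}"
        )
    out = []
    for row in reader:
        out.append(
            PlacementSpec(
                image_id=row["image_id"],
                x=int(row["x"]),
                y=int(row["y"]),
                mask_id=row["mask_id"],
                scale=float(row["scale"]),
                rotation=float(row["rotation"]),
                flip_horizontal=row["flip"].strip().lower() in ("1", "true", "yes"),
                blend_mode=row["blend_mode"].strip(),  # type: ignore[arg-type]
            )
        )
    return out
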