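"""Procedural synthetic fixtures: leaf-like backgrounds, whitefly-like
sprites, and fully labeled source datasets.

Real greenhouse imagery of *Bemisia tabaci* on crop leaves is small, pale
insects (roughly 1 mm, a handful to a few dozen pixels at field scale)
scattered over green leaf tissue with vein structure, illumination
gradients and sensor noise.  The generator emulates those coarse statistics
— green-dominant background with low-frequency lighting, branching vein
polylines, speckle noise, and elliptical pale-bodied sprites with
translucent wings — so that every stage of the augmentation pipeline can be
exercised and validated with exact, by-construction ground truth.  It does
not attempt photorealism, occlusion, motion blur, or other pest life
stages.

Defaults mirror the scale of the experiments the pipeline was designed
around: 512 x 512 images, a held-out mask pool of 20 source sprites, and
roughly 4.5 insects per image (a 560-image training split carrying ~2,520
objects).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import BoundingBox, DatasetManifest, LabeledImage
from .masks import MaskPool, ObjectMask, _tight_crop

#: median leaf green of the fixture palette (RGB); also the canvas color
#: generated patches are composited onto before GAN training.
LEAF_MEDIAN_RGB = (74, 122, 56)


@dataclass
class FixtureConfig:
    """Parameters of the synthetic dataset generator."""

    image_size: int = 512
    n_images: int = 140
    insects_per_image: tuple[int, int] = (2, 7)
    sprite_size: tuple[int, int] = (10, 22)
    pool_size: int = 20
    palette_seed: int = 7
    layout_seed: int = 11

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("insects_per_image", "sprite_size"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}: [{lo}, {hi}]")


def _rng_for(*parts) -> np.random.Generator:
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def make_leaf_background(config: FixtureConfig, index: int) -> LabeledImage:
    """A green-dominant leaf-like raster, deterministic per (seeds, index).

    Composition: base leaf green with per-image hue variation, a
    low-frequency illumination gradient, a branching main vein with side
    veins, and Gaussian speckle noise.
    """
    rng = _rng_for("bg", config.palette_seed, config.layout_seed, index)
    s = config.image_size
    base = np.array(LEAF_MEDIAN_RGB, dtype=np.float64)
    base = base + rng.uniform(-18, 18, size=3)
    base[1] = max(base[1], base[0] + 25, base[2] + 25)  # keep green dominant

    img = np.ones((s, s, 3)) * base

    # low-frequency illumination: directional gradient + one broad blob
    yy, xx = np.mgrid[0:s, 0:s] / s
    theta = rng.uniform(0, 2 * np.pi)
    grad = (np.cos(theta) * xx + np.sin(theta) * yy) * rng.uniform(10, 40)
    cy, cx = rng.uniform(0.2, 0.8, size=2)
    blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / rng.uniform(0.05, 0.2)))
    img += (grad + blob * rng.uniform(5, 25))[..., None]

    # branching veins: one main polyline plus side branches, slightly pale
    vein = np.zeros((s, s))
    n_pts = 8
    main_x = np.linspace(0, s - 1, n_pts)
    main_y = s / 2 + np.cumsum(rng.uniform(-s / 12, s / 12, size=n_pts))
    main_y = np.clip(main_y, 0, s - 1)

    def draw_polyline(xs, ys, value):
        from skimage.draw import line

        for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
            rr, cc = line(int(y0), int(x0), int(y1), int(x1))
            vein[rr, cc] = value

    draw_polyline(main_x, main_y, 1.0)
    for bx, by in zip(main_x[1:-1], main_y[1:-1]):
        angle = rng.uniform(0.4, 1.2) * rng.choice([-1, 1])
        length = rng.uniform(0.15, 0.4) * s
        ex = np.clip(bx + np.cos(angle) * length, 0, s - 1)
        ey = np.clip(by + np.sin(angle) * length, 0, s - 1)
        draw_polyline([bx, ex], [by, ey], 0.7)
    vein = ndimage.gaussian_filter(vein, sigma=1.2)
    img += (vein * 30)[..., None] * np.array([0.9, 1.0, 0.6])

    img += rng.normal(0, 4.0, size=img.shape)  # speckle
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(image_id=f"leaf{index:04d}", boxes=[], _pixels=pixels)


def make_insect_sprite(config: FixtureConfig, rng: np.random.Generator) -> ObjectMask:
    """A whitefly-like sprite: pale elliptical body + two translucent wings.

    The body is fully opaque; wing lobes carry partial alpha (strictly
    between 0 and 1), so downstream blending is exercised on soft mattes.
    Returned tight, with provenance ``original``.
    """
    lo, hi = config.sprite_size
    size = int(rng.integers(lo, hi + 1))
    c = size * 2  # working canvas, cropped tight at the end
    yy, xx = np.mgrid[0:c, 0:c] - c / 2 + 0.5

    body_len = size * rng.uniform(0.38, 0.5)
    body_wid = body_len * rng.uniform(0.45, 0.65)
    angle = rng.uniform(0, np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    body = (u / body_len) ** 2 + (v / body_wid) ** 2 <= 1.0

    alpha = body.astype(np.float64)
    wing_alpha = rng.uniform(0.45, 0.7)
    for side in (-1, 1):
        wang = angle + side * rng.uniform(0.5, 0.9)
        wca, wsa = np.cos(wang), np.sin(wang)
        wl = body_len * rng.uniform(1.1, 1.5)
        ww = body_wid * rng.uniform(0.7, 1.0)
        # wing root sits at the body center, lobe extends outward
        wu = wca * xx + wsa * yy - wl * 0.6
        wv = -wsa * xx + wca * yy
        wing = (wu / wl) ** 2 + (wv / ww) ** 2 <= 1.0
        alpha = np.maximum(alpha, wing * wing_alpha)

    body_color = np.array([235, 232, 200]) + rng.uniform(-15, 10, size=3)
    wing_color = np.array([248, 248, 240]) + rng.uniform(-8, 5, size=3)
    patch = np.where(body[..., None], body_color, wing_color)
    patch = np.clip(
        np.rint(patch + rng.normal(0, 3, size=patch.shape)), 0, 255
    ).astype(np.uint8)

    patch, alpha = _tight_crop(patch, alpha)
    return ObjectMask(
        patch=np.ascontiguousarray(patch),
        alpha=alpha,
        class_id=0,
        provenance="original",
        source_id="",
    )


def make_source_dataset(config: FixtureConfig) -> tuple[DatasetManifest, MaskPool]:
    """Generate a labeled source dataset plus a held-out sprite pool.

    Each background receives a drawn number of sprites hard-pasted at
    non-overlapping positions; the recorded boxes are the exact tight
    rectangles of the pasted mattes, so ground truth is correct by
    construction.  The held-out pool (default 20 sprites) never appears in
    the dataset images, mirroring a source mask pool assembled separately
    from the training images.
    """
    from .engine import PlacementSpec, paste_object

    layout = _rng_for("layout", config.palette_seed, config.layout_seed)
    images: list[LabeledImage] = []
    lo, hi = config.insects_per_image
    for i in range(config.n_images):
        img = make_leaf_background(config, i)
        n = int(layout.integers(lo, hi + 1))
        s = config.image_size
        placed_boxes: list[BoundingBox] = []
        for _ in range(n):
            sprite = make_insect_sprite(config, layout)
            h, w = sprite.shape
            for _attempt in range(50):
                x = int(layout.integers(0, s - w + 1))
                y = int(layout.integers(0, s - h + 1))
                cand = BoundingBox(0, x, y, w, h)
                if all(
                    min(cand.x_max, b.x_max) <= max(cand.x_min, b.x_min)
                    or min(cand.y_max, b.y_max) <= max(cand.y_min, b.y_min)
                    for b in placed_boxes
                ):
                    img, box = paste_object(
                        img, sprite, PlacementSpec(img.image_id, x, y, blend_mode="hard")
                    )
                    placed_boxes.append(box)
                    break
        images.append(img)

    pool_rng = _rng_for("pool", config.palette_seed, config.layout_seed)
    pool = MaskPool(
        masks=[
            _with_id(make_insect_sprite(config, pool_rng), f"sprite{j:03d}")
            for j in range(config.pool_size)
        ]
    )
    manifest = DatasetManifest(role="train", images=images, class_names=["whitefly"])
    return manifest, pool


def _with_id(mask: ObjectMask, source_id: str) -> ObjectMask:
    mask.source_id = source_id
    return mask
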