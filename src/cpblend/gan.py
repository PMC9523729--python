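"""DCGAN mask-pool expansion: learn the appearance of the source object
patches and synthesize new 32 x 32 RGB patches to diversify the paste pool.

The generator projects a latent vector to a ``base_resolution`` feature map
and applies three up-sampling blocks — nearest-neighbour 2x up-sampling, a
convolution with ReLU activation, then batch normalization — followed by a
final convolution with a hyperbolic-tangent activation, so the output is a
32 x 32 x 3 raster in [-1, 1].  The discriminator applies three strided
convolutional blocks with ReLU and dropout, with batch normalization on the
last two blocks, then a fully-connected sigmoid head scoring realness in
(0, 1).  Both networks are optimized with Adam at learning rate 0.0002
under the usual alternating binary cross-entropy objectives (the generator
uses the non-saturating form).

Generated patches are converted into pasteable masks by
``masks.segment_generated_patch``; degenerate generations are skipped and
resampled.  Expanding a source pool of 20 masks by 40 generated ones yields
the 60-mask pool the CPB+GAN pipeline pastes from.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from .fixtures import LEAF_MEDIAN_RGB
from .masks import DegenerateGenerationError, MaskPool, ObjectMask, segment_generated_patch

OUTPUT_SIZE = 32


@dataclass
class GanConfig:
    """Hyper-parameters of the patch DCGAN.

    ``base_resolution`` is the side of the first feature map; three 2x
    up-sampling doublings must reach the 32-px output, so it is pinned to 4.
    The learning rate default is the Adam rate the networks were designed
    around (0.0002); beta1 = 0.5 is the standard DCGAN choice.
    """

    latent_dim: int = 100
    base_resolution: int = 4
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 16
    epochs: int = 30
    dropout_p: float = 0.25
    seed: int = 0
    # capacity knobs: channels after the latent projection, halved per block
    base_channels: int = 64
    label_smoothing: float = 0.0
    input_noise_std: float = 0.0

    def __post_init__(self) -> None:
        if self.base_resolution * 2**3 != OUTPUT_SIZE:
            raise ValueError(
                f"base_resolution {self.base_resolution} * 2^3 != {OUTPUT_SIZE}"
            )
        if self.latent_dim < 1 or self.batch_size < 1:
            raise ValueError("latent_dim and batch_size must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        return cls(**d)


class GeneratorModel:
    """Latent vector -> 32 x 32 x 3 raster in [-1, 1]."""

    def __init__(self, config: GanConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        r, c0 = config.base_resolution, config.base_channels
        c1, c2, c3 = c0 // 2, c0 // 4, c0 // 8
        layers: list[_nn.Layer] = [
            _nn.Dense(config.latent_dim, c0 * r * r, rng),
            _nn.Reshape((c0, r, r)),
        ]
        for cin, cout in ((c0, c1), (c1, c2), (c2, c3)):
            layers += [
                _nn.UpsampleNearest2x(),
                _nn.Conv2d(cin, cout, rng),
                _nn.ReLU(),
                _nn.BatchNorm2d(cout),
            ]
        layers += [_nn.Conv2d(c3, 3, rng), _nn.Tanh()]
        self.net = _nn.Sequential(layers)

    def describe(self) -> list[str]:
        return self.net.describe()

    def sample(
        self, n: int, rng: np.random.Generator, training: bool = False
    ) -> np.ndarray:
        """Decode ``n`` latent draws into (n, 32, 32, 3) rasters in [-1, 1]."""
        z = rng.standard_normal((n, self.config.latent_dim))
        return self.decode(z, training=training)

    def decode(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.net.forward(z, training=training)  # (n, 3, 32, 32)
        return np.transpose(out, (0, 2, 3, 1))


class DiscriminatorModel:
    """32 x 32 x 3 raster -> realness score in (0, 1)."""

    def __init__(self, config: GanConfig):
        self.config = config
        rng = np.random.default_rng(config.seed + 1)
        self.dropout_rng = np.random.default_rng(config.seed + 2)
        c1, c2, c3 = 16, 32, 64
        layers: list[_nn.Layer] = [
            _nn.Conv2d(3, c1, rng, stride=2),
            _nn.ReLU(),
            _nn.Dropout(config.dropout_p, self.dropout_rng),
            _nn.Conv2d(c1, c2, rng, stride=2),
            _nn.BatchNorm2d(c2),
            _nn.ReLU(),
            _nn.Dropout(config.dropout_p, self.dropout_rng),
            _nn.Conv2d(c2, c3, rng, stride=2),
            _nn.BatchNorm2d(c3),
            _nn.ReLU(),
            _nn.Dropout(config.dropout_p, self.dropout_rng),
            _nn.Flatten(),
            _nn.Dense(c3 * 4 * 4, 1, rng),
            _nn.Sigmoid(),
        ]
        self.net = _nn.Sequential(layers)

    def describe(self) -> list[str]:
        return self.net.describe()

    def score(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """Score (n, 32, 32, 3) rasters in [-1, 1]; returns (n,) in (0, 1)."""
        if images.ndim != 4 or images.shape[1:] != (32, 32, 3):
            raise ValueError(f"expected (n, 32, 32, 3), got {images.shape}")
        x = np.transpose(images, (0, 3, 1, 2))
        return self.net.forward(x, training=training)[:, 0]


def build_generator(config: GanConfig) -> GeneratorModel:
    return GeneratorModel(config)


def build_discriminator(config: GanConfig) -> DiscriminatorModel:
    return DiscriminatorModel(config)


def pool_training_patches(pool: MaskPool) -> np.ndarray:
    """Render the pool's original masks as 32 x 32 training rasters in [-1, 1].

    Each mask is alpha-composited, centered, onto a square canvas of the
    median leaf green (so the border-median segmentation heuristic stays
    valid on generated patches), then resized to 32 x 32.
    """
    originals = [m for m in pool.masks if m.provenance == "original"]
    out = np.empty((len(originals), OUTPUT_SIZE, OUTPUT_SIZE, 3))
    bg = np.array(LEAF_MEDIAN_RGB, dtype=np.float64)
    for i, m in enumerate(originals):
        h, w = m.shape
        side = max(h, w)
        canvas = np.ones((side, side, 3)) * bg
        oy, ox = (side - h) // 2, (side - w) // 2
        a = m.alpha[..., None]
        canvas[oy : oy + h, ox : ox + w] = (
            a * m.patch.astype(np.float64) + (1 - a) * canvas[oy : oy + h, ox : ox + w]
        )
        patch = resize(canvas / 255.0, (OUTPUT_SIZE, OUTPUT_SIZE), order=1,
                       anti_aliasing=side > OUTPUT_SIZE)
        out[i] = patch * 2.0 - 1.0
    return out


def train_dcgan(
    pool: MaskPool,
    config: GanConfig,
    checkpoint_dir: str | os.PathLike | None = None,
    return_discriminator: bool = False,
) -> GeneratorModel | tuple[GeneratorModel, DiscriminatorModel]:
    """Adversarial training of the patch generator on the pool's originals.

    Alternates one discriminator update (real batch vs generated batch, BCE
    targets 1/0) and one generator update (non-saturating BCE toward 1) per
    mini-batch.  The parameter trajectory is a pure function of
    ``config.seed``.  Aborts with a diagnostic if either loss goes
    non-finite, keeping the last stable checkpoint when one is on disk.
    """
    real = pool_training_patches(pool)
    if len(real) < 2:
        raise ValueError(f"need >= 2 original masks to train, have {len(real)}")

    gen = build_generator(config)
    disc = build_discriminator(config)
    rng = np.random.default_rng(config.seed + 3)
    opt_g = _nn.Adam(
        gen.net.parameters(), lr=config.learning_rate,
        beta1=config.adam_beta1, beta2=config.adam_beta2,
    )
    opt_d = _nn.Adam(
        disc.net.parameters(), lr=config.learning_rate,
        beta1=config.adam_beta1, beta2=config.adam_beta2,
    )
    real_target = 1.0 - config.label_smoothing

    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    n = len(real)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = real[order[start : start + bs]]
            if config.input_noise_std > 0:
                batch = batch + rng.normal(0, config.input_noise_std, batch.shape)
            b = len(batch)

            # --- discriminator step ---
            fake = gen.sample(b, rng, training=True)
            disc.net.zero_grad()
            p_real = disc.score(batch, training=True)
            loss_real, dreal = _nn.bce_loss(p_real, real_target)
            disc.net.backward(_expand_score_grad(dreal))
            p_fake = disc.score(fake, training=True)
            loss_fake, dfake = _nn.bce_loss(p_fake, 0.0)
            disc.net.backward(_expand_score_grad(dfake))
            if not (np.isfinite(loss_real) and np.isfinite(loss_fake)):
                raise RuntimeError(
                    f"discriminator loss non-finite at epoch {epoch} "
                    f"(real={loss_real}, fake={loss_fake})"
                )
            opt_d.step()

            # --- generator step (non-saturating) ---
            z = rng.standard_normal((b, config.latent_dim))
            gen.net.zero_grad()
            disc.net.zero_grad()
            fake_imgs = gen.decode(z, training=True)
            p_gen = disc.score(fake_imgs, training=True)
            loss_gen, dgen = _nn.bce_loss(p_gen, 1.0)
            if not np.isfinite(loss_gen):
                raise RuntimeError(f"generator loss non-finite at epoch {epoch}")
            grad_images = disc.net.backward(_expand_score_grad(dgen))
            gen.net.backward(grad_images)
            opt_g.step()
            disc.net.zero_grad()

        if ckpt_dir is not None:
            save_checkpoint(gen, ckpt_dir / f"generator-epoch{epoch:03d}.npz")
    if return_discriminator:
        return gen, disc
    return gen


def _expand_score_grad(d: np.ndarray) -> np.ndarray:
    return d.reshape(-1, 1)


def save_checkpoint(gen: GeneratorModel, path: str | os.PathLike) -> None:
    """Single-file parameter archive with an embedded config echo."""
    arrays = {f"arr{i:03d}": a for i, a in enumerate(gen.net.state_arrays())}
    np.savez(path, config=json.dumps(gen.config.to_dict()), **arrays)


def load_checkpoint(path: str | os.PathLike) -> GeneratorModel:
    with np.load(path, allow_pickle=False) as data:
        config = GanConfig.from_dict(json.loads(str(data["config"])))
        arrays = [data[k] for k in sorted(k for k in data.files if k != "config")]
    gen = build_generator(config)
    gen.net.load_state_arrays(arrays)
    return gen


def expand_mask_pool(
    pool: MaskPool,
    generator: GeneratorModel,
    n_new: int,
    rng: np.random.Generator,
) -> MaskPool:
    """Append ``n_new`` generated masks to a copy of the pool.

    Latents are decoded in small batches, rescaled from [-1, 1] to 8-bit,
    and segmented into tight masks; degenerate generations (no separable
    foreground) are skipped and redrawn, up to a 10x attempt cap.  Original
    members are never mutated and ``n_initial`` never decreases.
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    class_id = pool.masks[0].class_id if pool.masks else 0
    new_masks: list[ObjectMask] = []
    attempts = 0
    cap = max(1, 10 * n_new)
    while len(new_masks) < n_new:
        if attempts >= cap:
            raise RuntimeError(
                f"generation attempt cap reached: {len(new_masks)} of {n_new} "
                "masks produced"
            )
        batch = min(16, n_new - len(new_masks), cap - attempts)
        patches = generator.sample(batch, rng, training=False)
        attempts += batch
        for patch in patches:
            if len(new_masks) >= n_new:
                break
            patch8 = np.clip(np.rint((patch + 1.0) * 127.5), 0, 255).astype(np.uint8)
            try:
                mask = segment_generated_patch(
                    patch8,
                    class_id=class_id,
                    source_id=f"gan{pool.n_final + len(new_masks):03d}",
                )
            except DegenerateGenerationError:
                continue
            new_masks.append(mask)
    return MaskPool(masks=list(pool.masks) + new_masks)
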