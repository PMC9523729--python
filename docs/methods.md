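# Methods

## The Copy-Paste-Blend operator

A source object is represented as an `ObjectMask`: an 8-bit color patch
with an aligned alpha matte in [0, 1], cropped **tight** (the support of
`alpha > 0` touches all four patch borders).  Pasting transforms the mask
(scale, rotation, horizontal flip), composites it onto the background at a
pixel position, and appends a bounding box equal to the tight rectangle of
the transformed matte — so annotations are correct by construction and the
count laws `N_if = k·N_ii`, `N_of = k·N_oi + pastes` are recomputable from
any output manifest.

Three blend operators are provided; which one "blending … for realism"
should be is genuinely open, so all three are config options:

- **hard** — binary cut-out (`alpha > 0` wins).  Exact, but leaves the
  paste outline that human reviewers identify first.
- **feathered** (default, `sigma = 1 px`) — the matte is Gaussian-softened
  (kernel truncated at 3σ) and composited linearly.  Pixels farther than 3σ
  from the matte support are bit-identical to the background; the patch is
  edge-replicated under the softened fringe so no dark halo appears.
- **seamless** — gradient-domain (Poisson) compositing over the
  `alpha > 0.5` support: a sparse Laplace system with patch gradients as
  guidance and background Dirichlet boundary values, solved per paste
  window with SciPy's sparse solver.  Only support pixels are modified, so
  everything outside the support's 1-px dilation is untouched.

Mask transforms resample bilinearly with alpha-premultiplied colors (no
background bleed), re-clip the matte to [0, 1], zero values below 10⁻³
(interpolation dust would otherwise defeat re-tightening), and re-crop
tight.  Exact multiples of 90° are rotated losslessly with `rot90`;
foreground *area accounting* thresholds the matte at 0.5, never the
compositing path.  A scale that would shrink either extent below one pixel
is an error rather than a silent clamp.

## Batch placement

Interactive use chooses paste locations by hand (a placements CSV stands in
for the original tool's clicks); batch augmentation samples them.  Each
candidate draws a mask and jitter (defaults: scale 0.7–1.3, rotation
±180°, flip p = 0.5, 1–6 pastes per image), transforms it to know its exact
extent, and proposes a uniform in-bounds position, accepted iff its box has
IoU ≤ 0.1 with every existing and already-accepted box; 100 attempts per
placement, shortfalls logged, never fatal.  The sampler takes the mask pool
as an argument because candidate extents depend on the drawn mask — the
realized paste box is then exactly the box the overlap test used.

Randomness: one policy seed; each (image, copy) pair gets a substream via
SHA-256 of `(seed, image_id, copy_index)`, so outputs are byte-identical
across reruns and independent of iteration order.  Copy 1 of each source
image keeps its original pixels and also receives pastes; the identity
configuration (`factor 1, pastes [0, 0]`) reduces to pure duplication,
which keeps both readings of "augmenting keeps the originals" available.

## The patch DCGAN

The generator maps a 100-d latent through a dense projection to a 4×4
feature map, then three blocks of [2× nearest-neighbour up-sampling →
3×3 convolution → ReLU → batch norm], then a 3×3 convolution with tanh:
a 32×32×3 patch in [−1, 1].  The discriminator is three stride-2
convolution blocks with ReLU and dropout (p = 0.25), batch norm on blocks
two and three, then a fully-connected sigmoid head.  Both are optimized
with Adam (lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999) under alternating binary
cross-entropy; the generator uses the non-saturating objective.  Label
smoothing and input noise exist as flags but default off.

The networks are implemented directly in NumPy (im2col convolutions,
hand-derived batch-norm backward, Adam) — at this size a forward/backward
pass is milliseconds, and a fully deterministic parameter trajectory per
seed is a test-surface requirement.  Latent dimension, channel widths,
batch size (16; 8 in the small study runs) and epochs are exposed in
`GanConfig`; none of them are pinned by the design beyond the architecture
itself and the 4→8→16→32 resolution chain.

Training patches are the pool's original masks composited centered onto a
square canvas of the fixture palette's median leaf green — not black — so
the border-median segmentation heuristic below remains valid on generated
patches, then resized to 32×32 and rescaled to [−1, 1].

Generated patches become pasteable masks by estimating the background as
the median color of the 1-px border frame, thresholding the luminance
distance from it (Otsu, with a 12-level minimum-contrast floor), keeping
the largest connected component, and closing 1-pixel holes.  Patches with
no separable foreground raise a *degenerate generation* error and are
redrawn, up to 10× the requested count; expanding a 20-mask pool by 40
yields exactly 60, originals untouched.  Whether generated masks should be
human-vetted before entering the pool is left to the caller (the pool index
records provenance, so a review pass can filter on it).

## Evaluation

IoU uses the half-open box convention.  Matching is greedy
confidence-ordered VOC (the Darknet evaluator's behaviour): per image,
descending confidence with ties by insertion order, each detection matched
to the unmatched ground truth of highest IoU, TP iff that IoU is *strictly*
greater than the threshold ("higher than" read strictly); a ground truth is
consumed only by a TP.  Recall is TP/(TP+FN) with 0/0 defined as 0 plus a
warning.  AP integrates the all-point interpolated precision–recall curve
(suffix-max precision envelope); an 11-point variant is a flag.  Average
IoU is fixed as the mean IoU over matched pairs at the 0.50 threshold — a
test-time matched-pair mean; it therefore always exceeds 0.50 whenever any
TP exists.  Count RMSE is the root-mean-square per-image count difference.

## The fixture generator

Backgrounds: green-dominant base color with per-image variation, a
directional low-frequency illumination gradient plus one broad blob,
a branching main vein with side veins, and Gaussian speckle (σ = 4 levels).
Sprites: an opaque pale ellipse body with two translucent wing lobes
(alpha 0.45–0.7), 10–22 px — small, pale, numerous, matching the coarse
statistics of adult whiteflies on leaves.  Datasets hard-paste a drawn
number of sprites (default 2–7, mean ≈ 4.5 per image, the density of the
motivating 560-image/2,520-object split) at non-overlapping positions;
the held-out pool (default 20) never appears in the images.  Everything is
a pure function of the two fixture seeds.

What fixtures do **not** model: photorealistic texture, specular
highlights, occlusion between insects, egg/nymph stages, camera blur.
Tests passing on fixtures therefore validate the *pipeline machinery*
(geometry, bookkeeping, blending locality, determinism, metric
definitions), not detector-level realism of the composites.

## Problem sizes and numerical choices

The acceptance run uses the study-scale structural sizes — 140 base images
at 512×512 augmented ×4 to 560 and ×2 to 1,120, a 20-mask pool expanded by
40 to 60 with a 30-epoch, batch-8 GAN run — all of which complete in a few
minutes on one CPU.  Unit and property tests use 96-px images and 3-image
manifests; one shared 30-epoch GAN training backs all trained-model tests.
Label round-trips are exact on counts and class ids and within 1 px on
coordinates (6-decimal normalized output; round-half-up conversion;
rounding overshoot clipped, minimum extent one pixel).  Matte persistence
quantizes alpha to 8 bits but never rounds a positive value to zero, so
tightness survives save/load.

## Known limitations

- The DCGAN is single-class and unconditional; per-species generation
  would need one pool and generator per class.
- Poisson blending recolors the whole pasted object toward the local
  background; for very translucent objects feathered blending is usually
  the better default, which is why it is the default.
- The evaluator scores axis-aligned boxes only, and multi-class datasets
  are aggregated by unweighted mean of per-class AP outside this package.
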