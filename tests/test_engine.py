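"""Copy-Paste-Blend engine: blending contracts, placement sampling, and
whole-dataset augmentation bookkeeping."""

import numpy as np
import pytest
from scipy import ndimage

from cpblend.annotations import LabeledImage, write_dataset
from cpblend.engine import (
    AugmentationPolicy,
    PlacementSpec,
    augment_dataset,
    paste_object,
    read_placements_csv,
    sample_placements,
)
from cpblend.evaluation import iou
from cpblend.masks import MaskPool, ObjectMask


def opaque_mask(h=10, w=10, color=(250, 240, 200)):
    patch = np.zeros((h, w, 3), np.uint8)
    patch[:] = color
    return ObjectMask(patch=patch, alpha=np.ones((h, w)))


@pytest.fixture
def background(rng):
    px = rng.integers(0, 256, size=(60, 80, 3), dtype=np.uint8)
    return LabeledImage(image_id="bg", boxes=[], _pixels=px)


class TestPasteObject:
    def test_hard_mode_is_exact_cut_and_keep(self, background):
        mask = opaque_mask(10, 10)
        out, box = paste_object(
            background, mask, PlacementSpec("bg", 5, 5, blend_mode="hard")
        )
        assert np.array_equal(out.pixels[5:15, 5:15], mask.patch)
        untouched = np.ones((60, 80), bool)
        untouched[5:15, 5:15] = False
        assert np.array_equal(out.pixels[untouched], background.pixels[untouched])
        assert (box.x_min, box.y_min, box.width, box.height) == (5, 5, 10, 10)
        # input not modified
        assert not np.array_equal(out.pixels, background.pixels)

    def test_zero_alpha_rejected(self, background):
        dead = ObjectMask(
            patch=np.zeros((5, 5, 3), np.uint8), alpha=np.zeros((5, 5))
        )
        with pytest.raises(ValueError, match="no foreground"):
            paste_object(background, dead, PlacementSpec("bg", 0, 0, blend_mode="hard"))

    def test_feathered_conserves_pixels_beyond_blend_radius(self, background):
        radius = 2.0
        mask = opaque_mask(9, 7)
        out, _ = paste_object(
            background, mask, PlacementSpec("bg", 20, 20, blend_mode="feathered"),
            feather_radius=radius,
        )
        support = np.zeros((60, 80), bool)
        support[20:29, 20:27] = mask.alpha > 0
        dist = ndimage.distance_transform_edt(~support)
        far = dist > 3 * radius
        assert np.array_equal(out.pixels[far], background.pixels[far])

    def test_seamless_bounded_and_local(self, background):
        mask = opaque_mask(12, 12, color=(255, 255, 255))
        out, _ = paste_object(
            background, mask, PlacementSpec("bg", 10, 30, blend_mode="seamless")
        )
        assert out.pixels.dtype == np.uint8
        support = np.zeros((60, 80), bool)
        support[30:42, 10:22] = mask.alpha > 0.5  # rows are y, columns are x
        outside = ~ndimage.binary_dilation(support)
        diff = np.abs(
            out.pixels.astype(int) - background.pixels.astype(int)
        ).max(axis=2)
        assert diff[outside].max() <= 2

    def test_box_equals_tight_rect_of_transformed_support(self, background):
        mask = opaque_mask(8, 14)
        spec = PlacementSpec(
            "bg", 12, 9, scale=1.4, rotation=37.0, flip_horizontal=True,
            blend_mode="hard",
        )
        out, box = paste_object(background, mask, spec)
        changed = (out.pixels != background.pixels).any(axis=2)
        ys, xs = np.nonzero(changed)
        assert (ys.min(), xs.min()) == (box.y_min, box.x_min)
        assert (ys.max() + 1, xs.max() + 1) == (box.y_max, box.x_max)

    def test_out_of_bounds_placement_error(self, background):
        with pytest.raises(ValueError, match="outside"):
            paste_object(
                background, opaque_mask(10, 10),
                PlacementSpec("bg", 75, 0, blend_mode="hard"),
            )

    def test_appends_to_existing_boxes(self, background):
        from cpblend.annotations import BoundingBox

        background.boxes.append(BoundingBox(0, 0, 0, 5, 5))
        out, box = paste_object(
            background, opaque_mask(6, 6), PlacementSpec("bg", 40, 40, blend_mode="hard")
        )
        assert len(out.boxes) == 2
        assert out.boxes[-1] == box


class TestSamplePlacements:
    def test_zero_requested(self, background, rng):
        pool = MaskPool(masks=[opaque_mask(5, 5)])
        assert sample_placements(background, 0, AugmentationPolicy(), rng, pool) == []

    def test_disjoint_at_zero_overlap(self, background, rng):
        from cpblend.annotations import BoundingBox

        pool = MaskPool(masks=[opaque_mask(8, 8)])
        policy = AugmentationPolicy(
            max_overlap_iou=0.0, scale_jitter=(1.0, 1.0), rotation_jitter=(0.0, 0.0),
            flip_probability=0.0,
        )
        specs = sample_placements(background, 3, policy, rng, pool)
        assert len(specs) == 3
        boxes = [BoundingBox(0, s.x, s.y, 8, 8) for s in specs]
        for i in range(3):
            for j in range(i + 1, 3):
                assert iou(boxes[i], boxes[j]) == 0.0

    def test_same_seed_gives_identical_lists(self, background):
        pool = MaskPool(masks=[opaque_mask(6, 9), opaque_mask(4, 4)])
        policy = AugmentationPolicy()
        a = sample_placements(background, 4, policy, np.random.default_rng(7), pool)
        b = sample_placements(background, 4, policy, np.random.default_rng(7), pool)
        assert a == b

    def test_shortfall_is_not_an_error(self, rng, caplog):
        tiny = LabeledImage(
            image_id="tiny", _pixels=np.zeros((12, 12, 3), np.uint8)
        )
        pool = MaskPool(masks=[opaque_mask(10, 10)])
        policy = AugmentationPolicy(
            max_overlap_iou=0.0, scale_jitter=(1.0, 1.0), rotation_jitter=(0.0, 0.0),
            flip_probability=0.0,
        )
        specs = sample_placements(tiny, 5, policy, rng, pool)
        assert len(specs) < 5  # only one 10x10 box fits disjointly in 12x12


class TestAugmentDataset:
    @pytest.mark.parametrize("factor", [1, 2, 4])
    def test_image_count_law(self, tiny_dataset, factor):
        manifest, pool = tiny_dataset
        policy = AugmentationPolicy(factor=factor, seed=5)
        out = augment_dataset(manifest, pool, policy)
        assert out.n_images == factor * manifest.n_images

    def test_object_count_law(self, tiny_dataset):
        manifest, pool = tiny_dataset
        policy = AugmentationPolicy(factor=2, seed=5, pastes_per_image=(1, 3))
        out = augment_dataset(manifest, pool, policy)
        n_pastes = out.n_objects - policy.factor * manifest.n_objects
        assert n_pastes > 0
        # recomputable from the manifest: every extra box is a paste
        assert out.n_objects == policy.factor * manifest.n_objects + n_pastes

    def test_identity_configuration_duplicates_source(self, tiny_dataset):
        manifest, pool = tiny_dataset
        policy = AugmentationPolicy(factor=1, pastes_per_image=(0, 0), seed=0)
        out = augment_dataset(manifest, pool, policy)
        assert out.n_images == manifest.n_images
        for src, dup in zip(manifest.images, out.images):
            assert np.array_equal(src.pixels, dup.pixels)
            assert src.boxes == dup.boxes

    def test_seeded_rerun_is_byte_identical(self, tiny_dataset, tmp_path):
        manifest, pool = tiny_dataset
        policy = AugmentationPolicy(factor=2, seed=11)
        for name in ("a", "b"):
            out = augment_dataset(manifest, pool, policy)
            write_dataset(out, tmp_path / name)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_empty_pool_rejected(self, tiny_dataset):
        manifest, _ = tiny_dataset
        with pytest.raises(ValueError, match="empty"):
            augment_dataset(manifest, MaskPool(), AugmentationPolicy())

    def test_unknown_placement_image_rejected(self, tiny_dataset):
        manifest, pool = tiny_dataset
        bad = [PlacementSpec("no-such-image", 1, 1, mask_id="random")]
        with pytest.raises(ValueError, match="unknown image"):
            augment_dataset(manifest, pool, AugmentationPolicy(), placements=bad)

    def test_unknown_placement_mask_rejected(self, tiny_dataset):
        manifest, pool = tiny_dataset
        bad = [PlacementSpec(manifest.images[0].image_id, 1, 1, mask_id="nope")]
        with pytest.raises(KeyError):
            augment_dataset(manifest, pool, AugmentationPolicy(), placements=bad)

    def test_explicit_placements_applied_to_first_copy(self, tiny_dataset):
        manifest, pool = tiny_dataset
        target = manifest.images[0]
        spec = PlacementSpec(
            target.image_id, 4, 4, mask_id=pool.masks[0].source_id,
            blend_mode="hard",
        )
        policy = AugmentationPolicy(factor=1, pastes_per_image=(0, 0), seed=0)
        out = augment_dataset(manifest, pool, policy, placements=[spec])
        assert len(out.images[0].boxes) == len(target.boxes) + 1
        new = out.images[0].boxes[-1]
        assert (new.x_min, new.y_min) == (4, 4)

    def test_streaming_to_disk_matches_counts(self, tiny_dataset, tmp_path):
        manifest, pool = tiny_dataset
        policy = AugmentationPolicy(factor=2, seed=3)
        out = augment_dataset(manifest, pool, policy, out_dir=tmp_path / "ds")
        assert out.n_images == 2 * manifest.n_images
        assert len(list((tmp_path / "ds" / "images").glob("*.png"))) == out.n_images
        assert (tmp_path / "ds" / "generation_log.jsonl").exists()


class TestPlacementsCsv:
    def test_parse(self):
        text = (
            "image_id,x,y,mask_id,scale,rotation,flip,blend_mode\n"
            "img0,10,20,sprite001,1.2,-45.0,true,hard\n"
        )
        specs = read_placements_csv(text)
        assert specs == [
            PlacementSpec("img0", 10, 20, "sprite001", 1.2, -45.0, True, "hard")
        ]

    def test_missing_header_rejected(self):
        with pytest.raises(ValueError, match="header"):
            read_placements_csv("image_id,x,y\nimg0,1,2\n")
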