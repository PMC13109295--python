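"""Texture generation, composition, refinement pairs, and objectives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafgen.render import MaskPatch
from leafgen.synthesis import (
    ArchiveRecord,
    CompositionConfig,
    PairExtractionArchive,
    ProceduralLeafStyle,
    ProceduralTextureGenerator,
    TextureGeneratorAdapter,
    build_refinement_pairs,
    cgan_loss,
    compose,
    l1_loss,
    procedural_texture,
    total_objective,
)

from conftest import random_blob_mask


def disc_mask(h=33, w=33, r=12):
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - h // 2) ** 2 + (xx - w // 2) ** 2) <= r**2).astype(np.uint8)


def patch(mask, bbox=None, instance_id=1):
    h, w = mask.shape
    return MaskPatch(instance_id=instance_id, mask=mask, bbox=bbox or (0, 0, w, h))


FLAT_STYLE = ProceduralLeafStyle(
    base_color=(60, 120, 50), base_jitter=0.0, vein_density=0.0,
    rim_darkening=0.0, noise_amplitude=0.0,
)


class TestProceduralTexture:
    def test_degenerate_style_constant_inside_mask(self):
        m = disc_mask()
        tex = procedural_texture(patch(m), FLAT_STYLE, seed=1)
        inside = tex[m.astype(bool)]
        assert np.all(inside == inside[0])
        assert tuple(inside[0]) == (60, 120, 50)

    def test_outside_mask_is_background_color(self):
        m = disc_mask()
        tex = procedural_texture(patch(m), FLAT_STYLE, seed=1)
        outside = tex[~m.astype(bool)]
        assert np.all(outside == np.array(FLAT_STYLE.background_color))

    def test_deterministic_given_seed(self):
        m = disc_mask()
        style = ProceduralLeafStyle()
        a = procedural_texture(patch(m), style, seed=9)
        b = procedural_texture(patch(m), style, seed=9)
        assert np.array_equal(a, b)
        c = procedural_texture(patch(m), style, seed=10)
        assert not np.array_equal(a, c)

    def test_full_rim_darkening_center_brighter_than_boundary(self):
        m = disc_mask(41, 41, 15)
        style = ProceduralLeafStyle(
            base_color=(100, 160, 90), base_jitter=0.0, vein_density=0.0,
            rim_darkening=1.0, noise_amplitude=0.0,
        )
        tex = procedural_texture(patch(m), style, seed=0).astype(int)
        center = tex[20, 20].sum()
        from scipy import ndimage

        boundary = m.astype(bool) & ~ndimage.binary_erosion(m.astype(bool))
        boundary_vals = tex[boundary].sum(axis=1)
        assert center > boundary_vals.max()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            procedural_texture(patch(np.zeros((5, 5), np.uint8)))

    def test_generator_interface_shape_contract(self):
        gen = ProceduralTextureGenerator(seed=3)
        m = disc_mask()
        out = gen.generate(patch(m))
        assert out.shape == (*m.shape, 3)
        assert out.dtype == np.uint8

    def test_adapter_rejects_wrong_shape(self):
        bad = TextureGeneratorAdapter(fn=lambda m: np.zeros((2, 2, 3), np.uint8))
        with pytest.raises(ValueError, match="shape"):
            bad.generate(patch(disc_mask()))


class TestCompose:
    def test_no_foreground_is_identity(self):
        bg = np.random.default_rng(0).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        out = compose([], [], bg)
        assert np.array_equal(out, bg)

    def test_full_frame_mask_total_replacement(self):
        bg = np.zeros((8, 8, 3), np.uint8)
        tex = np.full((8, 8, 3), 200, np.uint8)
        out = compose([patch(np.ones((8, 8), np.uint8))], [tex], bg)
        assert np.array_equal(out, tex)

    def test_overlap_shows_last_in_depth_order(self):
        # 4x4 toy, two 3x3 instances overlapping on a 2x3 block
        bg = np.zeros((4, 4, 3), np.uint8)
        m1 = patch(np.ones((3, 3), np.uint8), bbox=(0, 0, 3, 3), instance_id=1)
        m2 = patch(np.ones((3, 3), np.uint8), bbox=(0, 1, 3, 4), instance_id=2)
        t1 = np.full((3, 3, 3), 100, np.uint8)
        t2 = np.full((3, 3, 3), 220, np.uint8)
        out = compose([m1, m2], [t1, t2], bg, CompositionConfig(depth_order=(1, 2)))
        assert np.all(out[1:3, 0:3] == 220)  # overlap gets last-pasted texture
        assert np.all(out[0, 0:3] == 100)
        out_rev = compose([m1, m2], [t1, t2], bg, CompositionConfig(depth_order=(2, 1)))
        assert np.all(out_rev[1:3, 0:3] == 100)

    def test_background_conservation_outside_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            bg = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
            n = int(rng.integers(1, 5))
            patches, textures, covered = [], [], np.zeros((24, 24), bool)
            for i in range(n):
                m = random_blob_mask(rng, 10, 10)
                x0 = int(rng.integers(0, 14))
                y0 = int(rng.integers(0, 14))
                patches.append(patch(m, bbox=(x0, y0, x0 + 10, y0 + 10), instance_id=i + 1))
                textures.append(rng.integers(0, 256, (10, 10, 3), dtype=np.uint8))
                covered[y0 : y0 + 10, x0 : x0 + 10] |= m.astype(bool)
            out = compose(patches, textures, bg)
            assert np.array_equal(out[~covered], bg[~covered])

    def test_compose_crop_round_trip(self):
        bg = np.zeros((20, 20, 3), np.uint8)
        m = disc_mask(9, 9, 3)
        tex = np.random.default_rng(1).integers(0, 256, (9, 9, 3), dtype=np.uint8)
        p = patch(m, bbox=(5, 6, 14, 15))
        out = compose([p], [tex], bg)
        region = out[6:15, 5:14]
        assert np.array_equal(region[m.astype(bool)], tex[m.astype(bool)])

    def test_bbox_outside_background_rejected(self):
        bg = np.zeros((8, 8, 3), np.uint8)
        p = patch(np.ones((4, 4), np.uint8), bbox=(6, 6, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            compose([p], [np.zeros((4, 4, 3), np.uint8)], bg)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="masks but"):
            compose([patch(np.ones((2, 2), np.uint8))], [], np.zeros((4, 4, 3), np.uint8))

    def test_feathered_blend_stays_within_endpoints(self):
        bg = np.zeros((16, 16, 3), np.uint8)
        m = disc_mask(16, 16, 6)
        tex = np.full((16, 16, 3), 200, np.uint8)
        cfg = CompositionConfig(blend="feathered", feather_radius=3)
        out = compose([patch(m)], [tex], bg, cfg)
        assert out.max() <= 200
        assert np.array_equal(out[~m.astype(bool)], bg[~m.astype(bool)])
        assert out[8, 8, 0] == 200  # deep interior fully replaced


class TestRefinementPairs:
    def _archive_and_images(self, rng, n_images=2, recs_per_image=(0, 3)):
        images, records = {}, []
        for i, n_rec in zip(range(n_images), recs_per_image):
            img_id = f"img_{i}"
            images[img_id] = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
            for _ in range(n_rec):
                m = random_blob_mask(rng, 12, 12)
                x0, y0 = int(rng.integers(0, 20)), int(rng.integers(0, 20))
                records.append(
                    ArchiveRecord(
                        source_image_id=img_id,
                        mask=m,
                        texture=rng.integers(0, 256, (12, 12, 3), dtype=np.uint8),
                        bbox=(x0, y0, x0 + 12, y0 + 12),
                        score=float(rng.uniform()),
                    )
                )
        return PairExtractionArchive(records), images

    def test_image_without_records_round_trips_unchanged(self):
        rng = np.random.default_rng(0)
        archive, images = self._archive_and_images(rng)
        gen = ProceduralTextureGenerator(style=FLAT_STYLE)
        pairs = build_refinement_pairs(archive, gen, images)
        replaced, original = pairs[0]  # img_0 has zero records
        assert np.array_equal(replaced, original)

    def test_changed_pixels_equal_mask_union(self):
        rng = np.random.default_rng(7)
        archive, images = self._archive_and_images(rng, recs_per_image=(3, 2))
        gen = ProceduralTextureGenerator(style=FLAT_STYLE)
        pairs = build_refinement_pairs(archive, gen, images)
        by_image = archive.by_image()
        for (replaced, original), img_id in zip(pairs, sorted(images)):
            union = np.zeros(original.shape[:2], bool)
            for rec in by_image.get(img_id, []):
                x0, y0, x1, y1 = rec.bbox
                union[y0:y1, x0:x1] |= rec.mask.astype(bool)
            changed = np.any(replaced != original, axis=2)
            assert np.all(changed <= union)  # support within the mask union
            # and every mask pixel was overwritten with the generator output
            for rec in by_image.get(img_id, []):
                x0, y0, x1, y1 = rec.bbox
                tex = gen.generate(MaskPatch(0, rec.mask, rec.bbox))
                assert np.array_equal(
                    replaced[y0:y1, x0:x1][rec.mask.astype(bool)],
                    tex[rec.mask.astype(bool)],
                )

    def test_whole_image_record_total_replacement(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        rec = ArchiveRecord(
            source_image_id="a", mask=np.ones((16, 16), np.uint8),
            texture=np.zeros((16, 16, 3), np.uint8), bbox=(0, 0, 16, 16),
        )
        gen = ProceduralTextureGenerator(style=FLAT_STYLE)
        ((replaced, original),) = build_refinement_pairs(
            PairExtractionArchive([rec]), gen, {"a": img}
        )
        assert np.array_equal(original, img)
        expected = gen.generate(MaskPatch(0, rec.mask, rec.bbox))
        assert np.array_equal(replaced, expected)

    def test_missing_source_image_rejected(self):
        rec = ArchiveRecord(
            source_image_id="ghost", mask=np.ones((4, 4), np.uint8),
            texture=np.zeros((4, 4, 3), np.uint8), bbox=(0, 0, 4, 4),
        )
        with pytest.raises(ValueError, match="ghost"):
            build_refinement_pairs(
                PairExtractionArchive([rec]), ProceduralTextureGenerator(), {}
            )

    def test_archive_disk_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        archive, _ = self._archive_and_images(rng, recs_per_image=(2, 1))
        archive.save(tmp_path)
        loaded = PairExtractionArchive.load(tmp_path)
        assert len(loaded.records) == len(archive.records)
        for a, b in zip(
            sorted(archive.records, key=lambda r: r.source_image_id),
            sorted(loaded.records, key=lambda r: r.source_image_id),
        ):
            assert np.array_equal(a.mask.astype(bool), b.mask.astype(bool))
            assert np.array_equal(a.texture, b.texture)
            assert a.bbox == tuple(b.bbox)


class TestObjectives:
    def test_cgan_loss_closed_form_at_half(self):
        v = np.full((4, 4), 0.5)
        assert np.isclose(cgan_loss(v, v), 2 * np.log(0.5), atol=1e-12)

    def test_cgan_loss_supremum_in_perfect_limit(self):
        eps = 1e-12
        val = cgan_loss(np.array([1 - eps]), np.array([eps]))
        assert -1e-9 < val <= 0

    def test_cgan_loss_permutation_invariant(self):
        rng = np.random.default_rng(0)
        d_real = rng.uniform(0.01, 0.99, 32)
        d_fake = rng.uniform(0.01, 0.99, 32)
        assert np.isclose(
            cgan_loss(d_real, d_fake), cgan_loss(rng.permutation(d_real), d_fake)
        )

    def test_cgan_loss_nonpositive_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = rng.uniform(1e-6, 1 - 1e-6, 10)
            b = rng.uniform(1e-6, 1 - 1e-6, 10)
            assert cgan_loss(a, b) <= 0

    def test_cgan_loss_rejects_boundary_values(self):
        with pytest.raises(ValueError):
            cgan_loss(np.array([1.0]), np.array([0.5]))
        with pytest.raises(ValueError):
            cgan_loss(np.array([0.5]), np.array([0.0]))

    def test_l1_identity_and_offset(self):
        a = np.random.default_rng(2).uniform(0, 245, (8, 8, 3))
        assert l1_loss(a, a) == 0.0
        assert np.isclose(l1_loss(a, a + 10.0), 10.0)

    def test_l1_extreme_example(self):
        a = np.array([[0.0, 255.0]])
        b = np.array([[255.0, 0.0]])
        assert l1_loss(a, b) == 255.0

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_l1_is_a_metric_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(0, 255, (3, 4, 4, 3))
        assert np.isclose(l1_loss(a, b), l1_loss(b, a))
        assert l1_loss(a, c) <= l1_loss(a, b) + l1_loss(b, c) + 1e-9

    def test_total_objective_weights(self):
        assert total_objective(0.0, 0.0) == 0.0
        assert np.isclose(total_objective(-1.3863, 10.0), 9.986137)
        assert total_objective(-5.0, 7.0, w_gan=0.0) == 7.0
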