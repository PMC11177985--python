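"""Bullseye rendering, normalization, augmentation and dataset splits."""

import numpy as np
import pytest

from strain2infarct.bullseye import (BullseyeImage, augment_rotations,
                                     compose_channels, decompose_channels,
                                     default_strain_ranges, example_to_image,
                                     render_bullseye, render_mask, resize,
                                     split_dataset, strain_to_intensity)
from strain2infarct.library import (GeneratorConfig, InfarctSpec,
                                    StrainExample, generate_strain_example)

RANGES = {"CC": (-1.0, 1.0), "RR": (-1.0, 1.0), "LL": (-1.0, 1.0)}


def _example(strains):
    return StrainExample(strains=strains, mask=np.zeros((4, 8), np.uint8),
                         spec=InfarctSpec("mid", 0.0, 0.2, 1.0),
                         base_model_id=1, domain="low_fidelity", seed=0)


class TestRendering:
    def test_uniform_field_fills_disc(self):
        ex = _example(np.full((4, 3, 8), 0.37))
        grid = render_bullseye(ex, "CC", size=64)
        inside = grid != 0
        assert np.allclose(grid[inside], 0.37)
        # corners are outside the disc
        assert grid[0, 0] == 0 and grid[-1, -1] == 0

    def test_base_level_occupies_outer_ring_only(self):
        strains = np.zeros((4, 3, 8))
        strains[0, 0, :] = 1.0   # base level, CC component
        grid = render_bullseye(_example(strains), "CC", size=64)
        c = (64 - 1) / 2.0
        R = 32.0
        y, x = np.nonzero(grid)
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2) / R
        assert r.min() > 0.75 - 0.05
        assert r.max() <= 1.0

    def test_ring_boundaries_mid_level_lookup(self):
        strains = np.zeros((4, 3, 8))
        for lvl, val in enumerate((1.0, 2.0, 3.0, 4.0)):  # base..apex
            strains[lvl, 0, :] = val
        size = 128
        grid = render_bullseye(_example(strains), "CC", size=size)
        c = (size - 1) / 2.0
        px = int(round(c + 0.6 * size / 2.0))
        assert grid[int(c), px] == pytest.approx(2.0)  # radius 0.6R -> mid

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            render_bullseye(_example(np.zeros((4, 3, 8))), "XX", 64)

    def test_small_size_rejected(self):
        with pytest.raises(ValueError):
            render_bullseye(_example(np.zeros((4, 3, 8))), "CC", 16)


class TestIntensity:
    def test_affine_endpoints_and_midpoint(self):
        ranges = {"CC": (-0.3, 0.1)}
        assert strain_to_intensity(-0.3, "CC", ranges) == 0.0
        assert strain_to_intensity(0.1, "CC", ranges) == 1.0
        assert strain_to_intensity(-0.1, "CC", ranges) == pytest.approx(0.5)

    def test_clipping(self):
        ranges = {"CC": (0.0, 1.0)}
        assert strain_to_intensity(-2.0, "CC", ranges) == 0.0
        assert strain_to_intensity(3.0, "CC", ranges) == 1.0

    def test_default_ranges_cover_generated_values(self):
        cfg = GeneratorConfig(seed=0)
        ranges = default_strain_ranges(cfg)
        ex = generate_strain_example(InfarctSpec("mid", 1.0, 0.3, 1.0), cfg,
                                     seed=3)
        for k, comp in enumerate(("CC", "RR", "LL")):
            lo, hi = ranges[comp]
            vals = ex.strains[:, k, :]
            assert vals.min() > lo and vals.max() < hi


class TestCompose:
    def test_channel_order(self):
        circ = np.ones((8, 8))
        zero = np.zeros((8, 8))
        img = compose_channels(circ, zero, zero)
        assert img.pixels[..., 0].min() == 1.0
        assert img.pixels[..., 1:].max() == 0.0

    def test_identical_channels_grey(self):
        g = np.random.default_rng(0).random((8, 8))
        img = compose_channels(g, g, g)
        assert np.ptp(img.pixels, axis=-1).max() == 0.0

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        a, b, c = rng.random((3, 8, 8)).astype(np.float32)
        img = compose_channels(a, b, c)
        ra, rb, rc = decompose_channels(img)
        np.testing.assert_array_equal(ra, a)
        np.testing.assert_array_equal(rb, b)
        np.testing.assert_array_equal(rc, c)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_channels(np.zeros((8, 8)), np.zeros((8, 8)),
                             np.zeros((9, 9)))


def _images(n, size=16):
    rng = np.random.default_rng(5)
    out = []
    for i in range(n):
        out.append(BullseyeImage(
            pixels=rng.random((size, size, 3)).astype(np.float32),
            mask=(rng.random((size, size)) > 0.7).astype(np.uint8),
            meta={"source_id": i, "rotation": 0}))
    return out


class TestAugmentation:
    def test_fourfold_increase(self):
        assert len(augment_rotations(_images(148))) == 592

    def test_four_quarter_turns_restore_original(self):
        img = _images(1)[0]
        out = img
        for _ in range(4):
            out = augment_rotations([out])[1]  # the 90-degree copy
        np.testing.assert_array_equal(out.pixels, img.pixels)
        np.testing.assert_array_equal(out.mask, img.mask)

    def test_mask_pixel_count_preserved(self):
        img = _images(1)[0]
        for rot in augment_rotations([img]):
            assert rot.mask.sum() == img.mask.sum()

    def test_rotation_commutes_with_composition(self):
        rng = np.random.default_rng(2)
        a, b, c = rng.random((3, 8, 8)).astype(np.float32)
        composed_then_rotated = augment_rotations(
            [compose_channels(a, b, c)])[1].pixels
        rotated_then_composed = compose_channels(
            np.rot90(a), np.rot90(b), np.rot90(c)).pixels
        np.testing.assert_array_equal(composed_then_rotated,
                                      rotated_then_composed)

    def test_non_square_rejected(self):
        img = BullseyeImage(pixels=np.zeros((8, 10, 3), np.float32),
                            mask=np.zeros((8, 10), np.uint8))
        with pytest.raises(ValueError):
            augment_rotations([img])


class TestResize:
    def test_identity(self):
        img = _images(1)[0]
        out = resize(img, img.size)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = BullseyeImage(pixels=np.full((16, 16, 3), 0.25, np.float32),
                            mask=np.ones((16, 16), np.uint8))
        out = resize(img, 32)
        np.testing.assert_allclose(out.pixels, 0.25, atol=1e-6)

    def test_mask_stays_binary(self):
        img = _images(1)[0]
        for target in (32, 64):
            out = resize(img, target)
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            resize(_images(1)[0], 15)


class TestSplit:
    def test_all_train(self):
        split = split_dataset(_images(10), (1.0, 0.0, 0.0), seed=0)
        assert len(split.train) == 10 and not split.val and not split.test

    def test_deterministic(self):
        imgs = augment_rotations(_images(12))
        a = split_dataset(imgs, seed=3)
        b = split_dataset(imgs, seed=3)
        assert [i.meta["source_id"] for i in a.train] == \
            [i.meta["source_id"] for i in b.train]

    def test_groups_never_straddle_splits(self):
        imgs = augment_rotations(_images(12))
        split = split_dataset(imgs, (0.5, 0.25, 0.25), seed=1)
        sets = [set(i.meta["source_id"] for i in part)
                for part in (split.train, split.val, split.test)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_images(4), (0.5, 0.2, 0.2), seed=0)


class TestFullPreprocessing:
    def test_pixels_normalized_background_zero(self):
        cfg = GeneratorConfig(seed=0)
        ex = generate_strain_example(InfarctSpec("mid", 1.0, 0.3, 1.0), cfg,
                                     seed=2)
        img = example_to_image(ex, size=64, config=cfg, source_id=0)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        assert img.pixels[0, 0].max() == 0.0      # corner outside the disc
        assert img.mask[0, 0] == 0
        assert img.pixels.shape == (64, 64, 3)

    def test_mask_rendered_on_same_geometry(self):
        cfg = GeneratorConfig(seed=0)
        ex = generate_strain_example(InfarctSpec("mid", 1.0, 0.4, 1.0), cfg,
                                     seed=2)
        m = render_mask(ex, size=64)
        assert set(np.unique(m)) <= {0, 1}
        assert m.sum() > 0
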