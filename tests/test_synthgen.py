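"""Synthetic scene generator: determinism, degradation axes, coverage."""

import numpy as np
import pytest

from rfilm.dataio import load_pair, read_manifest
from rfilm.synthgen import (
    GenerationError,
    SceneConfig,
    generate_dataset,
    make_background,
    render_scene,
    sample_fragments,
)


def shoelace(poly):
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


class TestBackground:
    def test_degenerate_config_is_plain_soil(self):
        cfg = SceneConfig(straw_density=0, clod_density=0, weather="cloudy", seed=3)
        img = make_background(cfg, np.random.default_rng(cfg.seed)).pixels.astype(float)
        # only tonal drift + grain remain: spread stays within their amplitudes
        assert img.std() < 25
        assert (img > 240).sum() == 0

    def test_same_seed_is_bit_identical(self):
        cfg = SceneConfig(seed=5)
        a = make_background(cfg, np.random.default_rng(9)).pixels
        b = make_background(cfg, np.random.default_rng(9)).pixels
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_sunny_has_more_near_saturated_pixels(self, seed):
        sunny = make_background(SceneConfig(weather="sunny"), np.random.default_rng(seed))
        cloudy = make_background(SceneConfig(weather="cloudy"), np.random.default_rng(seed))
        assert (sunny.pixels > 240).sum() > (cloudy.pixels > 240).sum()

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(image_height_px=0)


class TestFragments:
    def test_zero_rate_gives_empty_list(self):
        cfg = SceneConfig(fragment_count_mean=0)
        assert sample_fragments(cfg, np.random.default_rng(0)) == []

    def test_area_scales_with_ground_sampling_distance(self):
        """Fragment areas at 9 m are (5/9)^2 of their 5 m counterparts."""
        cfg5 = SceneConfig(height_m=5, seed=2)
        cfg9 = SceneConfig(height_m=9, seed=2)
        f5 = sample_fragments(cfg5, np.random.default_rng(2))
        f9 = sample_fragments(cfg9, np.random.default_rng(2))
        assert len(f5) == len(f9) > 0
        for a, b in zip(f5, f9):
            assert shoelace(b) / shoelace(a) == pytest.approx(25 / 81, rel=1e-6)

    def test_mean_fragment_area_decreases_with_height(self):
        areas = {}
        for h in (5, 7, 9):
            cfg = SceneConfig(height_m=h, seed=4)
            frags = sample_fragments(cfg, np.random.default_rng(4))
            areas[h] = np.mean([shoelace(f) for f in frags])
        assert areas[5] > areas[7] > areas[9]

    def test_poisson_count_moment(self):
        """Sample mean count over 1000 draws sits within 3 SE of the rate."""
        cfg = SceneConfig(fragment_count_mean=4)
        rng = np.random.default_rng(8)
        counts = [len(sample_fragments(cfg, rng)) for _ in range(1000)]
        se = np.sqrt(4 / 1000)
        assert abs(np.mean(counts) - 4) < 3 * se

    def test_empty_area_range_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(fragment_area_px_range=(100, 40))


class TestRenderScene:
    def test_mask_coverage_consistency(self):
        scene = render_scene(SceneConfig(seed=6))
        expected = 100.0 * scene.mask.labels.sum() / scene.mask.labels.size
        assert scene.realized_coverage_pct == expected
        assert scene.image.shape == scene.mask.shape

    def test_determinism(self):
        a = render_scene(SceneConfig(seed=7))
        b = render_scene(SceneConfig(seed=7))
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.mask.labels, b.mask.labels)

    def test_target_coverage_zero(self):
        scene = render_scene(SceneConfig(target_coverage_pct=0, seed=1))
        assert scene.realized_coverage_pct == 0
        assert scene.mask.labels.sum() == 0

    def test_target_coverage_reached_within_half_point(self):
        scene = render_scene(SceneConfig(target_coverage_pct=10, seed=1))
        assert abs(scene.realized_coverage_pct - 10) <= 0.5

    def test_near_full_coverage_reachable_on_small_frame(self):
        cfg = SceneConfig(
            image_height_px=64, image_width_px=64, target_coverage_pct=100, seed=2
        )
        scene = render_scene(cfg)
        assert scene.realized_coverage_pct >= 99.5

    def test_unreachable_target_names_achieved_value(self):
        cfg = SceneConfig(
            fragment_area_px_range=(40000, 40001), target_coverage_pct=3, seed=0
        )
        with pytest.raises(GenerationError, match="closest achieved"):
            render_scene(cfg)


class TestGenerateDataset:
    def test_balanced_grid_six_images(self, tmp_path):
        cfg = SceneConfig(image_height_px=64, image_width_px=64)
        manifest = generate_dataset(6, cfg, tmp_path, seed=0)
        rows = read_manifest(manifest)
        cells = {(r["weather"], r["height_m"]) for r in rows}
        assert len(cells) == 6

    def test_manifest_round_trip_and_mask_alphabet(self, tmp_path):
        cfg = SceneConfig(image_height_px=64, image_width_px=64)
        generate_dataset(3, cfg, tmp_path, seed=1)
        rows = read_manifest(tmp_path / "manifest.csv")
        for row in rows:
            img, msk = load_pair(
                tmp_path / "images" / row["filename"], tmp_path / "masks" / row["filename"]
            )
            cov = 100.0 * msk.labels.sum() / msk.labels.size
            assert cov == pytest.approx(row["true_coverage_pct"], abs=1e-6)

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SceneConfig(image_height_px=64, image_width_px=64)
        m1 = generate_dataset(4, cfg, tmp_path / "a", seed=3)
        m2 = generate_dataset(4, cfg, tmp_path / "b", seed=3)
        assert m1.read_bytes() == m2.read_bytes()
        for name in ("scene_00000.png", "scene_00003.png"):
            assert (tmp_path / "a" / "images" / name).read_bytes() == (
                tmp_path / "b" / "images" / name
            ).read_bytes()
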