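"""Renderer and generator contracts: determinism, green-dominance,
component-count oracles, label ranges, coverage and class geometry."""


import numpy as np
import pytest
from scipy import ndimage

from phenonet import (
    AGE_RANGE_HOURS,
    ARABIDOPSIS_COUNT_RANGE,
    TOBACCO_COUNT_RANGE,
    CapacityError,
    ConfigurationError,
    RenderConfig,
    RosettePhenotype,
    generate_dataset,
    green_dominant_mask,
    load_ippn_dataset,
    render_rosette,
    save_dataset,
)


def n_green_components(image) -> int:
    return ndimage.label(green_dominant_mask(image))[1]


class TestRenderRosette:
    def test_single_leaf_single_green_region(self, single_rosette):
        assert n_green_components(single_rosette.image) == 1

    def test_deterministic_under_fixed_seed(self, plain_config):
        phen = RosettePhenotype(leaf_count=7, age_hours=450)
        a = render_rosette(phen, plain_config)
        b = render_rosette(phen, plain_config)
        assert np.array_equal(a.image, b.image)

    @pytest.mark.parametrize("count", [5, 9, 12])
    def test_component_count_matches_leaf_count_when_disjoint(self, count, plain_config):
        # the count oracle: noise-free renders at moderate density keep
        # blades disjoint, so connected green regions == generative count
        phen = RosettePhenotype(leaf_count=count, age_hours=500)
        sample = render_rosette(phen, plain_config)
        assert n_green_components(sample.image) == count

    def test_leaf_pixels_green_dominant_before_noise(self, plain_config):
        sample = render_rosette(RosettePhenotype(leaf_count=8, age_hours=600), plain_config)
        mask = green_dominant_mask(sample.image)
        assert mask.sum() > 0
        img = sample.image.astype(int)
        assert (img[mask][:, 1] > img[mask][:, 0]).all()
        assert (img[mask][:, 1] > img[mask][:, 2]).all()

    def test_leaf_area_increases_with_age(self, plain_config):
        areas = []
        for age in (392, 480, 560, 620):
            s = render_rosette(RosettePhenotype(leaf_count=6, age_hours=age), plain_config)
            areas.append(green_dominant_mask(s.image).sum())
        assert areas == sorted(areas)
        assert areas[0] < areas[-1]

    def test_capacity_error_when_frame_too_small(self):
        cfg = RenderConfig(image_size=32, background_style="plain", noise_sd=0.0)
        with pytest.raises(CapacityError):
            render_rosette(RosettePhenotype(leaf_count=20, age_hours=500), cfg)

    def test_image_size_below_minimum_rejected(self):
        cfg = RenderConfig(image_size=16)
        with pytest.raises(ConfigurationError):
            render_rosette(RosettePhenotype(leaf_count=3, age_hours=500), cfg)

    def test_margin_zero_renders_all_classes_identically(self):
        cfg = RenderConfig(image_size=64, class_margin=0.0, noise_sd=0.0,
                           background_style="plain", seed=3)
        imgs = [
            render_rosette(
                RosettePhenotype(leaf_count=6, age_hours=500, class_index=c), cfg
            ).image
            for c in range(5)
        ]
        for other in imgs[1:]:
            assert np.array_equal(imgs[0], other)

    def test_classes_differ_at_positive_margin(self):
        cfg = RenderConfig(image_size=64, class_margin=1.0, noise_sd=0.0,
                           background_style="plain", seed=3)
        imgs = [
            render_rosette(
                RosettePhenotype(leaf_count=6, age_hours=500, class_index=c), cfg
            ).image
            for c in (0, 2)
        ]
        assert not np.array_equal(imgs[0], imgs[1])


class TestGenerateDataset:
    def test_a2_scale_dataset_counts_in_range(self):
        samples = generate_dataset(
            165, "count", "arabidopsis_like", RenderConfig(image_size=64, seed=0), seed=5
        )
        assert len(samples) == 165
        labels = [s.label for s in samples]
        lo, hi = ARABIDOPSIS_COUNT_RANGE
        assert all(lo <= v <= hi for v in labels)

    def test_tobacco_counts_in_range(self):
        samples = generate_dataset(
            30, "count", "tobacco_like", RenderConfig(image_size=64, seed=0), seed=5
        )
        lo, hi = TOBACCO_COUNT_RANGE
        assert all(lo <= s.label <= hi for s in samples)

    def test_singleton_dataset(self):
        samples = generate_dataset(
            1, "count", "arabidopsis_like", RenderConfig(image_size=64, seed=0), seed=5
        )
        assert len(samples) == 1
        assert samples[0].image.shape == (64, 64, 3)

    def test_different_seeds_give_different_labels(self):
        cfg = RenderConfig(image_size=64, seed=0)
        a = [s.label for s in generate_dataset(200, "count", "arabidopsis_like", cfg, seed=8)]
        b = [s.label for s in generate_dataset(200, "count", "arabidopsis_like", cfg, seed=9)]
        assert a != b

    def test_generation_is_pure_function_of_inputs(self):
        cfg = RenderConfig(image_size=64, seed=0)
        a = generate_dataset(5, "age", "arabidopsis_like", cfg, seed=21)
        b = generate_dataset(5, "age", "arabidopsis_like", cfg, seed=21)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image, sb.image)
            assert sa.label == sb.label

    def test_label_coverage_of_count_range(self):
        samples = generate_dataset(
            50, "count", "arabidopsis_like", RenderConfig(image_size=64, seed=0), seed=13
        )
        lo, hi = ARABIDOPSIS_COUNT_RANGE
        span = hi - lo + 1
        covered = len({int(s.label) for s in samples})
        assert covered >= 0.8 * span

    def test_ages_in_default_range_and_correlated_with_count(self):
        samples = generate_dataset(
            200, "age", "arabidopsis_like", RenderConfig(image_size=64, seed=0), seed=17
        )
        ages = np.array([s.label for s in samples])
        counts = np.array([s.phenotype.leaf_count for s in samples])
        a0, a1 = AGE_RANGE_HOURS
        assert ages.min() >= a0 and ages.max() <= a1
        corr = np.corrcoef(counts, ages)[0, 1]
        assert 0.3 < corr < 0.9  # positive, configured around 0.6

    def test_unknown_task_or_style_rejected(self):
        cfg = RenderConfig(image_size=64)
        with pytest.raises(ConfigurationError):
            generate_dataset(5, "segmentation", "arabidopsis_like", cfg, seed=0)
        with pytest.raises(ConfigurationError):
            generate_dataset(5, "count", "maize_like", cfg, seed=0)


class TestPersistence:
    def test_round_trip_preserves_labels(self, tmp_path):
        cfg = RenderConfig(image_size=64, seed=0)
        samples = generate_dataset(8, "count", "arabidopsis_like", cfg, seed=31)
        out = save_dataset(samples, tmp_path / "ds")
        loaded = load_ippn_dataset(out, out / "Leaf_counts.csv", "count")
        assert len(loaded) == 8
        by_id = {s.id: s for s in loaded}
        for s in samples:
            assert by_id[f"{s.id}_rgb"].label == s.label

    def test_rewrite_same_seed_is_byte_identical(self, tmp_path):
        cfg = RenderConfig(image_size=64, seed=0)
        for d in ("a", "b"):
            samples = generate_dataset(4, "count", "arabidopsis_like", cfg, seed=31)
            save_dataset(samples, tmp_path / d)
        for name in ("Leaf_counts.csv", "Ages.csv", "Classes.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
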