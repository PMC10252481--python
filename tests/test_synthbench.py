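"""Synthetic benchmark: plateau landscape, VF images, dataset, CNN objective."""

import numpy as np
import pytest

from swarmbo.refdata import VF_CLASS_COUNTS
from swarmbo.space import define_vgg_space
from swarmbo.synthbench import (DEFAULT_BASINS, PlateauObjective,
                                PlateauParams, VF_CLASSES, VFDataset,
                                cnn_objective, generate_vf_dataset,
                                generate_vf_image, plateau_objective)


def config_at_basin(space, basin, **overrides):
    """A configuration sitting exactly at a basin centre with matching gates."""
    config = {}
    for p in space:
        if p.name in basin.gates:
            config[p.name] = basin.gates[p.name]
        elif p.name in basin.center:
            config[p.name] = p.from_unit(basin.center[p.name])
        elif p.is_categorical:
            config[p.name] = p.categories[0]
        else:
            config[p.name] = p.from_unit(0.5)
    config.update(overrides)
    return config


class TestPlateauObjective:
    def test_nonmatching_gate_scores_exact_baseline(self, vgg_space):
        basin = DEFAULT_BASINS[0]
        config = config_at_basin(vgg_space, basin, activation="Sigmoid")
        assert plateau_objective(config) == 20.55

    def test_basin_centre_scores_exact_peak(self, vgg_space):
        config = config_at_basin(vgg_space, DEFAULT_BASINS[0])
        assert plateau_objective(config) == pytest.approx(98.6, abs=1e-9)

    def test_value_at_one_length_scale(self, vgg_space):
        basin = DEFAULT_BASINS[0]
        params = PlateauParams()
        lr = vgg_space["learning_rate"]
        off = lr.from_unit(basin.center["learning_rate"] + params.length_scale)
        config = config_at_basin(vgg_space, basin, learning_rate=off)
        expected = 20.55 + (98.6 - 20.55) * np.exp(-0.5)
        assert plateau_objective(config) == pytest.approx(expected, rel=1e-9)

    def test_mostly_plateau_fraction(self, vgg_space):
        obj = PlateauObjective(vgg_space)
        rng = np.random.default_rng(17)
        vals = np.array([obj.noiseless(c) for c in vgg_space.sample(10_000, rng)])
        frac = (vals > 20.55 + 1).mean()
        assert 0.005 <= frac <= 0.20

    def test_noise_is_seeded_and_resettable(self, vgg_space):
        params = PlateauParams(noise_sd=1.0, seed=5)
        obj = PlateauObjective(vgg_space, params)
        config = config_at_basin(vgg_space, DEFAULT_BASINS[1])
        a = [obj(config) for _ in range(3)]
        obj.reset_noise(5)
        b = [obj(config) for _ in range(3)]
        assert a == b
        assert len(set(a)) == 3  # noise actually varies between calls

    def test_range_bounded_without_noise(self, vgg_space):
        obj = PlateauObjective(vgg_space)
        rng = np.random.default_rng(3)
        vals = [obj.noiseless(c) for c in vgg_space.sample(500, rng)]
        assert min(vals) >= 20.55 and max(vals) <= 98.6

    def test_noisy_range_clipped_to_four_sigma(self, vgg_space):
        obj = PlateauObjective(vgg_space, PlateauParams(noise_sd=5.0, seed=1))
        rng = np.random.default_rng(4)
        vals = [obj(c) for c in vgg_space.sample(300, rng)]
        assert min(vals) >= 20.55 - 20.0 and max(vals) <= 98.6 + 20.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PlateauParams(baseline=99.0, peak=98.0)
        with pytest.raises(ValueError):
            PlateauParams(length_scale=0.0)
        with pytest.raises(ValueError):
            PlateauParams(basins=())


class TestVfImages:
    def test_normal_images_have_almost_no_dark_pixels(self):
        # background N(0.8, 0.05): P(pixel < 0.5) = Phi(-6) ~ 1e-9
        rng = np.random.default_rng(0)
        frac = np.mean([
            (generate_vf_image("normal", 32, rng).grid < 0.5).mean()
            for _ in range(100)])
        assert frac <= 0.01

    def test_tunnel_and_central_scotoma_masks_are_complementary(self):
        a = generate_vf_image("central_scotoma", 32, np.random.default_rng(9))
        b = generate_vf_image("tunnel", 32, np.random.default_rng(9))
        dark_a = a.grid < 0.5
        dark_b = b.grid < 0.5
        # identical seeds draw the same radius, so the dark regions tile the
        # grid (up to rare noise excursions)
        assert (dark_a ^ dark_b).mean() > 0.95

    def test_same_seed_same_grid(self):
        a = generate_vf_image("hemianopia", 32, np.random.default_rng(4))
        b = generate_vf_image("hemianopia", 32, np.random.default_rng(4))
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_values_in_unit_interval_and_label_checked(self):
        img = generate_vf_image("quadrantanopia", 24, np.random.default_rng(1))
        assert img.grid.min() >= 0 and img.grid.max() <= 1
        with pytest.raises(ValueError):
            generate_vf_image("glaucoma", 32, np.random.default_rng(0))


class TestVfDataset:
    def test_reference_total_reproduces_reference_class_counts(self):
        data = generate_vf_dataset(1268, rng=np.random.default_rng(0), size=8)
        assert data.class_counts() == VF_CLASS_COUNTS

    def test_uniform_sixty_splits_eight_one_one(self):
        data = generate_vf_dataset(60, proportions=[1 / 6] * 6,
                                   rng=np.random.default_rng(1), size=8)
        for cls in VF_CLASSES:
            idx = [i for i, l in enumerate(data.labels) if l == cls]
            parts = [data.split[i] for i in idx]
            assert len(idx) == 10
            assert parts.count("train") == 8
            assert parts.count("val") == 1
            assert parts.count("test") == 1

    def test_split_sizes_conserve_n(self):
        for n in (61, 100, 317):
            data = generate_vf_dataset(n, rng=np.random.default_rng(2), size=8)
            assert len(data) == n
            assert (data.split.count("train") + data.split.count("val")
                    + data.split.count("test")) == n

    def test_split_fractions_stratified_within_one(self):
        data = generate_vf_dataset(300, rng=np.random.default_rng(3), size=8)
        for cls, m in data.class_counts().items():
            idx = [i for i, l in enumerate(data.labels) if l == cls]
            parts = [data.split[i] for i in idx]
            assert abs(parts.count("val") - 0.1 * m) <= 1
            assert abs(parts.count("test") - 0.1 * m) <= 1

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            generate_vf_dataset(100, proportions=[0.5] * 6)
        with pytest.raises(ValueError):
            generate_vf_dataset(10)

    def test_png_csv_round_trip(self, tmp_path):
        data = generate_vf_dataset(60, proportions=[1 / 6] * 6,
                                   rng=np.random.default_rng(5), size=8)
        data.save(tmp_path)
        back = VFDataset.load(tmp_path)
        assert back.labels == data.labels
        assert back.split == data.split
        # 8-bit quantization on disk
        assert np.abs(back.images - data.images).max() <= 1 / 255 + 1e-12


class TestCnnObjective:
    @pytest.fixture(scope="class")
    def small_data(self):
        return generate_vf_dataset(120, proportions=[1 / 6] * 6,
                                   rng=np.random.default_rng(8), size=16)

    def test_untrained_network_scores_near_chance(self, small_data):
        config = dict(feature_map=16, filter_size=2, activation="ReLU",
                      pool_size=2, optimizer="SGD", learning_rate=0.01,
                      batch_size=8, epoch=10, dropout_rate=0.2,
                      upper_layer="TRUE", lower_layer="TRUE")
        acc = cnn_objective(config, small_data, budget_scale=0.0, seed=0,
                            pretrain_steps=0)
        assert 0.0 <= acc <= 100.0
        # 6-class chance is ~16.7%; a 12-image validation split is noisy
        assert 0.0 <= acc <= 60.0

    def test_frozen_network_is_deterministic(self, small_data):
        config = dict(feature_map=16, filter_size=2, activation="ReLU",
                      pool_size=2, optimizer="ADAM", learning_rate=0.001,
                      batch_size=8, epoch=10, dropout_rate=0.2,
                      upper_layer="FALSE", lower_layer="FALSE")
        a = cnn_objective(config, small_data, budget_scale=0.0, seed=3,
                          pretrain_steps=0)
        b = cnn_objective(config, small_data, budget_scale=0.0, seed=3,
                          pretrain_steps=0)
        assert a == b

    def test_short_training_run_returns_finite_percent(self, small_data):
        config = dict(feature_map=16, filter_size=3, activation="ReLU",
                      pool_size=2, optimizer="ADAM", learning_rate=0.003,
                      batch_size=16, epoch=20, dropout_rate=0.3,
                      upper_layer="TRUE", lower_layer="FALSE")
        acc = cnn_objective(config, small_data, budget_scale=0.1, seed=1,
                            pretrain_steps=5)
        assert np.isfinite(acc) and 0.0 <= acc <= 100.0
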