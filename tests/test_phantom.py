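"""Phantom generator: determinism, noise statistics, drift oracles."""

import numpy as np
import pytest
from scipy import ndimage

from octa3d.exceptions import ConfigurationError, ValidationError
from octa3d.phantom import (
    DriftParams,
    PhantomConfig,
    add_speckle,
    avascular_cscan,
    generate_clean_volume,
    simulate_repeat_acquisitions,
)


class TestGenerateCleanVolume:
    def test_no_trees_gives_empty_volume(self):
        vol, mask = generate_clean_volume(PhantomConfig(n_trees=0, shape=(16, 32, 32)))
        assert not vol.any()
        assert not mask.any()

    def test_deterministic_for_fixed_seed(self):
        cfg = PhantomConfig(shape=(16, 32, 32), seed=5)
        v1, m1 = generate_clean_volume(cfg)
        v2, m2 = generate_clean_volume(cfg)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(m1, m2)

    def test_zero_attenuation_gives_uniform_vessel_intensity(self):
        cfg = PhantomConfig(shape=(16, 64, 64), attenuation_coeff=0.0, seed=2)
        vol, mask = generate_clean_volume(cfg)
        assert mask.any()
        values = np.unique(vol[mask])
        assert values.size == 1
        assert values[0] == pytest.approx(cfg.vessel_intensity)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(shape=(4, 32, 32))

    def test_mask_fraction_monotone_in_n_trees(self):
        fractions = [
            generate_clean_volume(PhantomConfig(shape=(16, 64, 64), n_trees=n, seed=9))[1].mean()
            for n in (2, 5, 10)
        ]
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_intensities_within_unit_range(self, clean_volume):
        vol, _ = clean_volume
        assert vol.min() >= 0.0 and vol.max() <= 1.0


class TestAddSpeckle:
    def test_zero_volume_zero_background_stays_zero(self):
        cfg = PhantomConfig(shape=(8, 16, 16), background_level=0.0)
        out = add_speckle(np.zeros((8, 16, 16)), cfg, seed=0)
        assert not out.any()

    def test_huge_shape_parameter_recovers_input(self):
        cfg = PhantomConfig(shape=(8, 16, 16), speckle_shape=1e6, background_level=0.0,
                            speckle_grain=(1, 1, 1))
        vol = np.full((8, 16, 16), 0.5)
        out = add_speckle(vol, cfg, seed=1)
        assert np.abs(out - vol).max() < 0.01 * vol.max()

    def test_deterministic(self):
        cfg = PhantomConfig(shape=(8, 16, 16))
        vol = np.random.default_rng(0).random((8, 16, 16)) * 0.5
        np.testing.assert_array_equal(add_speckle(vol, cfg, 7), add_speckle(vol, cfg, 7))

    def test_rejects_non_finite(self):
        cfg = PhantomConfig(shape=(8, 16, 16))
        bad = np.zeros((8, 16, 16))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            add_speckle(bad, cfg, 0)

    def test_signal_exceeds_background_after_noise(self, phantom_config, clean_volume):
        clean, mask = clean_volume
        noisy = add_speckle(clean, phantom_config, seed=4)
        assert noisy[mask].mean() > noisy[~mask].mean()


class TestRepeatAcquisitions:
    def test_zero_drift_single_repeat_is_pure_noise_pass(self, phantom_config, clean_volume):
        clean, _ = clean_volume
        reps = simulate_repeat_acquisitions(
            clean, 1, DriftParams(max_shift=0.0, max_rotation=0.0, seed=21), phantom_config)
        assert len(reps) == 1
        np.testing.assert_array_equal(
            reps[0].volume, add_speckle(clean, phantom_config, seed=reps[0].noise_seed))
        np.testing.assert_array_equal(reps[0].matrix, np.eye(3))

    def test_repeats_are_pairwise_different(self, drifting_repeats):
        for i in range(len(drifting_repeats)):
            for j in range(i + 1, len(drifting_repeats)):
                assert not np.array_equal(drifting_repeats[i].volume,
                                          drifting_repeats[j].volume)

    def test_returned_transform_round_trips(self, phantom_config, clean_volume):
        """Warping the clean volume forward with the returned matrix and
        back with its inverse reproduces the interior of the original."""
        clean, _ = clean_volume
        reps = simulate_repeat_acquisitions(
            clean, 3, DriftParams(max_shift=3.0, max_rotation=1.5, seed=31), phantom_config)
        for rep in reps:
            inv = np.linalg.inv(rep.matrix)
            z = clean.shape[0] // 2
            fwd = ndimage.affine_transform(clean[z], inv[:2, :2], offset=inv[:2, 2], order=1)
            back = ndimage.affine_transform(fwd, rep.matrix[:2, :2],
                                            offset=rep.matrix[:2, 2], order=1)
            interior = (slice(8, -8), slice(8, -8))
            assert np.abs(back[interior] - clean[z][interior]).max() < 0.35
            assert np.abs(back[interior] - clean[z][interior]).mean() < 0.01

    def test_rejects_nonpositive_repeat_count(self, phantom_config, clean_volume):
        with pytest.raises(ValidationError):
            simulate_repeat_acquisitions(clean_volume[0], 0, DriftParams(), phantom_config)


class TestAvascularCscan:
    def test_zero_background_is_black(self):
        cfg = PhantomConfig(shape=(8, 32, 32), background_level=0.0)
        assert not avascular_cscan(cfg, seed=0).any()

    def test_mean_matches_background_level(self):
        """Monte-Carlo: sample mean within 3 standard errors of the
        configured mean, accounting for the noise grain (one independent
        draw per grain cell)."""
        cfg = PhantomConfig(shape=(8, 128, 128))
        means = [avascular_cscan(cfg, seed=s).mean() for s in range(10)]
        gy, gx = cfg.speckle_grain[1:]
        n_indep = 10 * (128 // gy) * (128 // gx)
        se = (cfg.background_level / np.sqrt(3.0)) / np.sqrt(n_indep)
        assert abs(np.mean(means) - cfg.background_level) < 3 * se

    def test_deterministic(self):
        cfg = PhantomConfig(shape=(8, 32, 32))
        np.testing.assert_array_equal(avascular_cscan(cfg, 3), avascular_cscan(cfg, 3))
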