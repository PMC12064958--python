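"""Adversarial model: loss closed forms, architecture contracts, training
bookkeeping and checkpoint determinism."""

import numpy as np
import pytest

from octa3d import gan
from octa3d.exceptions import ValidationError
from octa3d.synthesis import TrainingPair


def _tiny_gen_spec():
    return gan.GeneratorSpec(n_levels=3, base_channels=4, max_channels=8)


def _tiny_disc_spec():
    return gan.DiscriminatorSpec(base_channels=4, n_blocks=1, max_channels=8)


def _tiny_dataset(rng, n=2, size=16):
    return [TrainingPair(input=rng.random((size, size)), label=rng.random((size, size)))
            for _ in range(n)]


class TestLosses:
    def test_content_loss_zero_for_identical_images(self, rng):
        img = rng.random((8, 8))
        assert gan.content_loss(img, img) == 0.0

    def test_content_loss_equals_constant_offset(self, rng):
        img = rng.random((8, 8)) * 0.4
        assert gan.content_loss(img, img + 0.5) == pytest.approx(0.5)

    def test_content_loss_matches_scalar_loop_oracle(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        acc = 0.0
        for i in range(8):
            for j in range(8):
                acc += abs(a[i, j] - b[i, j])
        assert gan.content_loss(a, b) == pytest.approx(acc / 64, abs=1e-12)

    def test_adversarial_loss_closed_form_at_half(self):
        assert gan.adversarial_loss(0.5) == pytest.approx(np.log(0.5))

    def test_adversarial_loss_limits(self):
        assert gan.adversarial_loss(1e-12) == pytest.approx(0.0, abs=1e-9)
        assert gan.adversarial_loss(1.0) == pytest.approx(np.log(gan.EPS))

    def test_generator_loss_direct_substitution(self):
        assert gan.generator_loss(0.1, -0.7, 1000.0) == pytest.approx(99.3)
        assert gan.generator_loss(0.3, -0.2, 0.0) == pytest.approx(-0.2)
        assert gan.generator_loss(0.0, 0.0, 1000.0) == 0.0

    def test_discriminator_loss_closed_forms(self):
        assert gan.discriminator_loss(0.5, 0.5) == pytest.approx(-2 * np.log(0.5))
        near_perfect = gan.discriminator_loss(1.0 - 1e-9, 1e-9)
        assert abs(near_perfect) < 1e-6

    def test_discriminator_loss_monotonicity(self):
        """Finite differences: loss decreases in D(label), increases in
        D(generated)."""
        base = gan.discriminator_loss(0.6, 0.4)
        assert gan.discriminator_loss(0.61, 0.4) < base
        assert gan.discriminator_loss(0.6, 0.41) > base

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            gan.content_loss(rng.random((4, 4)), rng.random((5, 5)))


class TestArchitectureContracts:
    @pytest.mark.parametrize("size,n_levels", [(64, 6), (128, 6), (256, 8)])
    def test_generator_preserves_spatial_shape(self, size, n_levels):
        spec = gan.GeneratorSpec(n_levels=n_levels, base_channels=4, max_channels=16)
        g = gan.build_generator(spec, seed=0, dtype=np.float32)
        out = g.forward(np.random.default_rng(0).random((size, size)), train=True)
        assert out.shape == (size, size)
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_indivisible_size_rejected(self):
        g = gan.build_generator(_tiny_gen_spec(), seed=0)
        with pytest.raises(ValidationError, match="divisible"):
            g.forward(np.zeros((12, 12)))

    def test_discriminator_output_sizes_match_conv_arithmetic(self):
        """The stated stack (entry conv + n blocks, all 4x4/s2/p1, then a
        4x4/s2/p0 head) must reproduce the sizes given by the convolution
        arithmetic (h + 2p - k)//s + 1 at every stage."""

        def expected_output(size, n_blocks):
            for _ in range(1 + n_blocks):
                size = (size + 2 - 4) // 2 + 1
            return (size - 4) // 2 + 1

        d64 = gan.build_discriminator(
            gan.DiscriminatorSpec(base_channels=4, n_blocks=3, max_channels=8),
            seed=0, dtype=np.float32)
        out = d64.forward(np.random.default_rng(0).random((64, 64)))
        assert out.shape == (expected_output(64, 3),) * 2 == (1, 1)

        d256 = gan.build_discriminator(
            gan.DiscriminatorSpec(base_channels=2, n_blocks=5, max_channels=4),
            seed=0, dtype=np.float32)
        out = d256.forward(np.random.default_rng(0).random((256, 256)))
        assert out.shape == (expected_output(256, 5),) * 2 == (1, 1)

    def test_discriminator_output_strictly_inside_unit_interval(self, rng):
        d = gan.build_discriminator(_tiny_disc_spec(), seed=1)
        p = d.forward(rng.random((16, 16)))
        assert ((p > 0) & (p < 1)).all()

    def test_discriminator_not_constant(self, rng):
        d = gan.build_discriminator(_tiny_disc_spec(), seed=1)
        p1 = d.forward(np.zeros((16, 16)), train=True)
        p2 = d.forward(rng.random((16, 16)), train=True)
        assert not np.allclose(p1, p2)

    def test_discriminator_too_small_input_rejected(self):
        d = gan.build_discriminator(gan.DiscriminatorSpec(base_channels=2, n_blocks=5,
                                                          max_channels=4), seed=0)
        with pytest.raises(ValidationError):
            d.forward(np.zeros((16, 16)))

    def test_channel_progression_doubles_to_cap(self):
        spec = gan.GeneratorSpec(n_levels=6, base_channels=64, max_channels=512)
        assert spec.channels() == [64, 128, 256, 512, 512, 512]


class TestTraining:
    def test_one_epoch_bookkeeping(self, rng):
        dataset = _tiny_dataset(rng, n=2)
        steps: list = []
        _, records = gan.train(
            dataset, gan.TrainConfig(epochs=1, seed=0, augment=False),
            gen_spec=_tiny_gen_spec(), disc_spec=_tiny_disc_spec(),
            dtype=np.float32, step_records=steps)
        assert len(records) == 1
        assert records[0].n_steps == 2
        assert len(steps) == 2  # one G and one D update logged per sample

    def test_g_loss_identity_holds_every_step(self, rng):
        steps: list = []
        _, records = gan.train(
            _tiny_dataset(rng, n=3), gan.TrainConfig(epochs=2, seed=1, augment=True),
            gen_spec=_tiny_gen_spec(), disc_spec=_tiny_disc_spec(),
            dtype=np.float32, step_records=steps)
        lam = 1e3
        for _, _, g, c, a, _ in steps:
            assert g == lam * c + a  # exact identity by construction
        for r in records:
            assert r.g_loss == lam * r.content_loss + r.adversarial_loss

    def test_training_reduces_content_loss_on_tiny_task(self, rng):
        """A few epochs on a constant mapping task must reduce the L1
        content loss."""
        label = np.zeros((16, 16))
        dataset = [TrainingPair(input=rng.random((16, 16)), label=label) for _ in range(4)]
        _, records = gan.train(
            dataset, gan.TrainConfig(epochs=10, seed=0, augment=False),
            gen_spec=_tiny_gen_spec(), disc_spec=_tiny_disc_spec(), dtype=np.float32)
        assert records[-1].content_loss < records[0].content_loss

    def test_checkpoint_resume_is_bit_for_bit(self, rng, tmp_path):
        """Training 2 epochs straight equals 1 epoch + checkpoint + resume,
        loss for loss and weight for weight."""
        dataset = _tiny_dataset(rng, n=2)
        straight_steps: list = []
        g_straight, rec_straight = gan.train(
            dataset, gan.TrainConfig(epochs=2, seed=7, augment=True, checkpoint_every=1),
            gen_spec=_tiny_gen_spec(), disc_spec=_tiny_disc_spec(),
            dtype=np.float32, checkpoint_dir=tmp_path / "a", step_records=straight_steps)
        resumed_steps: list = []
        g_resumed, rec_resumed = gan.train(
            dataset, gan.TrainConfig(epochs=2, seed=7, augment=True),
            gen_spec=_tiny_gen_spec(), disc_spec=_tiny_disc_spec(),
            dtype=np.float32, resume_from=tmp_path / "a" / "epoch_0001.npz",
            step_records=resumed_steps)
        assert [s for s in straight_steps if s[0] == 1] == resumed_steps
        assert len(rec_resumed) == 1
        assert rec_resumed[0] == rec_straight[1]
        for pa, pb in zip(g_straight.params(), g_resumed.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            gan.train([], gan.TrainConfig(epochs=1))
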