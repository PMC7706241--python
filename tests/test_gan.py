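"""DCGAN architecture ladders, training schedule contracts, sampling."""

import numpy as np
import pytest

from chdseg import nn
from chdseg.gan import (GanSpec, GanTrainConfig, build_discriminator,
                        build_generator, gan_training_step, pairs_to_gan_batch,
                        sample_synthetic, train_dcgan)

RNG = np.random.default_rng(0)


def _z(n=2, dim=100):
    return RNG.standard_normal((n, dim, 1, 1)).astype(np.float32)


class TestGeneratorArchitecture:
    def test_zero_noise_gives_finite_output_in_tanh_range(self):
        gen = build_generator(GanSpec(), seed=0)
        out = gen.forward(np.zeros((1, 100, 1, 1), np.float32))
        assert out.shape == (1, 2, 128, 128)
        assert np.isfinite(out).all()
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_spatial_ladder_matches_shape_arithmetic_oracle(self):
        """Strides [1,2,2,2,2,2] with kernel 4: 1->4->8->16->32->64->128,
        cross-checked against (n-1)*s - 2p + k per layer."""
        gen = build_generator(GanSpec(), seed=0)
        convs = [l for l in gen.layers if isinstance(l, nn.ConvTranspose2d)]
        assert len(convs) == 6
        assert [c.stride for c in convs] == [1, 2, 2, 2, 2, 2]
        assert all(c.kernel == 4 for c in convs)
        sizes = [1]
        for c in convs:
            sizes.append((sizes[-1] - 1) * c.stride - 2 * c.padding + c.kernel)
        assert sizes == [1, 4, 8, 16, 32, 64, 128]
        # and the actual forward trace agrees
        h = np.zeros((1, 100, 1, 1), np.float32)
        traced = [h.shape[-1]]
        for layer in gen.layers:
            h = layer.forward(h)
            if isinstance(layer, nn.ConvTranspose2d):
                traced.append(h.shape[-1])
        assert traced == sizes

    def test_last_activation_is_tanh_and_two_channels(self):
        gen = build_generator(GanSpec(), seed=0)
        assert isinstance(gen.layers[-1], nn.Tanh)
        out = gen.forward(_z(1))
        assert out.shape[1] == 2

    def test_different_noise_gives_different_outputs(self):
        gen = build_generator(GanSpec(out_size=32, gen_channels=(8, 8, 8)), seed=0)
        a = gen.forward(_z(1))
        b = gen.forward(_z(1))
        assert not np.allclose(a, b)


class TestDiscriminatorArchitecture:
    def test_probability_output_per_sample(self):
        disc = build_discriminator(GanSpec(), seed=1)
        x = RNG.standard_normal((5, 2, 128, 128)).astype(np.float32)
        p = disc.forward(x)
        assert p.shape == (5, 1, 1, 1)
        assert (p > 0).all() and (p < 1).all()

    def test_shape_ladder_mirrors_generator(self):
        disc = build_discriminator(GanSpec(), seed=1)
        convs = [l for l in disc.layers if isinstance(l, nn.Conv2d)]
        assert len(convs) == 6
        assert [c.stride for c in convs] == [2, 2, 2, 2, 2, 1]
        h = np.zeros((1, 2, 128, 128), np.float32)
        sizes = []
        for layer in disc.layers:
            h = layer.forward(h)
            if isinstance(layer, nn.Conv2d):
                sizes.append(h.shape[-1])
        assert sizes == [64, 32, 16, 8, 4, 1]

    def test_leaky_slope_and_sigmoid(self):
        disc = build_discriminator(GanSpec(), seed=1)
        leaks = [l for l in disc.layers if isinstance(l, nn.LeakyReLU)]
        assert len(leaks) == 5
        assert all(l.slope == 0.2 for l in leaks)
        assert isinstance(disc.layers[-1], nn.Sigmoid)

    def test_invalid_out_size_rejected(self):
        with pytest.raises(ValueError):
            GanSpec(out_size=48).validate()


SPEC32 = GanSpec(out_size=32, gen_channels=(16, 8, 8), disc_channels=(8, 8, 16))


def _real32(n=5):
    return RNG.standard_normal((n, 2, 32, 32)).astype(np.float32).clip(-1, 1)


class TestTrainingStep:
    def test_freezing_contract_by_parameter_snapshots(self):
        gen = build_generator(SPEC32, seed=0)
        disc = build_discriminator(SPEC32, seed=1)
        og, od = nn.Adam(gen.parameters()), nn.Adam(disc.parameters())
        g0 = [p.value.copy() for p in gen.parameters()]
        d0 = [p.value.copy() for p in disc.parameters()]
        counters = {}
        gan_training_step(gen, disc, _real32(), og, od,
                          np.random.default_rng(0), counters=counters)
        assert any(not np.array_equal(a, p.value)
                   for a, p in zip(d0, disc.parameters()))
        assert any(not np.array_equal(a, p.value)
                   for a, p in zip(g0, gen.parameters()))
        assert counters == {"disc_real_batches": 1, "disc_fake_batches": 1,
                            "gen_updates": 1}

    def test_generator_untouched_during_discriminator_phase(self):
        """Run only phase (a) by hand: generator parameters must not move."""
        gen = build_generator(SPEC32, seed=0)
        disc = build_discriminator(SPEC32, seed=1)
        od = nn.Adam(disc.parameters())
        g0 = [p.value.copy() for p in gen.parameters()]
        od.zero_grad()
        p_real = disc.forward(_real32())
        _, gr = nn.bce_loss_grad(p_real, 1.0)
        disc.backward(gr)
        fake = gen.forward(_z(5))
        p_fake = disc.forward(fake)
        _, gf = nn.bce_loss_grad(p_fake, 0.0)
        disc.backward(gf)
        od.step()
        assert all(np.array_equal(a, p.value)
                   for a, p in zip(g0, gen.parameters()))

    def test_perfect_discriminator_bce_limits(self):
        p_real = np.array([0.9999], np.float32)
        p_fake = np.array([0.0001], np.float32)
        lr, _ = nn.bce_loss_grad(p_real, 1.0)
        lf, _ = nn.bce_loss_grad(p_fake, 0.0)
        lg, _ = nn.bce_loss_grad(p_fake, 1.0)  # generator's view
        assert lr + lf < 1e-3
        assert lg > 9.0

    def test_schedule_counters_over_iterations(self, lv_pairs32):
        cfg = GanTrainConfig(iterations=6, seed=0, checkpoint_every=100)
        gen, disc, hist = train_dcgan(lv_pairs32, SPEC32, cfg)
        counters = hist[-1]["counters"]
        assert counters == {"disc_real_batches": 6, "disc_fake_batches": 6,
                            "gen_updates": 6}
        losses = [h for h in hist if "d_loss" in h]
        assert len(losses) == 6
        assert all(np.isfinite(h["d_loss"]) and np.isfinite(h["g_loss"])
                   for h in losses)


class TestSampling:
    def test_deterministic_per_seed_and_in_range(self):
        gen = build_generator(SPEC32, seed=3)
        a = sample_synthetic(gen, 3, seed=9, spec=SPEC32)
        b = sample_synthetic(gen, 3, seed=9, spec=SPEC32)
        for x, y in zip(a, b):
            assert np.array_equal(x.soft_mask, y.soft_mask)
            assert np.array_equal(x.image, y.image)
        assert all(0.0 <= s.soft_mask.min() and s.soft_mask.max() <= 1.0
                   for s in a)

    def test_requested_count_returned(self):
        gen = build_generator(SPEC32, seed=3)
        assert len(sample_synthetic(gen, 7, seed=0, spec=SPEC32, batch=3)) == 7


def test_real_batch_scaling_to_tanh_range(lv_pairs32):
    batch = pairs_to_gan_batch(lv_pairs32[:4])
    assert batch.shape == (4, 2, 32, 32)
    assert batch.min() >= -1.0 and batch.max() <= 1.0
    assert set(np.unique(batch[:, 1])) <= {-1.0, 1.0}  # masks are bipolar
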