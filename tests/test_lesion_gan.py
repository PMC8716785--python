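"""Lesion GAN: loss closed forms, generator/discriminator contracts, training."""

import numpy as np
import pytest

from cmbforge.lesion_gan import (
    GanConfig,
    Discriminator,
    Generator,
    adversarial_losses,
    border_loss,
    generate_masks,
    mask_volume_batch,
    train_lesion_gan,
    volume_loss,
    volume_fidelity_regression,
)
from cmbforge.types import VolumeDistribution, border_shell
from cmbforge.volume_model import smooth_volume_distribution


class TestVolumeLoss:
    def test_perfect_match_is_zero(self):
        masks = np.ones((3, 11, 11, 11))
        masks[:, 5, 5, 5] = 0.0  # one attenuated voxel each
        targets = mask_volume_batch(masks, (1, 1, 1))
        assert volume_loss(masks, targets, (1, 1, 1)) == pytest.approx(0.0)

    def test_single_pair_hand_value(self):
        # V_fake = 2 against V_in = 1 -> |2-1|/1 = 1
        mask = np.ones((1, 11, 11, 11))
        mask[0, 5, 5, 5] = 0.0
        mask[0, 5, 5, 6] = 0.0  # V_fake = 2 at unit spacing
        assert volume_loss(mask, [1.0], (1, 1, 1)) == pytest.approx(1.0)

    def test_batch_hand_value(self):
        # pairs (V_fake, V_in) = (3,4) and (5,4): (1/2)(1/4 + 1/4) = 0.25
        masks = np.ones((2, 11, 11, 11))
        masks[0, 5, 5, 3:6] = 0.0
        masks[1, 5, 5, 3:8] = 0.0
        assert volume_loss(masks, [4.0, 4.0], (1, 1, 1)) == pytest.approx(0.25)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            volume_loss(np.ones((1, 11, 11, 11)), [0.0], (1, 1, 1))


class TestMaskVolume:
    def test_all_ones_is_zero(self):
        assert mask_volume_batch(np.ones((1, 11, 11, 11)))[0] == 0.0

    def test_single_voxel_arithmetic(self):
        m = np.ones((1, 11, 11, 11))
        m[0, 5, 5, 5] = 0.25
        assert mask_volume_batch(m, (1, 1, 1))[0] == pytest.approx(0.75)

    def test_dark_core_with_anisotropic_spacing(self):
        # 27 fully dark voxels at 0.93 x 0.93 x 1.75 mm: 27 * 1.513575 mm^3
        m = np.ones((1, 11, 11, 11))
        m[0, 4:7, 4:7, 4:7] = 0.0
        v = mask_volume_batch(m, (0.93, 0.93, 1.75))[0]
        assert v == pytest.approx(27 * 0.93 * 0.93 * 1.75, rel=1e-12)
        assert v == pytest.approx(40.866525, abs=1e-6)


class TestBorderLoss:
    def test_shell_size_is_602(self):
        assert int(border_shell(11).sum()) == 11**3 - 9**3 == 602

    def test_unit_border_is_zero(self):
        m = np.ones((11, 11, 11))
        m[5, 5, 5] = 0.0  # interior does not count
        assert border_loss(m) == 0.0

    def test_half_border(self):
        m = np.ones((11, 11, 11))
        m[border_shell(11)] = 0.5
        assert border_loss(m) == pytest.approx(0.5)

    def test_single_dark_border_voxel(self):
        m = np.ones((11, 11, 11))
        m[0, 0, 0] = 0.0
        assert border_loss(m) == pytest.approx(1 / 602)


class TestAdversarialLosses:
    def test_uninformative_discriminator(self):
        d, g = adversarial_losses([0.5] * 4, [0.5] * 4)
        assert d == pytest.approx(2 * np.log(2), rel=1e-6)
        assert g == pytest.approx(np.log(0.5), rel=1e-6)

    def test_perfect_discriminator_limit(self):
        d, _ = adversarial_losses([1 - 1e-9], [1e-9])
        assert d == pytest.approx(0.0, abs=1e-5)


@pytest.fixture(scope="module")
def toy_setup():
    rng = np.random.default_rng(0)
    negs = rng.uniform(0.4, 0.9, size=(64, 11, 11, 11))
    reals = negs.copy()
    reals[:, 4:7, 4:7, 4:7] *= 0.2  # crude dark-core lesions
    dist = smooth_volume_distribution(np.clip(rng.gamma(2, 6, 100), 0.5, 79))
    return reals, negs, dist


class TestGeneratorContracts:
    @pytest.mark.parametrize("mode", ["none", "volume", "volume+background"])
    def test_output_shape_range_determinism(self, mode, toy_setup):
        _, negs, _ = toy_setup
        cfg = GanConfig(conditioning_mode=mode, seed=3)
        gen = Generator(cfg)
        rng = np.random.default_rng(1)
        z = rng.standard_normal((8, cfg.latent_dim))
        v = rng.uniform(0.05, 1.0, 8)
        out1 = gen.forward(z, v, negs[:8], train=False)
        out2 = gen.forward(z, v, negs[:8], train=False)
        assert out1.shape == (8, 11, 11, 11)
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        np.testing.assert_array_equal(out1, out2)

    def test_untrained_output_respects_range_for_many_draws(self):
        cfg = GanConfig(seed=1)
        gen = Generator(cfg)
        rng = np.random.default_rng(2)
        z = rng.standard_normal((1000, cfg.latent_dim))
        v = rng.uniform(0.01, 1.0, 1000)
        negs = rng.uniform(0, 1, (1000, 11, 11, 11))
        out = gen.forward(z, v, negs, train=False)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_same_seed_same_weights(self):
        g1 = Generator(GanConfig(seed=5))
        g2 = Generator(GanConfig(seed=5))
        for (p1, _), (p2, _) in zip(g1.parameters(), g2.parameters()):
            np.testing.assert_array_equal(p1, p2)

    def test_shape_mismatch_rejected(self):
        gen = Generator(GanConfig(seed=0))
        with pytest.raises(ValueError):
            gen.forward(np.zeros((2, 7)), np.zeros(2), np.zeros((2, 11, 11, 11)))


class TestDiscriminatorContracts:
    def test_output_in_unit_interval_and_deterministic(self):
        disc = Discriminator(GanConfig(seed=2))
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, (16, 11, 11, 11))
        s1 = disc.forward(p, train=False)
        s2 = disc.forward(p, train=False)
        assert ((s1 > 0) & (s1 < 1)).all()
        np.testing.assert_array_equal(s1, s2)

    def test_training_separates_toy_classes(self, toy_setup):
        reals, negs, dist = toy_setup
        cfg = GanConfig(epochs=30, seed=4)
        gen, _ = train_lesion_gan(reals, negs, dist, cfg)
        disc = Discriminator(cfg)  # fresh D scores are uninformative...
        # ...so check the trained pair instead: during training loss_d fell,
        # meaning D(real) > D(fake) on average; verify via a trained run log
        # (the separation statement itself):
        _, log = train_lesion_gan(reals, negs, dist, GanConfig(epochs=30, seed=4))
        assert log["loss_d"].iloc[-1] < log["loss_d"].iloc[0]


class TestTraining:
    def test_one_epoch_smoke_logs_all_components(self, toy_setup):
        reals, negs, dist = toy_setup
        gen, log = train_lesion_gan(reals, negs, dist, GanConfig(epochs=1, seed=1))
        assert len(log) == 1
        assert {"loss_d", "loss_g_adv", "loss_border", "loss_volume"} <= set(log.columns)

    def test_reproducible_per_seed(self, toy_setup):
        reals, negs, dist = toy_setup
        g1, l1 = train_lesion_gan(reals, negs, dist, GanConfig(epochs=2, seed=9))
        g2, l2 = train_lesion_gan(reals, negs, dist, GanConfig(epochs=2, seed=9))
        for (p1, _), (p2, _) in zip(g1.parameters(), g2.parameters()):
            np.testing.assert_array_equal(p1, p2)
        assert l1.equals(l2)

    def test_empty_inputs_rejected(self, toy_setup):
        _, negs, dist = toy_setup
        with pytest.raises(ValueError):
            train_lesion_gan([], negs, dist, GanConfig(epochs=1))

    def test_vanilla_gan_mode_ignores_conditions(self, toy_setup):
        """conditioning_mode='none' with zero border/volume weights is a
        plain GAN: the auxiliary loss components have no gradient weight."""
        reals, negs, dist = toy_setup
        cfg = GanConfig(epochs=2, conditioning_mode="none",
                        border_weight=0.0, volume_weight=0.0, seed=6)
        gen, log = train_lesion_gan(reals, negs, dist, cfg)
        z = np.random.default_rng(0).standard_normal((4, cfg.latent_dim))
        m1 = gen.forward(z, None, None, train=False)
        assert m1.shape == (4, 11, 11, 11)


def test_volume_fidelity_improves_with_volume_loss_weight():
    """R^2 of realized-vs-target volume grows with the volume-loss weight."""
    rng = np.random.default_rng(0)
    negs = rng.uniform(0.4, 0.9, size=(256, 11, 11, 11))
    reals = negs.copy()
    reals[:, 4:7, 4:7, 4:7] *= 0.2
    dist = smooth_volume_distribution(np.clip(rng.gamma(2, 6, 100), 0.5, 79))
    r2s = []
    for w in (0.0, 0.3, 1.0):
        cfg = GanConfig(epochs=80, volume_weight=w, non_saturating=True, seed=21)
        gen, _ = train_lesion_gan(reals, negs, dist, cfg)
        _, _, r2 = volume_fidelity_regression(gen, dist, n=300, neg_patches=negs, seed=2)
        r2s.append(r2)
    assert r2s[2] > r2s[0] + 0.1  # strict gain from no signal to full weight
    assert r2s[1] >= r2s[0] - 0.05  # intermediate weight not worse (slack for noise)


class TestFidelityRegression:
    def test_identity_stub(self):
        """An ideal generator (realized volume == target) gives slope 1, R2 1."""

        class _Ideal:
            class cfg:
                conditioning_mode = "volume"
                latent_dim = 4
                volume_cap = 80.0
                min_target_volume = 1.5

            def forward(self, z, v, neg, train=False):
                # dark voxels attenuating exactly v * 80 mm^3
                from cmbforge.types import voxel_volume

                n = z.shape[0]
                m = np.ones((n, 11, 11, 11))
                frac = np.asarray(v) * 80.0 / voxel_volume((0.93, 0.93, 1.75))
                for i, f in enumerate(frac):
                    flat = m[i].reshape(-1)
                    whole = int(f)
                    flat[:whole] = 0.0
                    flat[whole] = 1.0 - (f - whole)
                return m

        dist = VolumeDistribution.point_mass(20.0, n_bins=80)
        rng = np.random.default_rng(0)
        dist = smooth_volume_distribution(np.clip(rng.gamma(2, 5, 200), 0.5, 35))
        slope, intercept, r2 = volume_fidelity_regression(_Ideal(), dist, n=200, seed=1)
        assert slope == pytest.approx(1.0, abs=0.01)
        assert intercept == pytest.approx(0.0, abs=0.2)
        assert r2 > 0.999

    def test_noisy_stub_matches_analytic_r2(self):
        """realized = target + N(0, s^2): R2 -> var(t) / (var(t) + s^2)."""

        class _Noisy:
            class cfg:
                conditioning_mode = "volume"
                latent_dim = 4
                volume_cap = 80.0
                min_target_volume = 1.5

            def forward(self, z, v, neg, train=False):
                from cmbforge.types import voxel_volume

                n = z.shape[0]
                rng = np.random.default_rng(int(abs(z[0, 0] * 1e6)) % 2**31)
                target = np.asarray(v) * 80.0
                noisy = np.maximum(target + rng.normal(0, 3.0, n), 0.1)
                m = np.ones((n, 11, 11, 11))
                vv = voxel_volume((0.93, 0.93, 1.75))
                for i, t in enumerate(noisy):
                    f = t / vv
                    flat = m[i].reshape(-1)
                    whole = int(f)
                    flat[:whole] = 0.0
                    flat[whole] = 1.0 - (f - whole)
                return m

        rng = np.random.default_rng(0)
        dist = smooth_volume_distribution(np.clip(rng.uniform(1, 79, 500), 1, 79))
        slope, _, r2 = volume_fidelity_regression(_Noisy(), dist, n=2000, seed=2)
        targets_var = np.var(np.clip(np.random.default_rng(0).uniform(1, 79, 100000), 1, 79))
        # analytic R^2 for the uniform-ish target spread used here
        assert r2 == pytest.approx(targets_var / (targets_var + 9.0), abs=0.05)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_too_few_points_rejected(self):
        dist = VolumeDistribution.point_mass(5.0)
        with pytest.raises(ValueError):
            volume_fidelity_regression(Generator(GanConfig(seed=0)), dist, n=2)
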