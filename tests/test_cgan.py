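"""Adversarial losses, augmentation, generator/discriminator contracts and
the frame-mapping estimator (tiny configurations: correctness, not quality)."""

import numpy as np
import pytest

from petmoco import cgan, nn

TINY = dict(
    patch_shape=(16, 16, 16),
    depth=2,
    base_channels=4,
    disc_channels=4,
    epochs=1,
    patches_per_volume=1,
    augment=False,
    random_state=3,
)


class TestAdversarialLoss:
    def test_uninformative_discriminator(self):
        """D = 1/2 everywhere gives exactly 2 log(1/2)."""
        half = np.full((4, 8), 0.5)
        assert cgan.adversarial_loss(half, half) == pytest.approx(2 * np.log(0.5))

    def test_perfect_discriminator_supremum(self):
        ones = np.ones((4, 8))
        zeros = np.zeros((4, 8))
        val = cgan.adversarial_loss(ones, zeros)
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_always_non_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d_real = rng.uniform(0.01, 0.99, 16)
            d_fake = rng.uniform(0.01, 0.99, 16)
            assert cgan.adversarial_loss(d_real, d_fake) <= 0.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty batch"):
            cgan.adversarial_loss(np.array([]), np.array([0.5]))


class TestGeneratorObjective:
    def test_l1_zero_when_perfect(self):
        assert cgan.generator_objective(-1.0, 0.0, 1.0) == pytest.approx(-1.0)

    def test_lambda_scales_l1_linearly(self):
        base = cgan.generator_objective(0.0, 0.5, 1.0)
        assert cgan.generator_objective(0.0, 0.5, 2.0) == pytest.approx(2 * base)

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            cgan.generator_objective(0.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            cgan.CGANConfig(lambda_l1=0.0)


class TestAugmentPair:
    def test_identity_ranges_preserve_input(self):
        rng = np.random.default_rng(1)
        low = rng.random((12, 12, 12)).astype(np.float32)
        ref = rng.random((12, 12, 12)).astype(np.float32)
        a, b = cgan.augment_pair(
            low, ref, seed=0, rotation_deg=0, translation_vox=0, shear=0,
            noise_sigma=0, brightness=0, contrast=0,
        )
        assert np.allclose(a, low, atol=1e-6)
        assert np.allclose(b, ref, atol=1e-6)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        low = rng.random((12, 12, 12)).astype(np.float32)
        ref = rng.random((12, 12, 12)).astype(np.float32)
        a1, b1 = cgan.augment_pair(low, ref, seed=42)
        a2, b2 = cgan.augment_pair(low, ref, seed=42)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_spatial_alignment_preserved(self, small_dataset):
        """The same spatial transform hits both volumes: registering the
        augmented pair recovers identity within half a voxel."""
        from petmoco.registration import RegistrationConfig, register_rigid

        low = small_dataset.clean.data[..., 30]
        ref = small_dataset.clean.data[..., 36]
        lo, hi = cgan.robust_bounds(low)
        low_n = cgan.normalize(low, lo, hi)
        lo, hi = cgan.robust_bounds(ref)
        ref_n = cgan.normalize(ref, lo, hi)
        a, b = cgan.augment_pair(low_n, ref_n, seed=7, noise_sigma=0.0)
        est = register_rigid(
            a, b, small_dataset.clean.voxel_size,
            RegistrationConfig(shrink_factors=(2, 1), smoothing_sigmas=(1.0, 0.5),
                               sampling_strides=(1, 1), max_iter=(6, 3)),
        )
        trans_vox = np.abs(est.vector.translation).max() / 3.0
        assert trans_vox < 0.5


class TestArchitectureContracts:
    def test_generator_preserves_shape(self):
        gen = nn.UNet3D(depth=2, base=4, rng=np.random.default_rng(0))
        x = np.zeros((1, 1, 16, 16, 16), dtype=np.float32)
        assert gen.forward(x, train=False).shape == x.shape

    def test_discriminator_patch_grid_smaller(self):
        disc = nn.PatchDiscriminator(base=4, rng=np.random.default_rng(0))
        xy = np.zeros((1, 2, 16, 16, 16), dtype=np.float32)
        out = disc.forward(xy, train=False)
        assert out.shape[1] == 1
        assert np.prod(out.shape[2:]) < np.prod(xy.shape[2:])

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            cgan.CGANConfig(patch_shape=(20, 20, 20), depth=3)
        gen = nn.UNet3D(depth=3, base=4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="not divisible"):
            gen.forward(np.zeros((1, 1, 20, 20, 20), dtype=np.float32))

    def test_gradient_reaches_first_encoder_conv(self):
        """Skip connections keep the earliest encoder level trainable."""
        rng = np.random.default_rng(5)
        gen = nn.UNet3D(depth=2, base=4, rng=rng, dropout=0.0)
        x = rng.normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
        out = gen.forward(x, train=True)
        for _, g in gen.params():
            g[...] = 0.0
        gen.backward(np.ones_like(out) / out.size)
        first_conv_grad = gen.params()[0][1]
        assert np.isfinite(first_conv_grad).all()
        assert np.abs(first_conv_grad).max() > 0.0


@pytest.fixture(scope="module")
def tiny_pairs():
    """Four synthetic pairs: noisy blob -> smooth blob."""
    rng = np.random.default_rng(0)
    xs, ys = [], []
    for _ in range(4):
        base = np.zeros((24, 24, 24), dtype=np.float32)
        c = rng.integers(9, 15, 3)
        zz, yy, xx = np.indices(base.shape)
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        base[r2 < 49] = 100.0
        ys.append(base)
        xs.append(base + rng.normal(0, 30, base.shape).astype(np.float32))
    return np.stack(xs), np.stack(ys)


class TestFrameMappingEstimator:
    def test_fit_reduces_l1(self, tiny_pairs):
        X, Y = tiny_pairs
        model = cgan.CGANFrameMapping(frame_index=30, epochs=3, **{
            k: v for k, v in TINY.items() if k != "epochs"})
        model.fit(X, Y)
        assert model.final_l1_ < model.initial_l1_

    def test_seed_determinism(self, tiny_pairs):
        X, Y = tiny_pairs
        runs = []
        for _ in range(2):
            m = cgan.CGANFrameMapping(frame_index=30, **TINY).fit(X, Y)
            runs.append(m.loss_history_["g_l1"].to_numpy())
        assert np.array_equal(runs[0], runs[1])

    def test_predict_deterministic_and_finite(self, tiny_pairs):
        X, Y = tiny_pairs
        model = cgan.CGANFrameMapping(frame_index=30, **TINY).fit(X, Y)
        zero = np.zeros((1,) + X.shape[1:], dtype=np.float32)
        p1 = model.predict(zero)
        p2 = model.predict(zero)
        assert np.array_equal(p1, p2)
        assert np.isfinite(p1).all()

    def test_shape_mismatch_rejected(self, tiny_pairs):
        X, Y = tiny_pairs
        model = cgan.CGANFrameMapping(frame_index=30, **TINY).fit(X, Y)
        with pytest.raises(ValueError, match="does not match"):
            model.predict(np.zeros((1, 8, 8, 8), dtype=np.float32))

    def test_too_few_pairs(self, tiny_pairs):
        X, Y = tiny_pairs
        with pytest.raises(ValueError, match=">= 2"):
            cgan.train_mapping([(X[0], Y[0])], cgan.CGANConfig())

    def test_save_load_roundtrip(self, tiny_pairs, tmp_path):
        X, Y = tiny_pairs
        model = cgan.CGANFrameMapping(frame_index=30, **TINY).fit(X, Y)
        path = tmp_path / "mapping.npz"
        cgan.save_mapping(model, path)
        loaded = cgan.load_mapping(path)
        assert loaded.frame_index == 30
        assert np.array_equal(loaded.predict(X[:1]), model.predict(X[:1]))
        assert loaded.get_params() == model.get_params()

    def test_sklearn_get_set_params(self):
        model = cgan.CGANFrameMapping()
        params = model.get_params()
        assert "lambda_l1" in params and "random_state" in params
        model.set_params(lambda_l1=2.0)
        assert model.lambda_l1 == 2.0


class TestTiledInference:
    def test_tiling_matches_single_pass_when_patch_covers(self, tiny_pairs):
        X, Y = tiny_pairs
        model = cgan.CGANFrameMapping(frame_index=30, **{
            **TINY, "patch_shape": (24, 24, 24)}).fit(X, Y)
        vol = cgan.normalize(X[0], *cgan.robust_bounds(X[0]))
        full = cgan.tiled_inference(model.generator_, vol, (24, 24, 24))
        direct = model.generator_.forward(vol[None, None], train=False)[0, 0]
        assert np.allclose(full, direct, atol=1e-6)
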