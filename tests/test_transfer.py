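import numpy as np
import pytest

from cellvstain.core import Manifest, ValidationError, seeded_rng
from cellvstain.models import ModelSpec, build_model, train
from cellvstain.transfer import (
    CombinationRule,
    FineTuneConfig,
    combine_predictions,
    few_shot_curve,
    fine_tune_cgan,
    fine_tune_unet,
    select_combination_ratio,
    _subsample_manifest,
)


@pytest.fixture(scope="module")
def pretrained_pair(small_dataset):
    """A briefly trained U-Net + cGAN pair used as fine-tuning sources."""
    u = build_model(ModelSpec.preset("unet", "tiny", in_slices=3), seeded_rng(0))
    u = train(u, small_dataset, "factin", hp={"epochs": 5}, rng=seeded_rng(1))
    c = build_model(ModelSpec.preset("cgan", "tiny", in_slices=3), seeded_rng(0))
    c = train(c, small_dataset, "factin", hp={"epochs": 2}, rng=seeded_rng(1))
    return u, c


class TestCombine:
    def test_w1_returns_unet_exactly(self):
        rng = seeded_rng(2)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        np.testing.assert_array_equal(
            combine_predictions(a, b, CombinationRule(w=1.0)), a)
        np.testing.assert_array_equal(
            combine_predictions(a, b, CombinationRule(w=0.0)), b)

    def test_half_weight_constant_images(self):
        a, b = np.full((8, 8), 0.2), np.full((8, 8), 0.6)
        out = combine_predictions(a, b, CombinationRule(w=0.5))
        np.testing.assert_allclose(out, 0.4)

    def test_matches_direct_arithmetic(self):
        """w = 0.3 (a ratio chosen by the full-scale study) equals the
        brute-force per-pixel weighted mean."""
        rng = seeded_rng(3)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        out = combine_predictions(a, b, CombinationRule(w=0.3))
        np.testing.assert_allclose(out, 0.3 * a + 0.7 * b, atol=1e-15)

    def test_convex_envelope(self):
        rng = seeded_rng(4)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        for w in (0.1, 0.5, 0.9):
            out = combine_predictions(a, b, CombinationRule(w=w))
            assert (out >= np.minimum(a, b) - 1e-12).all()
            assert (out <= np.maximum(a, b) + 1e-12).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            combine_predictions(np.zeros((4, 4)), np.zeros((5, 5)),
                                CombinationRule(w=0.5))

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValidationError):
            CombinationRule(w=1.2)


class TestSelectRatio:
    def test_truth_equals_unet_selects_w1(self):
        rng = seeded_rng(5)
        truth = rng.random((32, 32))
        other = rng.random((32, 32))
        rule = select_combination_ratio([(truth, other, truth)])
        assert rule.w == 1.0

    def test_symmetric_noise_selects_near_half(self):
        """truth = 0.5*(unet+cgan) with independent zero-mean residuals has
        its optimum at w = 0.5."""
        rng = seeded_rng(6)
        triples = []
        for _ in range(6):
            truth = rng.random((32, 32))
            e1 = rng.normal(0, 0.1, truth.shape)
            e2 = rng.normal(0, 0.1, truth.shape)
            triples.append((truth + e1, truth + e2, truth))
        rule = select_combination_ratio(triples)
        assert 0.4 <= rule.w <= 0.6

    def test_result_member_of_grid(self):
        rng = seeded_rng(7)
        truth, other = rng.random((16, 16)), rng.random((16, 16))
        rule = select_combination_ratio([(truth, other, truth)],
                                        grid=(0.3, 0.5, 0.7))
        assert rule.w in (0.3, 0.5, 0.7)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValidationError):
            select_combination_ratio([])


class TestFineTuneUNet:
    def test_family_mismatch_rejected(self, pretrained_pair, small_dataset):
        _, cgan = pretrained_pair
        with pytest.raises(ValidationError):
            fine_tune_unet(cgan, small_dataset)

    def test_zero_epochs_identity(self, pretrained_pair, small_dataset):
        unet, _ = pretrained_pair
        ft = fine_tune_unet(unet, small_dataset,
                            FineTuneConfig(epochs=0, n_finetune_images=4),
                            seeded_rng(8))
        a, b = unet.state_dict(), ft.state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_lr_reduction_one_is_plain_continued_training(
            self, pretrained_pair, small_dataset):
        unet, _ = pretrained_pair
        n = len([r for r in small_dataset.rows if r.split == "train"])
        cfg = FineTuneConfig(lr_reduction=1.0, epochs=2, n_finetune_images=n)
        ft = fine_tune_unet(unet, small_dataset, cfg, seeded_rng(9))
        # replicate: same subsample draw, then plain training at base lr
        rng = seeded_rng(9)
        sub = _subsample_manifest(small_dataset, n, rng)
        ref = unet.clone()
        ref = train(ref, sub, "factin", hp={"lr": unet.spec.lr, "epochs": 2},
                    rng=rng)
        a, b = ft.state_dict(), ref.state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            FineTuneConfig(lr_reduction=0.0)
        with pytest.raises(ValidationError):
            FineTuneConfig(n_finetune_images=0)


class TestFineTuneCGAN:
    def test_weight_surgery_exact(self, pretrained_pair, small_dataset):
        """At setup exactly the last discriminator layer is redrawn; the
        generator output is bit-identical before any step."""
        _, cgan = pretrained_pair
        ft = fine_tune_cgan(cgan, small_dataset,
                            FineTuneConfig(epochs=0, n_finetune_images=4),
                            seeded_rng(10))
        a, b = cgan.state_dict(), ft.state_dict()
        differing = sorted(k for k in a if not np.array_equal(a[k], b[k]))
        assert differing == ["disc.final.b", "disc.final.w"] or \
            differing == ["disc.final.w"]
        assert ft.reinitialized_params == ["disc.final.w", "disc.final.b"]
        x = seeded_rng(11).random((3, 64, 64))
        np.testing.assert_array_equal(cgan.predict(x), ft.predict(x))

    def test_family_mismatch_rejected(self, pretrained_pair, small_dataset):
        unet, _ = pretrained_pair
        with pytest.raises(ValidationError):
            fine_tune_cgan(unet, small_dataset)

    def test_finetune_step_runs(self, pretrained_pair, small_dataset):
        _, cgan = pretrained_pair
        ft = fine_tune_cgan(cgan, small_dataset,
                            FineTuneConfig(epochs=1, n_finetune_images=4),
                            seeded_rng(12))
        assert np.isfinite(ft.log["loss"]).all()


class TestFewShotCurve:
    def test_size_exceeding_manifest_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            few_shot_curve(small_dataset, [100])

    def test_same_seed_identical_results(self, small_dataset):
        a = few_shot_curve(small_dataset, [4], cfg=FineTuneConfig(epochs=1),
                           rng=seeded_rng(13))
        b = few_shot_curve(small_dataset, [4], cfg=FineTuneConfig(epochs=1),
                           rng=seeded_rng(13))
        assert a.equals(b)

    def test_columns_and_rows(self, small_dataset, pretrained_pair):
        unet, _ = pretrained_pair
        df = few_shot_curve(small_dataset, [2, 4], pretrained=unet,
                            cfg=FineTuneConfig(epochs=1), rng=seeded_rng(14))
        assert list(df.columns) == ["n", "scratch_pcc", "finetuned_pcc"]
        assert list(df.n) == [2, 4]
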