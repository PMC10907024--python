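import numpy as np
import pytest

from cellvstain.core import Manifest, ValidationError, seeded_rng
from cellvstain.metrics import evaluate_model
from cellvstain.models import FAMILIES, ModelSpec, TrainedModel, build_model, train


@pytest.fixture(scope="module")
def trained_unet(small_dataset):
    """A tiny U-Net trained once on the shared dataset (smoke benchmark)."""
    spec = ModelSpec.preset("unet", "tiny", in_slices=3)
    model = build_model(spec, seeded_rng(2))
    return train(model, small_dataset, "factin", rng=seeded_rng(3))


class TestBuildModel:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_shape_contract_and_output_range(self, family):
        spec = ModelSpec.preset(family, "tiny", in_slices=3)
        model = build_model(spec, seeded_rng(0))
        out = model.predict(seeded_rng(1).random((3, 64, 64)))
        assert out.shape == (64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_single_slice_input(self):
        model = build_model(ModelSpec.preset("unet", "tiny", in_slices=1), seeded_rng(0))
        assert model.predict(np.zeros((1, 64, 64))).shape == (64, 64)

    def test_indivisible_size_rejected_at_predict(self):
        model = build_model(ModelSpec.preset("unet", "tiny", in_slices=1), seeded_rng(0))
        with pytest.raises(ValidationError, match="divisible"):
            model.predict(np.zeros((1, 60, 60)))

    def test_wrong_slice_count_rejected(self):
        model = build_model(ModelSpec.preset("unet", "tiny", in_slices=3), seeded_rng(0))
        with pytest.raises(ValidationError):
            model.predict(np.zeros((2, 64, 64)))

    def test_res_unet_parameter_count_analytic(self):
        """res-UNet differs from vanilla U-Net by exactly the 1x1 residual
        projections: sum over blocks of (cin*cout + cout)."""
        spec_u = ModelSpec.preset("unet", "tiny", in_slices=3)
        spec_r = ModelSpec.preset("res_unet", "tiny", in_slices=3)
        nu = build_model(spec_u, seeded_rng(0)).net.n_parameters()
        nr = build_model(spec_r, seeded_rng(0)).net.n_parameters()
        depth, w, cin = spec_u.depth, spec_u.base_width, spec_u.in_slices
        widths = [w * 2 ** i for i in range(depth + 1)]
        blocks = []
        blocks.append((cin, widths[0]))
        for i in range(1, depth):
            blocks.append((widths[i - 1], widths[i]))
        blocks.append((widths[depth - 1], widths[depth]))          # bottleneck
        for i in range(depth):
            blocks.append((widths[i] + widths[i + 1], widths[i]))  # decoder
        expected = sum(ci * co + co for ci, co in blocks)
        assert nr - nu == expected

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(family="vgg")
        with pytest.raises(ValidationError):
            ModelSpec(depth=1)


class TestPredict:
    def test_deterministic(self, trained_unet):
        x = seeded_rng(5).random((3, 64, 64))
        np.testing.assert_array_equal(trained_unet.predict(x), trained_unet.predict(x))

    def test_tiled_inference_shape_and_seams(self, trained_unet):
        """Feathered tiling: a constant input yields no extra seam
        discontinuity relative to a single-tile prediction."""
        const = np.full((3, 128, 128), 0.5)
        out = trained_unet.predict(const, tile=64)
        assert out.shape == (128, 128)
        single = trained_unet.predict(np.full((3, 64, 64), 0.5))
        jump_tiled = max(np.abs(np.diff(out, axis=0)).max(),
                         np.abs(np.diff(out, axis=1)).max())
        jump_single = max(np.abs(np.diff(single, axis=0)).max(),
                          np.abs(np.diff(single, axis=1)).max())
        assert jump_tiled <= jump_single + 1e-6

    def test_tile_divisibility_check(self, trained_unet):
        with pytest.raises(ValidationError):
            trained_unet.predict(np.zeros((3, 128, 128)), tile=60)


class TestTrain:
    def test_zero_epochs_is_identity(self, small_dataset):
        spec = ModelSpec.preset("unet", "tiny", in_slices=3)
        model = build_model(spec, seeded_rng(4))
        before = model.state_dict()
        train(model, small_dataset, "factin", hp={"epochs": 0}, rng=seeded_rng(5))
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_smoke_benchmark_beats_untrained(self, small_dataset, trained_unet):
        """Trained tiny U-Net reaches PCC >= 0.5 on the easy synthetic
        mapping; an untrained model stays near zero."""
        r_trained = evaluate_model(lambda s: trained_unet.predict(s),
                                   small_dataset, "factin").mean_r
        untrained = build_model(ModelSpec.preset("unet", "tiny", in_slices=3),
                                seeded_rng(9))
        r_raw = evaluate_model(lambda s: untrained.predict(s),
                               small_dataset, "factin").mean_r
        assert r_trained >= 0.5
        assert abs(r_raw) < 0.3
        assert r_trained > r_raw

    def test_loss_trend_nonincreasing_moving_average(self, trained_unet):
        loss = np.array(trained_unet.log["loss"])
        k = max(len(loss) // 5, 1)
        head = loss[:k].mean()
        tail = loss[-k:].mean()
        assert tail < head

    def test_cgan_trains_with_finite_losses(self, small_dataset):
        spec = ModelSpec.preset("cgan", "tiny", in_slices=3)
        model = build_model(spec, seeded_rng(6))
        model = train(model, small_dataset, "factin", hp={"epochs": 2},
                      rng=seeded_rng(7))
        assert np.isfinite(model.log["loss"]).all()
        out = model.predict(seeded_rng(8).random((3, 64, 64)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_missing_channel_rejected(self, small_dataset):
        model = build_model(ModelSpec.preset("unet", "tiny", in_slices=3), seeded_rng(0))
        with pytest.raises(ValidationError):
            train(model, small_dataset, "tubulin", rng=seeded_rng(0))


def test_checkpoint_roundtrip(tmp_path, trained_unet):
    path = tmp_path / "model.npz"
    trained_unet.save(path)
    back = TrainedModel.load(path)
    x = seeded_rng(10).random((3, 64, 64))
    np.testing.assert_array_equal(trained_unet.predict(x), back.predict(x))
    assert back.spec == trained_unet.spec
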