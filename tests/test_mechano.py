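import numpy as np
import pytest

from cellvstain.core import ValidationError, seeded_rng
from cellvstain import synthdata as sd
from cellvstain.mechano import (
    HIDDEN_LAYERS,
    YAPSample,
    condition_report,
    predict_yap,
    samples_to_arrays,
    train_yap_predictor,
    yap_nc_ratio,
)
from cellvstain.singlecell import FEATURE_NAMES, SingleCellSegmentation


def _disk(radius, shape=(64, 64), center=(32, 32)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


@pytest.fixture
def seg():
    return SingleCellSegmentation(cell_mask=_disk(18), nucleus_mask=_disk(8))


class TestYapRatio:
    def test_uniform_image_gives_one(self, seg):
        assert yap_nc_ratio(np.full((64, 64), 0.42), seg) == pytest.approx(1.0)

    def test_piecewise_constant(self, seg):
        img = np.full((64, 64), 0.4)
        img[seg.nucleus_mask] = 0.8
        assert yap_nc_ratio(img, seg) == pytest.approx(2.0)

    def test_matches_pixel_loop_oracle(self, seg):
        img = seeded_rng(1).random((64, 64)) * 0.8 + 0.1
        num = den = 0.0
        ncount = ccount = 0
        for r in range(64):
            for c in range(64):
                if seg.nucleus_mask[r, c]:
                    num += img[r, c]
                    ncount += 1
                elif seg.cell_mask[r, c]:
                    den += img[r, c]
                    ccount += 1
        assert yap_nc_ratio(img, seg) == pytest.approx(
            (num / ncount) / (den / ccount), abs=1e-12)

    def test_invariant_to_positive_scaling(self, seg):
        img = seeded_rng(2).random((64, 64)) * 0.5 + 0.2
        assert yap_nc_ratio(0.37 * img, seg) == pytest.approx(
            yap_nc_ratio(img, seg), rel=1e-12)

    def test_zero_cytoplasm_rejected(self):
        mask = _disk(10)
        seg = SingleCellSegmentation(cell_mask=mask, nucleus_mask=mask)
        with pytest.raises(ValidationError):
            yap_nc_ratio(np.full((64, 64), 0.5), seg)


class TestPredictor:
    def test_architecture_fixed(self):
        assert HIDDEN_LAYERS == (256, 256, 4)
        df = sd.simulate_yap_samples(60, seeded_rng(3))
        pred = train_yap_predictor(df, hp={"max_iter": 30}, rng=seeded_rng(4))
        assert pred.mlp.hidden_layer_sizes == (256, 256, 4)

    def test_noise_free_linear_target_learnable(self):
        df = sd.simulate_yap_samples(300, seeded_rng(5), noise_frac=0.0)
        pred = train_yap_predictor(df, rng=seeded_rng(6))
        assert pred.log["holdout_r2"] >= 0.95

    def test_permuted_labels_unlearnable(self):
        df = sd.simulate_yap_samples(200, seeded_rng(7))
        df["yap_nc_true"] = seeded_rng(8).permutation(df["yap_nc_true"].to_numpy())
        pred = train_yap_predictor(df, rng=seeded_rng(9))
        assert pred.log["holdout_r2"] <= 0.1

    def test_too_few_samples_rejected(self):
        df = sd.simulate_yap_samples(10, seeded_rng(10))
        with pytest.raises(ValidationError):
            train_yap_predictor(df)

    def test_wrong_feature_count_rejected(self):
        df = sd.simulate_yap_samples(60, seeded_rng(11))
        pred = train_yap_predictor(df, hp={"max_iter": 20}, rng=seeded_rng(12))
        with pytest.raises(ValidationError):
            predict_yap(pred, np.zeros(16))

    def test_prediction_deterministic(self):
        df = sd.simulate_yap_samples(60, seeded_rng(13))
        pred = train_yap_predictor(df, hp={"max_iter": 30}, rng=seeded_rng(14))
        x = df[list(FEATURE_NAMES)].iloc[0].to_numpy()
        assert predict_yap(pred, x) == predict_yap(pred, x)

    def test_normalization_uses_training_statistics_only(self):
        """Stored z-score statistics come from the training subset; applying
        them to new features must reproduce the pipeline's predictions."""
        df = sd.simulate_yap_samples(120, seeded_rng(15))
        pred = train_yap_predictor(df, hp={"max_iter": 50}, rng=seeded_rng(16))
        X, _, _ = samples_to_arrays(df)
        manual = pred.mlp.predict((X - pred.feature_mean) / pred.feature_scale)
        pipeline = pred.mlp.predict(pred.transform(X))
        np.testing.assert_array_equal(manual, pipeline)
        full_mean = X.mean(axis=0)
        assert not np.allclose(pred.feature_mean, full_mean)

    def test_yap_sample_validation(self):
        with pytest.raises(ValidationError):
            YAPSample(features=np.zeros(17), yap_nc_true=-1.0)
        with pytest.raises(ValidationError):
            YAPSample(features=np.zeros(5), yap_nc_true=1.0)


class TestConditionReport:
    def test_perfect_predictions_r2_one(self):
        df = sd.simulate_yap_samples(90, seeded_rng(17), n_groups=3)
        _, _, _ = samples_to_arrays(df)
        table, r2 = condition_report(df, df["yap_nc_true"].to_numpy())
        assert r2 == pytest.approx(1.0)
        assert set(table.kind) == {"measured", "predicted"}

    def test_single_group_rejected(self):
        df = sd.simulate_yap_samples(60, seeded_rng(18))
        with pytest.raises(ValidationError):
            condition_report(df, df["yap_nc_true"].to_numpy())

    def test_designed_nonmonotone_ordering_reproduced(self):
        """Middle condition highest by design; the report preserves it."""
        df = sd.simulate_yap_samples(240, seeded_rng(19), n_groups=3)
        table, _ = condition_report(df, df["yap_nc_true"].to_numpy())
        med = table[table.kind == "measured"].set_index("condition")["median"]
        assert med["group1"] > med["group2"] > med["group0"]
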