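"""YAP nuclear/cytoplasmic ratio: ground truth and prediction.

The mechanotransduction readout is the YAP n/c ratio — mean YAP
immunofluorescence intensity over the nucleus divided by the mean over
the cytoplasm (cell minus nucleus).  A supervised multilayer perceptron
with three hidden layers of widths (256, 256, 4), ReLU activations and a
scalar linear output predicts this ratio from the 17 single-cell
morphometric features, so that once a YAP predictor is trained, the
mechanobiological state can be read from label-free images alone.

Features are z-scored with statistics estimated from the training set
only; zero-variance features are left unscaled with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .core import ValidationError, logger
from .singlecell import FEATURE_NAMES, CellFeatureVector, SingleCellSegmentation

HIDDEN_LAYERS = (256, 256, 4)


@dataclass
class YAPSample:
    features: np.ndarray              # length-17, FEATURE_NAMES order
    yap_nc_true: float
    condition: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (len(FEATURE_NAMES),):
            raise ValidationError(
                f"expected {len(FEATURE_NAMES)} features, got {self.features.shape}")
        if not (np.isfinite(self.yap_nc_true) and self.yap_nc_true > 0):
            raise ValidationError("yap_nc_true must be positive and finite")


def yap_nc_ratio(yap_image: np.ndarray, seg: SingleCellSegmentation,
                 background: float = 0.0) -> float:
    """Mean YAP intensity over the nucleus / mean over the cytoplasm.

    ``background`` is subtracted from both means when provided (off by
    default).  The ratio is invariant to positive rescaling of the image.
    """
    yap_image = np.asarray(yap_image, dtype=np.float64)
    if yap_image.shape != seg.cell_mask.shape:
        raise ValidationError("YAP image and segmentation shapes differ")
    cyto = seg.cell_mask & ~seg.nucleus_mask
    if not cyto.any():
        raise ValidationError("empty cytoplasm mask")
    nuc_mean = float(yap_image[seg.nucleus_mask].mean()) - background
    cyto_mean = float(yap_image[cyto].mean()) - background
    if cyto_mean <= 0:
        raise ValidationError("non-positive cytoplasmic mean; cell excluded")
    return nuc_mean / cyto_mean


@dataclass
class YAPPredictor:
    mlp: MLPRegressor
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    log: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_scale


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a list of YAPSample or a DataFrame with the 17 feature
    columns, ``yap_nc_true`` and optional ``condition``."""
    if isinstance(samples, pd.DataFrame):
        X = samples[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
        y = samples["yap_nc_true"].to_numpy(dtype=np.float64)
        g = (samples["condition"].to_numpy() if "condition" in samples
             else np.array([""] * len(samples)))
        return X, y, g
    X = np.stack([s.features for s in samples])
    y = np.array([s.yap_nc_true for s in samples])
    g = np.array([s.condition for s in samples])
    return X, y, g


def train_yap_predictor(
    samples,
    hp: dict | None = None,
    rng: np.random.Generator | None = None,
    holdout_fraction: float = 0.25,
) -> YAPPredictor:
    """Fit the (17 -> 256 -> 256 -> 4 -> 1) MLP on YAP samples.

    A seeded holdout split reports generalization R^2 in the training log;
    the model itself is fit on the remaining samples.
    """
    rng = rng or np.random.default_rng(0)
    hp = dict(hp or {})
    X, y, _ = samples_to_arrays(samples)
    n = X.shape[0]
    if n < 30:
        raise ValidationError(f"need >= 30 samples, got {n}")
    if not np.isfinite(X).all():
        raise ValidationError("features contain non-finite values")
    perm = rng.permutation(n)
    n_ho = max(1, int(round(holdout_fraction * n)))
    ho, tr = perm[:n_ho], perm[n_ho:]
    mean = X[tr].mean(axis=0)
    scale = X[tr].std(axis=0)
    dead = scale < 1e-12
    if dead.any():
        warnings.warn(
            f"zero-variance features left unscaled: "
            f"{[FEATURE_NAMES[i] for i in np.flatnonzero(dead)]}")
        scale = np.where(dead, 1.0, scale)
    Xtr = (X[tr] - mean) / scale
    # the narrow (..., 4) layer can collapse on unlucky inits; restart a few
    # times and keep the best internal-validation fit
    mlp, best_score = None, -np.inf
    for _ in range(int(hp.get("n_restarts", 3))):
        cand = MLPRegressor(
            hidden_layer_sizes=HIDDEN_LAYERS,
            activation="relu",
            solver="adam",
            learning_rate_init=float(hp.get("lr", 5e-4)),
            batch_size=int(hp.get("batch_size", 16)),
            max_iter=int(hp.get("max_iter", 2000)),
            early_stopping=bool(hp.get("early_stopping", True)),
            n_iter_no_change=int(hp.get("patience", 30)),
            validation_fraction=0.15,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")      # convergence chatter
            cand.fit(Xtr, y[tr])
        score = getattr(cand, "best_validation_score_", None)
        if score is None:
            score = cand.score(Xtr, y[tr])
        if score > best_score:
            mlp, best_score = cand, score
    pred = YAPPredictor(mlp=mlp, feature_mean=mean, feature_scale=scale)
    r2 = float(mlp.score(pred.transform(X[ho]), y[ho]))
    train_pred = mlp.predict(Xtr)
    pred.log = {
        "holdout_r2": r2,
        "n_train": int(len(tr)),
        "n_holdout": int(n_ho),
        "train_rmse": float(np.sqrt(np.mean((train_pred - y[tr]) ** 2))),
    }
    logger.info("YAP predictor held-out R^2 = %.4f", r2)
    return pred


def evaluate_predictor(predictor: YAPPredictor, samples) -> float:
    """R^2 of a trained predictor on an independent sample set."""
    X, y, _ = samples_to_arrays(samples)
    return float(predictor.mlp.score(predictor.transform(X), y))


def predict_yap(predictor: YAPPredictor, features) -> float:
    """Predict the YAP n/c ratio for one 17-feature cell profile."""
    if isinstance(features, CellFeatureVector):
        x = features.as_array()
    else:
        x = np.asarray(features, dtype=np.float64)
    if x.shape != (len(FEATURE_NAMES),):
        raise ValidationError(
            f"expected {len(FEATURE_NAMES)} features, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValidationError("features must be finite")
    return float(predictor.mlp.predict(predictor.transform(x[None]))[0])


def condition_report(
    samples,
    predictions: np.ndarray,
    out_csv=None,
) -> tuple[pd.DataFrame, float]:
    """Per-condition summary (median, IQR) plus overall predicted-vs-true R^2.

    Requires at least two condition groups; group order of first
    appearance is preserved.
    """
    X, y, groups = samples_to_arrays(samples)
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.shape != y.shape:
        raise ValidationError("predictions and samples must align")
    uniq = list(dict.fromkeys(groups))
    if len(uniq) < 2:
        raise ValidationError("need >= 2 condition groups")
    rows = []
    for g in uniq:
        m = groups == g
        for kind, vals in (("measured", y[m]), ("predicted", predictions[m])):
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"condition": g, "kind": kind, "n": int(m.sum()),
                         "median": q2, "iqr": q3 - q1})
    table = pd.DataFrame(rows)
    ss_res = float(((y - predictions) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table, r2
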