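"""Patch-wise Pearson correlation evaluation.

The quality metric throughout is the Pearson correlation coefficient with
a small regularizer eps added to the denominator so that constant patches
yield r = 0 instead of dividing by zero:

    r = sum((x - xbar)(y - ybar)) /
        (sqrt(sum((x - xbar)^2)) * sqrt(sum((y - ybar)^2)) + eps)

Images are tiled into non-overlapping patches anchored at (0, 0); trailing
partial patches are dropped; the report averages r over patches unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Manifest, ValidationError, load_pair

DEFAULT_EPS = 1e-8
DEFAULT_PATCH = 512


def pcc(x: np.ndarray, y: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """Regularized Pearson correlation between two equal-shape arrays."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 elements")
    xc = x - x.mean()
    yc = y - y.mean()
    num = float((xc * yc).sum())
    den = float(np.sqrt((xc ** 2).sum()) * np.sqrt((yc ** 2).sum())) + eps
    return num / den


@dataclass
class PCCReport:
    r_values: list[float]
    patch_size: int
    eps: float
    channel: str = ""

    @property
    def mean_r(self) -> float:
        if not self.r_values:
            raise ValidationError("empty PCC report")
        return float(np.mean(self.r_values))

    @property
    def n_patches(self) -> int:
        return len(self.r_values)


def patchwise_pcc(pred: np.ndarray, truth: np.ndarray,
                  patch: int = DEFAULT_PATCH, eps: float = DEFAULT_EPS,
                  channel: str = "") -> PCCReport:
    """Tile the image pair into non-overlapping patches and correlate each."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    h, w = pred.shape
    patch = min(patch, h, w)
    rs = []
    for i in range(0, h - patch + 1, patch):
        for j in range(0, w - patch + 1, patch):
            rs.append(pcc(pred[i:i + patch, j:j + patch],
                          truth[i:i + patch, j:j + patch], eps=eps))
    return PCCReport(r_values=rs, patch_size=patch, eps=eps, channel=channel)


def evaluate_model(predict_fn, test_manifest: Manifest, channel: str,
                   patch: int = DEFAULT_PATCH, eps: float = DEFAULT_EPS,
                   out_csv: str | Path | None = None) -> PCCReport:
    """Evaluate a predictor on the ``test`` split of a manifest.

    ``predict_fn`` maps a (slices, H, W) DIC stack to a (H, W) prediction
    (a :class:`~cellvstain.models.TrainedModel`'s ``predict`` or a combined
    rule).  Train/test splits must be disjoint by pair id.
    """
    train_ids = {r.pair_id for r in test_manifest.rows if r.split == "train"}
    test_rows = [r for r in test_manifest.rows if r.split == "test"]
    overlap = train_ids & {r.pair_id for r in test_rows}
    if overlap:
        raise ValidationError(f"pairs in both train and test splits: {sorted(overlap)}")
    if not test_rows:
        raise ValidationError("manifest has no test rows")
    rs = []
    records = []
    patch_used = patch
    for row in test_rows:
        pair = load_pair(row, root=test_manifest.root)
        pred = predict_fn(pair.dic_stack)
        rep = patchwise_pcc(pred, pair.targets[channel], patch=patch, eps=eps,
                            channel=channel)
        patch_used = rep.patch_size
        rs.extend(rep.r_values)
        records.append({"pair_id": row.pair_id, "mean_r": rep.mean_r,
                        "n_patches": rep.n_patches})
    if out_csv is not None:
        pd.DataFrame.from_records(records).to_csv(out_csv, index=False)
    return PCCReport(r_values=rs, patch_size=patch_used, eps=eps, channel=channel)
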