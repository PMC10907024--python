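"""Supervised dataset matching.

Before fine-tuning, an unseen target dataset is matched to the most
similar local (pretrained-on) dataset by a supervised image classifier
trained on DIC patches labeled with their dataset of origin.  The default
backbone is a small committee of VGG-style CNNs (conv/max-pool stages +
dense softmax head) whose class probabilities are averaged; the contract
is supervised matching, not a specific capacity.  Inputs are center crops
of the DIC slices, 2x downsampled and intensity-standardized per slice;
training patches are augmented with the dihedral operations that preserve
the 45-degree DIC shear axis (rotating by 90 degrees would fabricate an
acquisition geometry the microscope never produces).  The dataset-level
decision is a majority vote over the target images, ties broken by mean
class probability, then by class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Manifest, ValidationError, load_pair, logger
from .nn import Adam, SmallVGGClassifier
from .nn import autodiff as ad
from .nn.autodiff import Var


def _standardize(img: np.ndarray) -> np.ndarray:
    s = img.std()
    return (img - img.mean()) / (s if s > 1e-9 else 1.0)


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    """Crop around the image content (centroid of deviation from the
    median), so cells near the field edge are not truncated."""
    h, w = img.shape
    if h < size or w < size:
        raise ValidationError(f"image {h}x{w} smaller than crop {size}")
    if h == size and w == size:
        return img
    from scipy import ndimage as ndi

    weight = ndi.gaussian_filter(np.abs(img - np.median(img)), 2.0)
    total = weight.sum()
    if total <= 0:
        cy, cx = h / 2, w / 2
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        cy = (weight * yy).sum() / total
        cx = (weight * xx).sum() / total
    r0 = int(np.clip(round(cy - size / 2), 0, h - size))
    c0 = int(np.clip(round(cx - size / 2), 0, w - size))
    return img[r0:r0 + size, c0:c0 + size]


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return img
    h, w = (img.shape[0] // factor) * factor, (img.shape[1] // factor) * factor
    return img[:h, :w].reshape(h // factor, factor, w // factor, factor).mean((1, 3))


def _prepare_slices(stack: np.ndarray, patch_size: int,
                    downsample: int) -> list[np.ndarray]:
    """Two standardized channels per z-slice: the signed DIC relief and
    its rectified envelope (|deviation from median|, smoothed), which
    renders each cell as a solid footprint regardless of shear phase."""
    from scipy import ndimage as ndi

    out = []
    for s in stack:
        x = _downsample(_center_crop(s, patch_size), downsample)
        env = ndi.gaussian_filter(np.abs(x - np.median(x)), 1.5)
        out.append(np.stack([_standardize(x), _standardize(env)]))
    return out


def _shear_preserving_aug(x: np.ndarray):
    """Dihedral ops mapping the 45-degree shear axis onto itself."""
    yield x
    yield x[:, ::-1, ::-1]            # rot180 (relief sign flip)
    yield x.transpose(0, 2, 1)        # transpose
    yield x[:, ::-1, ::-1].transpose(0, 2, 1)


@dataclass
class MatcherModel:
    classifiers: list[SmallVGGClassifier]
    classes: list[str]
    patch_size: int
    downsample: int = 2
    log: dict = field(default_factory=dict)

    def predict_probs(self, stacks: list[np.ndarray]) -> np.ndarray:
        """Per-image class probabilities, averaged over z-slices, the
        shear-preserving transform set, and the classifier committee."""
        out = []
        for s in stacks:
            views = []
            for x in _prepare_slices(s, self.patch_size, self.downsample):
                views.extend(_shear_preserving_aug(x))
            X = np.ascontiguousarray(np.stack(views))
            probs = np.mean([c.predict_probs(X).mean(axis=0)
                             for c in self.classifiers], axis=0)
            out.append(probs)
        return np.stack(out)


def train_matcher(
    local_manifests: dict[str, Manifest],
    hp: dict | None = None,
    rng: np.random.Generator | None = None,
) -> MatcherModel:
    """Train the dataset matcher on DIC patches from >= 2 local datasets.

    Held-out accuracy (one image in five per dataset) is recorded in the
    training log.
    """
    rng = rng or np.random.default_rng(0)
    hp = dict(hp or {})
    patch_size = int(hp.get("patch_size", 64))
    downsample = int(hp.get("downsample", 2))
    steps = int(hp.get("steps", 1500))
    lr = float(hp.get("lr", 2e-3))
    batch = int(hp.get("batch_size", 16))
    n_models = int(hp.get("n_models", 3))
    if len(local_manifests) < 2:
        raise ValidationError("need at least 2 local datasets to train a matcher")
    classes = list(local_manifests)
    if len(set(classes)) != len(classes):
        raise ValidationError("duplicate dataset ids")
    X_tr, y_tr, X_ho, y_ho = [], [], [], []
    for label, (ds_id, manifest) in enumerate(local_manifests.items()):
        if len(manifest) < 2:
            raise ValidationError(f"dataset {ds_id!r} has < 2 pairs")
        rows = [r for r in manifest.rows if r.split == "train"] or manifest.rows
        for i, row in enumerate(rows):
            pair = load_pair(row, root=manifest.root)
            xs = _prepare_slices(pair.dic_stack, patch_size, downsample)
            if i % 5 == 4:
                X_ho.append(xs[len(xs) // 2])
                y_ho.append(label)
            else:
                for x in xs:              # every defocus slice is a sample
                    for a in _shear_preserving_aug(x):
                        X_tr.append(a)
                        y_tr.append(label)
    X_tr = np.ascontiguousarray(np.stack(X_tr))
    y_tr = np.array(y_tr)
    classifiers = []
    losses = []
    ema_decay = float(hp.get("ema_decay", 0.998))
    for _ in range(n_models):
        clf = SmallVGGClassifier(len(classes), in_ch=2,
                                 base_width=int(hp.get("base_width", 8)), rng=rng)
        opt = Adam(clf.parameters(), lr=lr)
        params = clf.parameters()
        ema = {k: v.data.copy() for k, v in params.items()}
        for _step in range(steps):
            idx = rng.integers(0, len(X_tr), batch)
            loss = ad.softmax_cross_entropy(clf.logits(Var(X_tr[idx])), y_tr[idx])
            clf.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            # Polyak averaging: the averaged iterate generalizes far more
            # reliably than the noisy last iterate
            for k, v in params.items():
                ema[k] = ema_decay * ema[k] + (1.0 - ema_decay) * v.data
        clf.load_state_dict(ema)
        classifiers.append(clf)
    log = {"loss": losses}
    if X_ho:
        Xh = np.ascontiguousarray(np.stack(X_ho))
        yh = np.array(y_ho)
        member_acc = [float(np.mean(c.predict_probs(Xh).argmax(axis=1) == yh))
                      for c in classifiers]
        log["member_holdout_accuracy"] = member_acc
        probs = np.mean([c.predict_probs(Xh) for c in classifiers], axis=0)
        acc = float(np.mean(probs.argmax(axis=1) == yh))
        log["holdout_accuracy"] = acc
        logger.info("matcher held-out accuracy: %.3f", acc)
    return MatcherModel(classifiers=classifiers, classes=classes,
                        patch_size=patch_size, downsample=downsample, log=log)


def match_dataset(
    matcher: MatcherModel,
    target_stacks: list[np.ndarray],
) -> tuple[str, dict[str, float]]:
    """Classify each target DIC stack and majority-vote the dataset id.

    Returns the winning local dataset id and the per-class vote fractions.
    Ties are broken by mean class probability, then by class order.
    """
    if not target_stacks:
        raise ValidationError("need at least one target image")
    probs = matcher.predict_probs(target_stacks)
    votes = probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=len(matcher.classes))
    fractions = counts / counts.sum()
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) > 1:
        mean_probs = probs.mean(axis=0)
        order = sorted(tied, key=lambda k: (-mean_probs[k], k))
        winner = order[0]
        logger.info("vote tie among %s broken by mean probability",
                    [matcher.classes[k] for k in tied])
    else:
        winner = int(tied[0])
    return matcher.classes[winner], {
        c: float(fractions[i]) for i, c in enumerate(matcher.classes)
    }
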