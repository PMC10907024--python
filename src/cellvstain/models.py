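"""Image-to-image model zoo: build, train, predict, checkpoint.

Five families learn the DIC-stack -> fluorescence translation per channel:
vanilla U-Net, res-UNet, att-UNet, a DeepLab-v3+-style ASPP regressor, and
a conditional GAN (U-Net generator + patch discriminator, least-squares
adversarial loss plus L1).  Two size presets are provided: ``paper``
(depth 4, width 64, 512-px I/O) mirrors common full-scale defaults, and
``tiny`` (depth 3, width 8, 64-128 px) is the CPU-friendly default used by
the test benchmarks.  F-actin and nuclei models are trained separately and
share no state.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ImagePair,
    Manifest,
    TrainingDivergedError,
    ValidationError,
    load_pair,
    logger,
)
from .metrics import pcc
from .nn import Adam, DeepLabLike, Module, PatchDiscriminator, UNet
from .nn import autodiff as ad
from .nn.autodiff import Var

FAMILIES = ("unet", "res_unet", "att_unet", "deeplab", "cgan")


@dataclass
class ModelSpec:
    family: str = "unet"
    depth: int = 3
    base_width: int = 8
    in_slices: int = 3
    loss: str = "mae"              # unet family/deeplab: mae; cgan: l1+lsgan
    lr: float = 1e-3
    batch_size: int = 8
    epochs: int = 30
    lr_decay: float = 1.0          # multiplicative, per epoch
    lambda_l1: float = 100.0       # cGAN L1 weight
    size_preset: str = "tiny"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose {FAMILIES}")
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.base_width < 4:
            raise ValidationError("base_width must be >= 4")
        if self.in_slices < 1:
            raise ValidationError("in_slices must be >= 1")

    @classmethod
    def preset(cls, family: str, preset: str = "tiny", in_slices: int = 3,
               **overrides) -> "ModelSpec":
        if preset == "paper":
            base = dict(depth=4, base_width=64, lr=2e-4, batch_size=4, epochs=200)
        elif preset == "tiny":
            base = dict(depth=3, base_width=8, lr=5e-4, batch_size=2, epochs=50)
        else:
            raise ValidationError(f"unknown preset {preset!r}")
        base.update(overrides)
        return cls(family=family, in_slices=in_slices, size_preset=preset, **base)


def _build_net(spec: ModelSpec, rng: np.random.Generator) -> Module:
    if spec.family == "unet":
        return UNet(spec.in_slices, spec.depth, spec.base_width, rng)
    if spec.family == "res_unet":
        return UNet(spec.in_slices, spec.depth, spec.base_width, rng, residual=True)
    if spec.family == "att_unet":
        return UNet(spec.in_slices, spec.depth, spec.base_width, rng, attention=True)
    if spec.family == "deeplab":
        return DeepLabLike(spec.in_slices, spec.base_width, rng)
    if spec.family == "cgan":
        return UNet(spec.in_slices, spec.depth, spec.base_width, rng)
    raise ValidationError(spec.family)


@dataclass
class TrainedModel:
    """A (possibly still untrained) network plus provenance and logs."""

    spec: ModelSpec
    net: Module
    disc: PatchDiscriminator | None = None
    pretrain_dataset_id: str = ""
    finetuned_on: str = ""
    log: dict = field(default_factory=lambda: {"loss": [], "val_pcc": []})

    @property
    def divisor(self) -> int:
        return 2 ** self.net.depth

    def predict(self, stack: np.ndarray, tile: int | None = None) -> np.ndarray:
        """Map a (in_slices, H, W) stack to an (H, W) prediction in [0, 1].

        With ``tile``, larger images are processed as overlapping tiles
        blended with feathered (triangular) weights, so constant inputs
        show no seams.
        """
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 3 or stack.shape[0] != self.spec.in_slices:
            raise ValidationError(
                f"expected ({self.spec.in_slices}, H, W) stack, got {stack.shape}")
        H, W = stack.shape[1:]
        if tile is None:
            if H % self.divisor or W % self.divisor:
                raise ValidationError(
                    f"spatial size {H}x{W} not divisible by {self.divisor}; "
                    "pass tile= for tiled inference")
            return self.net(Var(stack[None])).data[0, 0]
        t = int(tile)
        if t % self.divisor:
            raise ValidationError(f"tile size must be divisible by {self.divisor}")
        if H < t or W < t:
            raise ValidationError("image smaller than tile")
        stride = max(t // 2, 1)
        tri = 1.0 - np.abs(np.linspace(-1, 1, t, endpoint=False) + 1.0 / t)
        weight = np.outer(tri, tri) + 1e-6
        acc = np.zeros((H, W))
        wacc = np.zeros((H, W))
        rows = sorted({min(r, H - t) for r in range(0, H, stride)})
        cols = sorted({min(c, W - t) for c in range(0, W, stride)})
        for r in rows:
            for c in cols:
                out = self.net(Var(stack[None, :, r:r + t, c:c + t])).data[0, 0]
                acc[r:r + t, c:c + t] += out * weight
                wacc[r:r + t, c:c + t] += weight
        return acc / wacc

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"net.{k}": v for k, v in self.net.state_dict().items()}
        if self.disc is not None:
            state.update({f"disc.{k}": v for k, v in self.disc.state_dict().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(
            {k[4:]: v for k, v in state.items() if k.startswith("net.")})
        if self.disc is not None:
            self.disc.load_state_dict(
                {k[5:]: v for k, v in state.items() if k.startswith("disc.")})

    def save(self, path: str | Path) -> None:
        meta = {
            "spec": asdict(self.spec),
            "pretrain_dataset_id": self.pretrain_dataset_id,
            "finetuned_on": self.finetuned_on,
            "log": self.log,
        }
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez_compressed(str(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec = ModelSpec(**meta["spec"])
            model = build_model(spec, np.random.default_rng(0))
            state = {k.replace("__", "."): data[k] for k in data.files
                     if k != "__meta__"}
        model.load_state_dict(state)
        model.pretrain_dataset_id = meta["pretrain_dataset_id"]
        model.finetuned_on = meta["finetuned_on"]
        model.log = meta["log"]
        return model

    def clone(self) -> "TrainedModel":
        return copy.deepcopy(self)


def build_model(spec: ModelSpec, rng: np.random.Generator | None = None) -> TrainedModel:
    """Instantiate an untrained model of the requested family."""
    rng = rng or np.random.default_rng(0)
    net = _build_net(spec, rng)
    disc = None
    if spec.family == "cgan":
        disc = PatchDiscriminator(spec.in_slices + 1, spec.base_width, rng)
    return TrainedModel(spec=spec, net=net, disc=disc)


def _load_training_arrays(manifest: Manifest, channel: str, in_slices: int):
    stacks, targets = [], []
    for row in manifest.rows:
        pair = load_pair(row, root=manifest.root)
        if channel not in pair.targets:
            raise ValidationError(f"pair {row.pair_id} lacks channel {channel!r}")
        if pair.n_slices != in_slices:
            raise ValidationError(
                f"pair {row.pair_id} has {pair.n_slices} slices, spec wants {in_slices}")
        stacks.append(pair.dic_stack)
        targets.append(pair.targets[channel][None])
    return np.stack(stacks), np.stack(targets)


def train(
    model: TrainedModel,
    train_manifest: Manifest,
    channel: str,
    hp: dict | None = None,
    rng: np.random.Generator | None = None,
    val_fraction: float = 0.2,
    patience: int = 10,
    min_epochs: int = 30,
) -> TrainedModel:
    """Train (in place) on the ``train`` rows of a manifest.

    A validation subset (last ``val_fraction`` of the training rows, at
    least one pair when there are >= 5) is held out for per-epoch PCC;
    the best-validation weights are restored at the end.  NaN loss aborts
    with :class:`TrainingDivergedError`.
    """
    rng = rng or np.random.default_rng(0)
    hp = dict(hp or {})
    spec = model.spec
    lr = float(hp.get("lr", spec.lr))
    batch = int(hp.get("batch_size", spec.batch_size))
    epochs = int(hp.get("epochs", spec.epochs))
    lr_decay = float(hp.get("lr_decay", spec.lr_decay))
    rows = [r for r in train_manifest.rows if r.split == "train"] or train_manifest.rows
    if not rows:
        raise ValidationError("empty training manifest")
    sub = Manifest(rows=rows, root=train_manifest.root)
    X, Y = _load_training_arrays(sub, channel, spec.in_slices)
    n = X.shape[0]
    n_val = int(round(val_fraction * n)) if n >= 5 else 0
    if n_val:
        Xtr, Ytr, Xva, Yva = X[:-n_val], Y[:-n_val], X[-n_val:], Y[-n_val:]
    else:
        Xtr, Ytr, Xva, Yva = X, Y, X, Y
    if epochs <= 0:
        return model

    is_cgan = spec.family == "cgan"
    opt = Adam(model.net.parameters(), lr=lr)
    dopt = Adam(model.disc.parameters(), lr=lr) if is_cgan else None
    best_state, best_pcc = None, -np.inf
    bad_evals = 0
    ntr = Xtr.shape[0]
    steps_per_epoch = max(1, int(np.ceil(ntr / batch)))
    for epoch in range(epochs):
        order = rng.permutation(ntr)
        for s in range(steps_per_epoch):
            idx = order[s * batch:(s + 1) * batch]
            if idx.size == 0:
                continue
            xb, yb = Xtr[idx], Ytr[idx]
            if is_cgan:
                loss_val = _cgan_step(model, xb, yb, opt, dopt, spec.lambda_l1)
            else:
                pred = model.net(Var(xb))
                loss = ad.mae_loss(pred, yb)
                model.net.zero_grad()
                loss.backward()
                opt.step()
                loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss_val}")
            model.log["loss"].append(loss_val)
        # per-epoch validation PCC
        val_pred = model.net(Var(Xva)).data
        vp = float(np.mean([pcc(val_pred[i, 0], Yva[i, 0]) for i in range(len(Xva))]))
        model.log["val_pcc"].append(vp)
        if vp > best_pcc:
            best_pcc, best_state = vp, model.state_dict()
            bad_evals = 0
        else:
            bad_evals += 1
            # the MAE objective sits on a constant-output plateau early on;
            # don't let the plateau trigger the stop before min_epochs
            if bad_evals >= patience and epoch + 1 >= min_epochs:
                logger.info("early stop at epoch %d (best val PCC %.3f)", epoch, best_pcc)
                break
        opt.lr *= lr_decay
        if dopt is not None:
            dopt.lr *= lr_decay
    if best_state is not None:
        model.load_state_dict(best_state)
    if not model.pretrain_dataset_id and rows:
        model.pretrain_dataset_id = rows[0].dataset_id
    return model


def _cgan_step(model: TrainedModel, xb: np.ndarray, yb: np.ndarray,
               gopt: Adam, dopt: Adam, lambda_l1: float) -> float:
    """One LSGAN + L1 update of discriminator then generator."""
    # discriminator: real pairs -> 1, fake pairs -> 0
    fake = model.net(Var(xb)).data            # detached
    d_real = model.disc(Var(np.concatenate([xb, yb], axis=1)))
    d_fake = model.disc(Var(np.concatenate([xb, fake], axis=1)))
    d_loss = ad.add(ad.mul(ad.mse_loss(d_real, np.ones_like(d_real.data)), 0.5),
                    ad.mul(ad.mse_loss(d_fake, np.zeros_like(d_fake.data)), 0.5))
    model.disc.zero_grad()
    d_loss.backward()
    dopt.step()
    # generator: fool the discriminator + L1 to target
    gen = model.net(Var(xb))
    d_gen = model.disc(ad.concat_channels([Var(xb), gen]))
    g_adv = ad.mul(ad.mse_loss(d_gen, np.ones_like(d_gen.data)), 0.5)
    g_l1 = ad.mae_loss(gen, yb)
    g_loss = ad.add(g_adv, ad.mul(g_l1, lambda_l1))
    model.net.zero_grad()
    model.disc.zero_grad()       # generator step must not move the critic
    g_loss.backward()
    gopt.step()
    if not (np.isfinite(d_loss.data) and np.isfinite(g_loss.data)):
        raise TrainingDivergedError("cGAN loss diverged")
    return float(g_l1.data)
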