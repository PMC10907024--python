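"""Shared data model, file I/O, manifests and seeded randomness.

The working intensity domain everywhere in this package is float64 in
[0, 1]; integer TIFFs are rescaled by their dtype maximum on load and
quantized to 16 bit on write.  Image coordinates are (row, col), 0-based;
masks are boolean arrays of the same shape as the image they refer to.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("cellvstain")

#: channel vocabulary used by manifests and targets
KNOWN_CHANNELS = ("factin", "nuclei")


class CellVStainError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(CellVStainError):
    """An input violated a documented contract."""


class PlacementError(CellVStainError):
    """A paste location could not be used (out of bounds / border contact)."""


class DependencyError(CellVStainError):
    """A pipeline stage was run before the stages it depends on."""


class TrainingDivergedError(CellVStainError):
    """Optimization produced a non-finite loss."""


def seeded_rng(seed: int) -> np.random.Generator:
    """Return a deterministic random source for the whole pipeline.

    The same seed yields bit-identical stochastic decisions (paste
    locations, rescales, weight initialization) on the same platform.
    """
    if seed < 0:
        raise ValidationError(f"seed must be >= 0, got {seed}")
    return np.random.default_rng(int(seed))


def derive_seed(rng: np.random.Generator) -> int:
    """Draw a child seed (< 2**31) for a sub-stage or external library."""
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class ImagePair:
    """One training/evaluation unit: a DIC z-stack plus fluorescence targets.

    Attributes
    ----------
    dic_stack:
        float array of shape (n_slices, rows, cols) in [0, 1].
    targets:
        mapping channel name -> 2-D float array matching the slice shape.
    pixel_size_um:
        physical pixel size; used to convert morphometric areas/lengths.
    """

    id: str
    dic_stack: np.ndarray
    targets: dict[str, np.ndarray]
    dataset_id: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.dic_stack = np.asarray(self.dic_stack, dtype=np.float64)
        if self.dic_stack.ndim == 2:
            self.dic_stack = self.dic_stack[None]
        if self.dic_stack.ndim != 3 or self.dic_stack.shape[0] < 1:
            raise ValidationError(
                f"dic_stack must be (slices, rows, cols) with >= 1 slice, "
                f"got shape {self.dic_stack.shape}"
            )
        if not np.isfinite(self.dic_stack).all():
            raise ValidationError("dic_stack contains non-finite values")
        shape = self.dic_stack.shape[1:]
        clean = {}
        for name, arr in self.targets.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != shape:
                raise ValidationError(
                    f"target {name!r} shape {arr.shape} != DIC slice shape {shape}"
                )
            if not np.isfinite(arr).all():
                raise ValidationError(f"target {name!r} contains non-finite values")
            clean[name] = arr
        self.targets = clean

    @property
    def shape(self) -> tuple[int, int]:
        return self.dic_stack.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.dic_stack.shape[0]

    def copy(self) -> "ImagePair":
        return ImagePair(
            id=self.id,
            dic_stack=self.dic_stack.copy(),
            targets={k: v.copy() for k, v in self.targets.items()},
            dataset_id=self.dataset_id,
            pixel_size_um=self.pixel_size_um,
        )


@dataclass
class DatasetDescriptor:
    """A named dataset: the unit the matcher classifies over."""

    dataset_id: str
    magnification: str = "10x"
    pixel_size_um: float = 1.0
    channels: tuple[str, ...] = KNOWN_CHANNELS
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        for ch in self.channels:
            if ch not in KNOWN_CHANNELS:
                raise ValidationError(
                    f"unknown channel {ch!r}; known: {KNOWN_CHANNELS}"
                )


@dataclass
class ManifestRow:
    pair_id: str
    dic_path: str
    target_paths: dict[str, str]
    dataset_id: str = ""
    split: str = "train"
    pixel_size_um: float = 1.0


@dataclass
class Manifest:
    """A CSV-backed list of image pairs; paths are relative to ``root``."""

    rows: list[ManifestRow] = field(default_factory=list)
    root: Path = Path(".")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[ManifestRow]:
        return iter(self.rows)

    def subset(self, split: str | None = None, ids: Sequence[str] | None = None) -> "Manifest":
        rows = self.rows
        if split is not None:
            rows = [r for r in rows if r.split == split]
        if ids is not None:
            keep = set(ids)
            rows = [r for r in rows if r.pair_id in keep]
        return Manifest(rows=list(rows), root=self.root)

    @property
    def channels(self) -> tuple[str, ...]:
        if not self.rows:
            return ()
        return tuple(sorted(self.rows[0].target_paths))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        records = []
        for r in self.rows:
            rec = {
                "pair_id": r.pair_id,
                "dic_path": r.dic_path,
                "dataset_id": r.dataset_id,
                "split": r.split,
                "pixel_size_um": r.pixel_size_um,
            }
            for ch, p in r.target_paths.items():
                rec[f"target_{ch}"] = p
            records.append(rec)
        pd.DataFrame.from_records(records).to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        path = Path(path)
        df = pd.read_csv(path)
        target_cols = [c for c in df.columns if c.startswith("target_")]
        rows = []
        for rec in df.to_dict("records"):
            rows.append(
                ManifestRow(
                    pair_id=str(rec["pair_id"]),
                    dic_path=str(rec["dic_path"]),
                    target_paths={
                        c[len("target_"):]: str(rec[c]) for c in target_cols
                    },
                    dataset_id=str(rec.get("dataset_id", "")),
                    split=str(rec.get("split", "train")),
                    pixel_size_um=float(rec.get("pixel_size_um", 1.0)),
                )
            )
        return cls(rows=rows, root=path.parent)


def _read_grayscale_tiff(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim not in (2, 3):
        raise ValidationError(f"{path}: expected grayscale 2-D/3-D TIFF, got shape {arr.shape}")
    return arr


def normalize_intensity(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer image by its dtype max; pass floats through.

    Float inputs must already be in [0, 1].
    """
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    arr = arr.astype(np.float64)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValidationError(
            "float images must be in [0, 1]; "
            f"got range [{np.nanmin(arr):.3g}, {np.nanmax(arr):.3g}]"
        )
    return arr


def load_pair(row: ManifestRow, root: str | Path = ".") -> ImagePair:
    """Load a manifest row into an :class:`ImagePair` with [0, 1] intensities."""
    root = Path(root)
    dic = normalize_intensity(_read_grayscale_tiff(root / row.dic_path))
    if dic.ndim == 2:
        dic = dic[None]
    targets = {}
    for ch, rel in row.target_paths.items():
        t = normalize_intensity(_read_grayscale_tiff(root / rel))
        if t.ndim == 3:
            if t.shape[0] != 1:
                raise ValidationError(f"target {ch!r} must be single-page, got {t.shape}")
            t = t[0]
        targets[ch] = t
    return ImagePair(
        id=row.pair_id,
        dic_stack=dic,
        targets=targets,
        dataset_id=row.dataset_id,
        pixel_size_um=row.pixel_size_um,
    )


def write_prediction(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] intensity image as a 16-bit grayscale TIFF.

    Round-trip quantization error is at most 1/65535.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValidationError("prediction contains non-finite values")
    if image.size and (image.min() < -1e-9 or image.max() > 1 + 1e-9):
        raise ValidationError("prediction values must lie in [0, 1]")
    q = np.round(np.clip(image, 0.0, 1.0) * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), q, photometric="minisblack")


def write_image_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (slices, rows, cols) [0, 1] stack as a multi-page 16-bit TIFF."""
    stack = np.asarray(stack, dtype=np.float64)
    if not np.isfinite(stack).all():
        raise ValidationError("stack contains non-finite values")
    q = np.round(np.clip(stack, 0.0, 1.0) * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), q, photometric="minisblack")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(cfg: Mapping, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(dict(cfg), sort_keys=False))
    else:
        path.write_text(json.dumps(dict(cfg), indent=2))


@contextmanager
def stage_timer(name: str):
    """Log wall-clock duration of a pipeline stage to the package logger."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
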