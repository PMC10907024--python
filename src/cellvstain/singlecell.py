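"""Single-cell morphometry from (virtually) stained F-actin and nuclei.

The mechanobiological profile of a cell is summarized by 17 features:
8 basic size/shape parameters (area, perimeter, minor and major axis, for
cell and nucleus), compactness / eccentricity / major-axis angle for both
compartments, the two mean intensities, and the nuclear/cytoplasmic area
ratio.  Conventions: perimeter is the 4-direction Crofton estimator,
axes come from the equivalent-ellipse second central moments, the angle is
measured from the row axis and reported in degrees in [-90, 90), and all
lengths/areas are physical (micrometres) given the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .core import ValidationError, logger

#: canonical ordering of the 17 single-cell features
FEATURE_NAMES: tuple[str, ...] = (
    "cell_area",
    "cell_perimeter",
    "cell_minor_axis",
    "cell_major_axis",
    "nuc_area",
    "nuc_perimeter",
    "nuc_minor_axis",
    "nuc_major_axis",
    "cell_compactness",
    "nuc_compactness",
    "cell_eccentricity",
    "nuc_eccentricity",
    "cell_angle",
    "nuc_angle",
    "cell_mean_intensity",
    "nuc_mean_intensity",
    "nc_ratio",
)

BASIC_FEATURES: tuple[str, ...] = FEATURE_NAMES[:8]


@dataclass
class SingleCellSegmentation:
    """Cell and nucleus masks for one cell; nucleus is inside the cell."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    provenance: str = "connected-component"   # or "manual"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValidationError("cell and nucleus masks must share a shape")
        if not self.cell_mask.any() or not self.nucleus_mask.any():
            raise ValidationError("masks must be non-empty")
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise ValidationError("nucleus mask must lie inside the cell mask")

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.cell_mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class CellFeatureVector:
    values: dict[str, float]
    pixel_size_um: float = 1.0
    source_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=np.float64)

    def __len__(self) -> int:
        return len(FEATURE_NAMES)


@dataclass
class SegmentationParams:
    min_area: int = 50
    nucleus_min_area: int = 10
    smooth_sigma: float = 1.0
    require_single_nucleus: bool = True
    exclude_border: bool = False


def _binarize(image: np.ndarray, sigma: float) -> np.ndarray:
    from skimage.filters import threshold_otsu

    smoothed = ndi.gaussian_filter(image, sigma) if sigma > 0 else image
    if smoothed.max() - smoothed.min() < 1e-9:
        return np.zeros_like(image, dtype=bool)
    mask = smoothed > threshold_otsu(smoothed)
    return ndi.binary_fill_holes(mask)


def segment_from_stains(
    factin: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams | None = None,
    source_id: str = "",
) -> list[SingleCellSegmentation]:
    """Cell masks from binarized F-actin, nuclei from the nuclear stain.

    Each F-actin connected component becomes a candidate cell; nuclear
    components are assigned to the cell that contains most of their area.
    Cells without exactly one nucleus are excluded (binucleate or anucleate
    artifacts) unless ``require_single_nucleus`` is off.
    """
    params = params or SegmentationParams()
    if factin.shape != nuclei.shape:
        raise ValidationError("F-actin and nuclei images must be co-registered")
    cell_lab, n_cells = ndi.label(_binarize(factin, params.smooth_sigma),
                                  structure=np.ones((3, 3)))
    nuc_lab, n_nuc = ndi.label(_binarize(nuclei, params.smooth_sigma),
                               structure=np.ones((3, 3)))
    assigned: dict[int, list[int]] = {}
    for j in range(1, n_nuc + 1):
        nmask = nuc_lab == j
        if nmask.sum() < params.nucleus_min_area:
            continue
        owners = cell_lab[nmask]
        owners = owners[owners > 0]
        if owners.size == 0:
            continue
        host = int(np.bincount(owners).argmax())
        assigned.setdefault(host, []).append(j)
    out = []
    for i in range(1, n_cells + 1):
        cmask = cell_lab == i
        if cmask.sum() < params.min_area:
            continue
        if params.exclude_border:
            rr, cc = np.nonzero(cmask)
            if (rr.min() == 0 or cc.min() == 0 or rr.max() == cmask.shape[0] - 1
                    or cc.max() == cmask.shape[1] - 1):
                continue
        nucs = assigned.get(i, [])
        if params.require_single_nucleus and len(nucs) != 1:
            logger.info("cell %d in %s excluded: %d nuclei", i, source_id, len(nucs))
            continue
        if not nucs:
            continue
        nmask = np.isin(nuc_lab, nucs) & cmask
        if not nmask.any():
            continue
        out.append(SingleCellSegmentation(
            cell_mask=cmask, nucleus_mask=nmask,
            provenance="connected-component", source_id=source_id,
        ))
    return out


def _region(mask: np.ndarray):
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        raise ValidationError("empty mask")
    return props[0]


def _angle_deg(orientation: float) -> float:
    """Map skimage orientation (radians) to degrees in [-90, 90)."""
    deg = np.degrees(orientation)
    if deg >= 90.0:
        deg -= 180.0
    if deg < -90.0:
        deg += 180.0
    return float(deg)


def extract_features(
    seg: SingleCellSegmentation,
    factin: np.ndarray,
    nuclei: np.ndarray,
    pixel_size_um: float = 1.0,
) -> CellFeatureVector:
    """Compute the 17-feature mechanobiological profile of one cell."""
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    ps = pixel_size_um
    cell = _region(seg.cell_mask)
    nuc = _region(seg.nucleus_mask)
    cell_area_px = float(cell.area)
    nuc_area_px = float(nuc.area)
    cyto_px = cell_area_px - nuc_area_px
    if cyto_px <= 0:
        raise ValidationError("zero cytoplasm: nucleus fills the cell mask")
    cp = float(cell.perimeter_crofton)
    np_ = float(nuc.perimeter_crofton)
    vals = {
        "cell_area": cell_area_px * ps ** 2,
        "cell_perimeter": cp * ps,
        "cell_minor_axis": float(cell.axis_minor_length) * ps,
        "cell_major_axis": float(cell.axis_major_length) * ps,
        "nuc_area": nuc_area_px * ps ** 2,
        "nuc_perimeter": np_ * ps,
        "nuc_minor_axis": float(nuc.axis_minor_length) * ps,
        "nuc_major_axis": float(nuc.axis_major_length) * ps,
        "cell_compactness": 4 * np.pi * cell_area_px / cp ** 2,
        "nuc_compactness": 4 * np.pi * nuc_area_px / np_ ** 2,
        "cell_eccentricity": float(cell.eccentricity),
        "nuc_eccentricity": float(nuc.eccentricity),
        "cell_angle": _angle_deg(float(cell.orientation)),
        "nuc_angle": _angle_deg(float(nuc.orientation)),
        "cell_mean_intensity": float(factin[seg.cell_mask].mean()),
        "nuc_mean_intensity": float(nuclei[seg.nucleus_mask].mean()),
        "nc_ratio": nuc_area_px / cyto_px,
    }
    for k, v in vals.items():
        if not np.isfinite(v):
            raise ValidationError(f"non-finite feature {k}")
    return CellFeatureVector(values=vals, pixel_size_um=ps, source_id=seg.source_id)


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = (a & b).sum()
    union = (a | b).sum()
    return inter / union if union else 0.0


def profile_dataset(
    segmentations: list[SingleCellSegmentation],
    factin_images: dict[str, np.ndarray],
    nuclei_images: dict[str, np.ndarray],
    pixel_size_um: float = 1.0,
    out: str | Path | None = None,
    truth_segmentations: list[SingleCellSegmentation] | None = None,
    min_match_iou: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, float] | None]:
    """One feature row per cell; optional agreement stats vs ground truth.

    When ``truth_segmentations`` is given, predicted cells are matched to
    ground-truth cells of the same source image by best mask IoU, and the
    Pearson r between predicted- and truth-derived values is reported per
    feature (requires >= 3 matched cells).
    """
    if not segmentations:
        logger.warning("profile_dataset: no cells")
        return pd.DataFrame(columns=list(FEATURE_NAMES)), None
    rows = []
    feats = []
    for seg in segmentations:
        fv = extract_features(seg, factin_images[seg.source_id],
                              nuclei_images[seg.source_id], pixel_size_um)
        feats.append(fv)
        rows.append({"source_id": seg.source_id, "provenance": seg.provenance,
                     **fv.values})
    table = pd.DataFrame(rows)
    agreement = None
    if truth_segmentations is not None:
        from .metrics import pcc

        pred_rows, truth_rows = [], []
        for tseg in truth_segmentations:
            best, best_iou = None, min_match_iou
            for seg, fv in zip(segmentations, feats):
                if seg.source_id != tseg.source_id:
                    continue
                i = _iou(seg.cell_mask, tseg.cell_mask)
                if i > best_iou:
                    best, best_iou = fv, i
            if best is None:
                continue
            tfv = extract_features(tseg, factin_images[tseg.source_id],
                                   nuclei_images[tseg.source_id], pixel_size_um)
            pred_rows.append(best.as_array())
            truth_rows.append(tfv.as_array())
        if len(pred_rows) >= 3:
            P = np.array(pred_rows)
            T = np.array(truth_rows)
            agreement = {
                name: float(pcc(P[:, i], T[:, i]))
                for i, name in enumerate(FEATURE_NAMES)
            }
            agreement["n_matched"] = len(pred_rows)
    if out is not None:
        table.to_csv(out, index=False)
    return table, agreement


@dataclass
class CellTrack:
    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    features: list[CellFeatureVector] = field(default_factory=list)
    division_frame: int | None = None
    parent: int | None = None


def track_over_time(
    frames: list[dict[str, np.ndarray]],
    params: SegmentationParams | None = None,
    pixel_size_um: float = 1.0,
    gate_px: float = 10.0,
) -> list[CellTrack]:
    """Per-frame segmentation + nearest-centroid linking of cells.

    ``frames`` is an ordered list of dicts with ``factin`` and ``nuclei``
    images (e.g. virtual stains of a live acquisition).  A division is
    flagged when two current cells link back to the same track; the track
    records the division frame and two child tracks are spawned.
    """
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    active_masks: list[np.ndarray] = []
    next_id = 0
    for t, frame in enumerate(frames):
        fa = frame["factin"] if isinstance(frame, dict) else frame.targets["factin"]
        nu = frame["nuclei"] if isinstance(frame, dict) else frame.targets["nuclei"]
        segs = segment_from_stains(fa, nu, params, source_id=f"frame{t}")
        claims: dict[int, list[tuple[float, SingleCellSegmentation]]] = {}
        unmatched = []
        for seg in segs:
            cy, cx = seg.centroid
            best_k, best_d = None, gate_px
            for k in range(len(active)):
                py, px = active[k].centroids[-1]
                d = float(np.hypot(cy - py, cx - px))
                if best_k is not None and abs(d - best_d) <= 1e-6:
                    # equal-distance tie: prefer larger mask overlap
                    if _iou(seg.cell_mask, active_masks[k]) > _iou(
                            seg.cell_mask, active_masks[best_k]):
                        best_k, best_d = k, d
                        logger.info("frame %d: linking tie broken by overlap", t)
                elif d < best_d:
                    best_k, best_d = k, d
            if best_k is None:
                unmatched.append(seg)
            else:
                claims.setdefault(best_k, []).append((best_d, seg))

        def _extend(tr: CellTrack, seg: SingleCellSegmentation) -> None:
            tr.frames.append(t)
            tr.centroids.append(seg.centroid)
            tr.features.append(extract_features(seg, fa, nu, pixel_size_um))

        survivors: list[CellTrack] = []
        survivor_masks: list[np.ndarray] = []
        for k, tr in enumerate(active):
            got = sorted(claims.get(k, []), key=lambda x: x[0])
            if not got:
                continue
            if len(got) == 1:
                _, seg = got[0]
                _extend(tr, seg)
                survivors.append(tr)
                survivor_masks.append(seg.cell_mask)
            else:
                tr.division_frame = t
                for _, seg in got[:2]:
                    child = CellTrack(track_id=next_id, parent=tr.track_id)
                    next_id += 1
                    _extend(child, seg)
                    tracks.append(child)
                    survivors.append(child)
                    survivor_masks.append(seg.cell_mask)
        for seg in unmatched:
            tr = CellTrack(track_id=next_id)
            next_id += 1
            _extend(tr, seg)
            tracks.append(tr)
            survivors.append(tr)
            survivor_masks.append(seg.cell_mask)
        active, active_masks = survivors, survivor_masks
    return tracks
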