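import numpy as np
import pytest

from cellvstain.core import ValidationError, seeded_rng
from cellvstain import synthdata as sd
from cellvstain.singlecell import (
    BASIC_FEATURES,
    FEATURE_NAMES,
    SegmentationParams,
    SingleCellSegmentation,
    extract_features,
    profile_dataset,
    segment_from_stains,
    track_over_time,
)


def _disk(radius, shape=(64, 64), center=None):
    c = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius ** 2


def _ellipse(a, b, theta=0.0, shape=(128, 128), center=None):
    c = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    dr, dc = yy - c[0], xx - c[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _seg(cell_mask, nucleus_scale=0.4):
    """Segmentation with a concentric scaled-down nucleus."""
    from scipy import ndimage as ndi

    r = int(np.sqrt(cell_mask.sum() / np.pi) * nucleus_scale)
    cy, cx = ndi.center_of_mass(cell_mask)
    nuc = _disk(max(r, 2), cell_mask.shape, (int(cy), int(cx))) & cell_mask
    return SingleCellSegmentation(cell_mask=cell_mask, nucleus_mask=nuc)


class TestMorphometryOracles:
    def test_digital_disk_recovery(self):
        """Disk r=20 px, 1 um pixels: area within 2% of pi r^2, nearly
        circular (eccentricity <= 0.05), compactness in [0.95, 1.1]."""
        seg = _seg(_disk(20))
        fv = extract_features(seg, np.full((64, 64), 0.5), np.full((64, 64), 0.5), 1.0)
        assert fv.values["cell_area"] == pytest.approx(np.pi * 400, rel=0.02)
        assert fv.values["cell_eccentricity"] <= 0.05
        assert 0.95 <= fv.values["cell_compactness"] <= 1.1

    def test_ellipse_axes_and_angle(self):
        """Axis-aligned ellipse (a=30, b=10): axes within 3% of 60/20 px,
        angle within 2 degrees of 0."""
        seg = _seg(_ellipse(30, 10))
        fv = extract_features(seg, np.zeros((128, 128)), np.zeros((128, 128)), 1.0)
        assert fv.values["cell_major_axis"] == pytest.approx(60, rel=0.03)
        assert fv.values["cell_minor_axis"] == pytest.approx(20, rel=0.03)
        assert abs(fv.values["cell_angle"]) <= 2.0

    @pytest.mark.parametrize("phi_deg", [20, 45, 70])
    def test_rotation_equivariance(self, phi_deg):
        """Rotating the ellipse by phi shifts the angle feature by phi
        (mod 180) within 2 degrees and keeps sizes within 3%."""
        base = _seg(_ellipse(30, 14, theta=0.0))
        rot = _seg(_ellipse(30, 14, theta=np.radians(phi_deg)))
        z = np.zeros((128, 128))
        f0 = extract_features(base, z, z, 1.0)
        f1 = extract_features(rot, z, z, 1.0)
        d = (f1.values["cell_angle"] - f0.values["cell_angle"]) % 180.0
        assert min(abs(d - phi_deg), abs(d - phi_deg + 180), abs(d - phi_deg - 180)) <= 2.0
        for k in ("cell_area", "cell_perimeter", "cell_major_axis", "cell_minor_axis"):
            assert f1.values[k] == pytest.approx(f0.values[k], rel=0.03)

    def test_scale_law(self):
        """Doubling the object (re-rasterized at x2 scale) multiplies area
        by 4 and lengths by 2 within 3%."""
        mask = _ellipse(20, 12, theta=0.3, shape=(96, 96))
        big = _ellipse(40, 24, theta=0.3, shape=(192, 192))
        f_small = extract_features(_seg(mask), np.zeros(mask.shape),
                                   np.zeros(mask.shape), 1.0)
        f_big = extract_features(_seg(big), np.zeros(big.shape),
                                 np.zeros(big.shape), 1.0)
        assert f_big.values["cell_area"] == pytest.approx(
            4 * f_small.values["cell_area"], rel=0.03)
        for k in ("cell_perimeter", "cell_major_axis", "cell_minor_axis"):
            assert f_big.values[k] == pytest.approx(2 * f_small.values[k], rel=0.03)

    def test_pixel_size_conversion(self):
        seg = _seg(_disk(15))
        f1 = extract_features(seg, np.zeros((64, 64)), np.zeros((64, 64)), 1.0)
        f2 = extract_features(seg, np.zeros((64, 64)), np.zeros((64, 64)), 0.5)
        assert f2.values["cell_area"] == pytest.approx(0.25 * f1.values["cell_area"])
        assert f2.values["cell_perimeter"] == pytest.approx(0.5 * f1.values["cell_perimeter"])

    def test_uniform_intensity_means(self):
        seg = _seg(_disk(15))
        fv = extract_features(seg, np.full((64, 64), 0.5), np.full((64, 64), 0.5), 1.0)
        assert fv.values["cell_mean_intensity"] == pytest.approx(0.5)
        assert fv.values["nuc_mean_intensity"] == pytest.approx(0.5)

    def test_seventeen_finite_features(self):
        seg = _seg(_disk(12))
        fv = extract_features(seg, np.full((64, 64), 0.3), np.full((64, 64), 0.7), 1.0)
        arr = fv.as_array()
        assert arr.shape == (17,)
        assert np.isfinite(arr).all()
        assert list(fv.values) == list(FEATURE_NAMES)

    def test_zero_cytoplasm_rejected(self):
        mask = _disk(10)
        seg = SingleCellSegmentation(cell_mask=mask, nucleus_mask=mask)
        with pytest.raises(ValidationError, match="cytoplasm"):
            extract_features(seg, np.zeros((64, 64)), np.zeros((64, 64)), 1.0)


class TestSegmentation:
    def test_synthetic_scene_recovered(self, round_scene):
        segs = segment_from_stains(round_scene.factin, round_scene.nuclei,
                                   SegmentationParams(min_area=40))
        assert len(segs) == len(round_scene.cells)
        for s in segs:
            assert not (s.nucleus_mask & ~s.cell_mask).any()
            assert s.nucleus_mask.sum() <= s.cell_mask.sum()

    def test_binucleate_cell_excluded(self):
        fa = np.full((64, 64), 0.05)
        nu = np.full((64, 64), 0.05)
        fa[_ellipse(20, 14, shape=(64, 64))] = 0.8
        nu[_disk(5, (64, 64), (32, 22))] = 0.9
        nu[_disk(5, (64, 64), (32, 42))] = 0.9
        segs = segment_from_stains(fa, nu, SegmentationParams(min_area=40))
        assert segs == []
        relaxed = segment_from_stains(
            fa, nu, SegmentationParams(min_area=40, require_single_nucleus=False))
        assert len(relaxed) == 1

    def test_manual_mask_bypass(self):
        """Provided masks pass through unchanged (manual provenance)."""
        seg = SingleCellSegmentation(cell_mask=_disk(12), nucleus_mask=_disk(5),
                                     provenance="manual")
        assert seg.provenance == "manual"
        assert seg.cell_mask.sum() > seg.nucleus_mask.sum()

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValidationError):
            SingleCellSegmentation(cell_mask=_disk(5),
                                   nucleus_mask=_disk(10))


class TestProfileDataset:
    def test_self_agreement_is_perfect(self, round_scene):
        segs = [
            SingleCellSegmentation(cell_mask=c, nucleus_mask=n, source_id="s")
            for c, n in zip(round_scene.cell_masks, round_scene.nucleus_masks)
        ]
        table, agreement = profile_dataset(
            segs, {"s": round_scene.factin}, {"s": round_scene.nuclei},
            truth_segmentations=segs)
        assert len(table) == len(segs)
        for k in BASIC_FEATURES:
            assert agreement[k] == pytest.approx(1.0, abs=1e-6)

    def test_empty_input_warns(self):
        table, agreement = profile_dataset([], {}, {})
        assert table.empty and agreement is None


class TestTracking:
    @staticmethod
    def _frame(centers, shape=(96, 96), a=12, b=9):
        fa = np.full(shape, 0.05)
        nu = np.full(shape, 0.05)
        for (cy, cx) in centers:
            fa[_ellipse(a, b, shape=shape, center=(cy, cx))] = 0.8
            nu[_disk(4, shape, (cy, cx))] = 0.9
        return {"factin": fa, "nuclei": nu}

    def test_static_cell_constant_features(self):
        frames = [self._frame([(48, 48)]) for _ in range(5)]
        tracks = track_over_time(frames, SegmentationParams(min_area=40))
        assert len(tracks) == 1
        areas = [f.values["cell_area"] for f in tracks[0].features]
        assert np.ptp(areas) / np.mean(areas) <= 0.02

    def test_translation_tracked(self):
        frames = [self._frame([(30, 30 + 3 * t)]) for t in range(5)]
        tracks = track_over_time(frames, SegmentationParams(min_area=40))
        assert len(tracks) == 1
        cs = tracks[0].centroids
        steps = [np.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(cs, cs[1:])]
        assert all(abs(s - 3.0) < 1.0 for s in steps)

    def test_division_flagged(self):
        frames = [
            self._frame([(48, 48)]),
            self._frame([(48, 48)]),
            self._frame([(42, 40), (54, 56)], a=9, b=7),
        ]
        tracks = track_over_time(frames, SegmentationParams(min_area=30),
                                 gate_px=15.0)
        parents = [t for t in tracks if t.division_frame is not None]
        assert len(parents) == 1
        assert parents[0].division_frame == 2
        children = [t for t in tracks if t.parent == parents[0].track_id]
        assert len(children) == 2
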