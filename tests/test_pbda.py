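import warnings

import numpy as np
import pytest

from cellvstain.core import PlacementError, ValidationError, seeded_rng
from cellvstain import pbda
from cellvstain import synthdata as sd
from helpers import dense_poisson_oracle


def _two_ellipse_image():
    img = np.full((64, 64), 0.1)
    yy, xx = np.mgrid[0:64, 0:64]
    img[((yy - 18) / 8) ** 2 + ((xx - 18) / 11) ** 2 <= 1] = 0.8
    img[((yy - 46) / 9) ** 2 + ((xx - 44) / 7) ** 2 <= 1] = 0.7
    return img


class TestBinarize:
    def test_two_components(self):
        mask = pbda.binarize_factin(_two_ellipse_image())
        from scipy import ndimage as ndi
        _, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert n == 2

    def test_constant_image_empty_mask(self):
        mask = pbda.binarize_factin(np.full((32, 32), 0.4))
        assert not mask.any()

    def test_iou_against_ground_truth(self, round_scene):
        mask = pbda.binarize_factin(round_scene.factin)
        for cm in round_scene.cell_masks:
            inter = (mask & cm).sum()
            union = (mask & cm).sum() + (~mask & cm).sum() + 0.0
            # per-cell IoU restricted to the cell's neighbourhood
            iou = inter / (cm | (mask & cm)).sum()
            assert iou >= 0.9

    def test_fixed_method_needs_level(self):
        with pytest.raises(ValidationError):
            pbda.binarize_factin(_two_ellipse_image(), method="fixed")


class TestExtractInstances:
    def test_one_instance_per_cell(self, round_scene):
        pair = sd.scene_to_pair(round_scene, 3)
        mask = pbda.binarize_factin(round_scene.factin)
        inst = pbda.extract_instances(pair, mask, min_area=40)
        assert len(inst) == len(round_scene.cells)
        for i in inst:
            assert i.mask.any()
            # fluorescence zeroed outside the mask
            assert i.factin_patch[~i.mask].max() == 0.0
            assert i.dic_patch.shape[1:] == i.mask.shape

    def test_min_area_filter(self, round_scene):
        pair = sd.scene_to_pair(round_scene, 3)
        mask = pbda.binarize_factin(round_scene.factin)
        assert pbda.extract_instances(pair, mask, min_area=10**6) == []

    def test_desk_scale_pool_count(self, tmp_path):
        """Every generated cell lands in the source pool (the full-scale
        run isolates thousands; the desk analog is exact by construction)."""
        from cellvstain.core import DatasetDescriptor, load_pair

        rng = seeded_rng(9)
        n_expected = 0
        pairs = []
        for k in range(6):
            scene = sd.generate_scene(3, "round", (96, 96), rng=rng)
            n_expected += len(scene.cells)
            pairs.append(sd.scene_to_pair(scene, 3, pair_id=f"s{k}"))
        pool = pbda.build_source_pool(pairs, min_area=40)
        assert len(pool) == n_expected


class TestPoissonBlend:
    def test_empty_mask_identity(self):
        t = seeded_rng(2).random((20, 20))
        out = pbda.poisson_blend(np.zeros((8, 8)), t, np.zeros((8, 8), bool), (3, 3))
        np.testing.assert_array_equal(out, t)

    def test_identical_source_is_identity(self):
        """When source equals the overlapped target region the Dirichlet
        problem's unique solution is the target itself."""
        t = seeded_rng(2).random((20, 20)) * 0.2 + 0.4
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        out = pbda.poisson_blend(t[5:13, 5:13].copy(), t, mask, (5, 5))
        assert np.abs(out - t).max() < 1e-9

    def test_matches_independent_dense_solver(self):
        """Production sparse solve vs an independently assembled dense
        system, on random 32x32 cases (mid-range values, no clipping)."""
        rng = seeded_rng(11)
        for _ in range(5):
            src = rng.random((12, 12)) * 0.2 + 0.4
            tgt = rng.random((32, 32)) * 0.2 + 0.4
            mask = np.zeros((12, 12), bool)
            mask[2:10, 3:9] = True
            loc = (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
            out = pbda.poisson_blend(src, tgt, mask, loc)
            ref = dense_poisson_oracle(src, tgt, mask, loc)
            assert np.abs(out - ref).max() < 1e-5
            # boundary rows (outside mask) exactly equal the target
            assert np.array_equal(out[~_placed(mask, loc, tgt.shape)],
                                  tgt[~_placed(mask, loc, tgt.shape)])

    def test_border_touching_mask_rejected(self):
        mask = np.ones((6, 6), bool)
        with pytest.raises(PlacementError):
            pbda.poisson_blend(np.zeros((6, 6)), np.zeros((16, 16)), mask, (2, 2))

    def test_out_of_bounds_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        with pytest.raises(PlacementError):
            pbda.poisson_blend(np.zeros((8, 8)), np.zeros((16, 16)), mask, (12, 12))


def _placed(mask, loc, shape):
    full = np.zeros(shape, bool)
    full[loc[0]:loc[0] + mask.shape[0], loc[1]:loc[1] + mask.shape[1]] = mask
    return full


@pytest.fixture(scope="module")
def pool(protrusive_scene):
    pair = sd.scene_to_pair(protrusive_scene, 3)
    return pbda.build_source_pool([pair], min_area=40)


class TestSynthesizeComposite:
    def test_contract_suite(self, pool):
        """Accepted pastes: disjoint masks, scale in [0.8, 1.2], count
        <= max_cells, identical geometry across channels."""
        bg = pbda.blank_background((96, 96), 3, rng=seeded_rng(3))
        rec = pbda.synthesize_composite(pool, bg, max_cells=8, rng=seeded_rng(4))
        assert rec.n_accepted <= 8
        assert len(rec.pastes) == 8
        for p in rec.pastes:
            assert 0.8 <= p.scale <= 1.2
        # disjointness: union area equals the sum of accepted mask areas
        total = 0
        for p in rec.pastes:
            if p.accepted:
                inst = pbda._rescale_instance(pool.instances[p.instance_index], p.scale)
                total += inst.mask.sum()
        assert rec.union_mask.sum() == total
        # channel geometry: pasted nuclei foreground sits inside pasted F-actin
        nuc_fg = (rec.pair.targets["nuclei"] > 0.3) & rec.union_mask
        fa_fg = rec.union_mask
        assert (nuc_fg & ~fa_fg).sum() == 0
        # DIC foreground colocated with the paste mask
        dic_dev = np.abs(rec.pair.dic_stack[0] - 0.5)
        assert dic_dev[rec.union_mask].mean() > dic_dev[~rec.union_mask].mean()

    def test_deterministic_under_seed(self, pool):
        bg = pbda.blank_background((96, 96), 3, rng=seeded_rng(3))
        a = pbda.synthesize_composite(pool, bg, max_cells=5, rng=seeded_rng(5))
        b = pbda.synthesize_composite(pool, bg, max_cells=5, rng=seeded_rng(5))
        np.testing.assert_array_equal(a.pair.targets["factin"],
                                      b.pair.targets["factin"])
        assert [p.location for p in a.pastes] == [p.location for p in b.pastes]

    def test_too_small_background_zero_pastes(self, pool):
        bg = pbda.blank_background((64, 64), 3, rng=seeded_rng(3))
        bg.dic_stack = bg.dic_stack[:, :16, :16]
        bg.targets = {k: v[:16, :16] for k, v in bg.targets.items()}
        rec = pbda.synthesize_composite(pool, bg, max_cells=3, max_attempts=10,
                                        rng=seeded_rng(6))
        assert rec.n_accepted == 0
        assert all(not p.accepted for p in rec.pastes)

    def test_empty_pool_rejected(self):
        bg = pbda.blank_background((64, 64), 3, rng=seeded_rng(3))
        with pytest.raises(ValidationError):
            pbda.synthesize_composite(pbda.SourcePool(), bg, rng=seeded_rng(0))
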