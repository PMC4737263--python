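"""Tests of probability-density maps, ROI sampling and subtraction maps."""

import numpy as np
import pytest

from svdmap.image import GeometryError, GridMismatchError, InputError, LesionMask, VolumeImage
from svdmap.pdmap import (
    PDMap,
    RegionROI,
    default_roiset,
    pd_map,
    region_table,
    round_half_up,
    rounded_table,
    sample_roi,
    subtract_maps,
)

SHAPE = (16, 16, 16)


def _mask(voxels=(), cls="wmh"):
    data = np.zeros(SHAPE, np.uint8)
    for v in voxels:
        data[v] = 1
    return LesionMask(data, np.eye(4), lesion_class=cls)


class TestPDMap:
    def test_single_affected_subject_of_188_reports_point_005(self):
        """One lesioned subject out of 188 gives PD 1/188 -> 0.005 at 3 decimals."""
        v = (5, 6, 7)
        masks = [_mask([v])] + [_mask() for _ in range(187)]
        out = pd_map(masks, "all")
        assert out.n == 188
        assert out.data[v] == pytest.approx(1.0 / 188.0)
        assert round_half_up(out.data[v], 3) == 0.005

    def test_all_and_half_lesioned_endpoints(self):
        v = (2, 3, 4)
        full = pd_map([_mask([v]) for _ in range(8)], "all")
        assert full.data[v] == 1.0
        half = pd_map([_mask([v]) for _ in range(4)] + [_mask() for _ in range(4)], "all")
        assert half.data[v] == 0.5

    def test_affected_only_denominator(self):
        v = (1, 1, 1)
        masks = [_mask([v], cls="lacune") for _ in range(87)] + [
            _mask(cls="lacune") for _ in range(100)
        ]
        out = pd_map(masks, "affected_only")
        assert out.n == 87
        assert out.data[v] == 1.0
        with pytest.raises(InputError):
            pd_map([_mask(cls="lacune")] * 3, "affected_only")

    def test_mass_conservation_exact(self, rng):
        masks = [
            LesionMask((rng.random(SHAPE) < 0.1).astype(np.uint8), np.eye(4), lesion_class="wmh")
            for _ in range(9)
        ]
        out = pd_map(masks, "all")
        total = sum(m.voxel_count for m in masks)
        assert out.counts.sum() == total
        assert np.abs(out.data * out.n - out.counts).max() < 1e-9

    def test_adding_empty_mask_monotonicity(self, rng):
        masks = [
            LesionMask((rng.random(SHAPE) < 0.2).astype(np.uint8), np.eye(4), lesion_class="wmh")
            for _ in range(5)
        ]
        base_all = pd_map(masks, "all")
        more_all = pd_map(masks + [_mask()], "all")
        assert np.all(more_all.data <= base_all.data)
        base_aff = pd_map(masks, "affected_only")
        more_aff = pd_map(masks + [_mask()], "affected_only")
        assert np.array_equal(base_aff.data, more_aff.data)

    def test_subject_order_irrelevant(self, rng):
        masks = [
            LesionMask((rng.random(SHAPE) < 0.3).astype(np.uint8), np.eye(4), lesion_class="wmh")
            for _ in range(6)
        ]
        a = pd_map(masks, "all")
        b = pd_map(masks[::-1], "all")
        assert a.data.tobytes() == b.data.tobytes()

    def test_mirrored_cohort_is_mirror_symmetric(self, rng):
        masks = []
        for _ in range(6):
            half = (rng.random(SHAPE) < 0.2)
            sym = half | half[::-1, :, :]
            masks.append(LesionMask(sym.astype(np.uint8), np.eye(4), lesion_class="wmh"))
        out = pd_map(masks, "all")
        assert np.abs(out.data - out.data[::-1, :, :]).max() < 2.0 / out.n

    def test_grid_mismatch_rejected(self):
        other = LesionMask(np.zeros((8, 8, 8), np.uint8), np.eye(4), lesion_class="wmh")
        with pytest.raises(GridMismatchError):
            pd_map([_mask(), other], "all")


class TestSampleROI:
    def _pd(self, data):
        data = np.asarray(data, float)
        return PDMap(data=data, counts=(data * 10).astype(int), n=10,
                     lesion_class="wmh", affine=np.eye(4))

    def test_uniform_map(self):
        pdm = self._pd(np.full(SHAPE, 0.3))
        roi = RegionROI("r", (4, 4, 4))
        assert sample_roi(pdm, roi, "mean") == pytest.approx(0.3)
        assert sample_roi(pdm, roi, "max") == pytest.approx(0.3)

    def test_hand_worked_mixed_cube(self):
        data = np.zeros(SHAPE)
        data[2, 2:4, 2:4] = 0.2  # 4 voxels at 0.2, the other 4 at 0
        pdm = self._pd(data)
        roi = RegionROI("r", (2, 2, 2))
        assert sample_roi(pdm, roi, "mean") == pytest.approx(0.1)
        assert sample_roi(pdm, roi, "max") == pytest.approx(0.2)

    def test_empty_map_samples_zero(self):
        pdm = self._pd(np.zeros(SHAPE))
        assert sample_roi(pdm, RegionROI("r", (0, 0, 0))) == 0.0

    def test_out_of_grid_rejected(self):
        pdm = self._pd(np.zeros(SHAPE))
        with pytest.raises(GeometryError):
            sample_roi(pdm, RegionROI("r", (15, 15, 15)))


class TestRegionTable:
    def test_single_class_single_column(self, atlas):
        masks = [_mask_on(atlas, [(30, 30, 30)]) for _ in range(3)]
        table = region_table({"infarct": pd_map(masks, "all")}, default_roiset(atlas))
        assert list(table.columns) == ["region", "laterality", "infarct"]

    def test_tract_planted_lesions_rank_highest(self, atlas):
        """Masks covering the tract ROI only -> tract PD exceeds all others."""
        rois = default_roiset(atlas)
        data = np.zeros(atlas.shape, np.uint8)
        from svdmap.synthetic import REGION_LABELS

        data[np.isin(atlas.data, (REGION_LABELS["tract_left"], REGION_LABELS["tract_right"]))] = 1
        masks = [LesionMask(data, atlas.affine, lesion_class="infarct") for _ in range(4)]
        table = region_table({"infarct": pd_map(masks, "all")}, rois)
        tract_vals = table[table.region == "tract"]["infarct"]
        other_vals = table[table.region != "tract"]["infarct"]
        assert tract_vals.min() > other_vals.max()

    def test_all_empty_masks_zero_table(self, atlas):
        masks = [_mask_on(atlas, []) for _ in range(3)]
        table = region_table({"infarct": pd_map(masks, "all")}, default_roiset(atlas))
        assert (table["infarct"] == 0).all()

    def test_rounding_matches_half_up_three_decimals(self, atlas):
        masks = [_mask_on(atlas, [(30, 30, 30)])] + [_mask_on(atlas, []) for _ in range(187)]
        table = region_table({"infarct": pd_map(masks, "all")}, default_roiset(atlas))
        r = rounded_table(table)
        assert set(np.unique(r["infarct"])) <= {0.0, 0.001, 0.005}

    def test_missing_class_map_listed(self, atlas):
        with pytest.raises(InputError):
            region_table({}, default_roiset(atlas))


def _mask_on(atlas, voxels, cls="infarct"):
    data = np.zeros(atlas.shape, np.uint8)
    for v in voxels:
        data[v] = 1
    return LesionMask(data, atlas.affine, lesion_class=cls)


class TestSubtraction:
    def _pd_from(self, data, cls="wmh", n=10):
        data = np.asarray(data, float)
        return PDMap(data=data, counts=(data * n).round().astype(int), n=n,
                     lesion_class=cls, affine=np.eye(4))

    def test_identical_maps(self):
        a = self._pd_from(np.full(SHAPE, 0.4))
        diff, overlap = subtract_maps(a, a)
        assert np.all(diff == 0)
        assert overlap == 1.0

    def test_disjoint_supports(self):
        x = np.zeros(SHAPE); x[0, 0, 0] = 0.5
        y = np.zeros(SHAPE); y[5, 5, 5] = 0.5
        _, overlap = subtract_maps(self._pd_from(x), self._pd_from(y))
        assert overlap == 0.0

    def test_nested_supports(self):
        b = np.zeros(SHAPE)
        b[2:6, 2:6, 2:6] = 0.6
        a = np.zeros(SHAPE)
        a[3:5, 3:5, 3:5] = 0.6  # a support inside b, equal on the overlap
        diff, overlap = subtract_maps(self._pd_from(a), self._pd_from(b))
        assert diff.min() == pytest.approx(-0.6)
        assert diff.max() == 0.0
        assert overlap == pytest.approx(8 / 64)

    def test_grid_mismatch(self):
        a = self._pd_from(np.zeros(SHAPE))
        b = PDMap(np.zeros((8, 8, 8)), np.zeros((8, 8, 8), int), 5, "wmh", np.eye(4))
        with pytest.raises(GridMismatchError):
            subtract_maps(a, b)


def test_round_half_up_behaviour():
    assert round_half_up(0.0005, 3) == 0.001
    assert round_half_up(1 / 188, 3) == 0.005
    assert round_half_up(0.1234, 3) == 0.123
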