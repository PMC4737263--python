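"""Tests of colour fusion, minimum-variance quantization and lacune detection."""

import numpy as np
import pytest

from svdmap.image import GridMismatchError, InputError, LesionMask, VolumeImage
from svdmap.segmentation import (
    ColorVolume,
    RescaleError,
    detect_lacunes,
    extract_lesion_class,
    fuse_channels,
    minimum_variance_quantize,
    sphericity,
    _surface_area_mm2,
)
from svdmap.synthetic import LesionSpec, TemplateSpec, make_template, equivalent_diameter_mm
from tests._oracles import brute_force_quantize


def _vol(data, name=""):
    return VolumeImage(np.asarray(data, dtype=np.float32), np.eye(4), name=name)


def _colors_from_points(points, counts):
    """Pack a list of colours (with multiplicities) into a 1-voxel-deep volume."""
    rows = np.repeat(np.asarray(points, dtype=np.uint8), counts, axis=0)
    n = len(rows)
    colors = rows.reshape(n, 1, 1, 3)
    mask = np.ones((n, 1, 1), dtype=bool)
    return ColorVolume(colors=colors, brain_mask=mask, affine=np.eye(4))


class TestFuseChannels:
    def test_identical_sequences_give_equal_channels(self, rng):
        data = rng.uniform(0, 100, size=(8, 8, 8))
        mask = np.ones((8, 8, 8), dtype=bool)
        out = fuse_channels(_vol(data, "a"), _vol(data, "b"), mask)
        assert np.array_equal(out.colors[..., 0], out.colors[..., 1])
        assert np.all(out.colors[..., 2] == 0)

    def test_extreme_voxel_maps_to_pure_red(self, rng):
        a = rng.uniform(10, 20, size=(6, 6, 6))
        b = rng.uniform(10, 20, size=(6, 6, 6))
        a[3, 3, 3] = 1000.0  # far above the clip ceiling
        b[3, 3, 3] = -1000.0
        out = fuse_channels(_vol(a, "a"), _vol(b, "b"), np.ones((6, 6, 6), bool))
        assert tuple(out.colors[3, 3, 3]) == (255, 0, 0)

    def test_constant_sequence_raises_naming_it(self):
        a = _vol(np.zeros((6, 6, 6)), name="flat_flair")
        b = _vol(np.arange(216, dtype=float).reshape(6, 6, 6), name="t1")
        with pytest.raises(RescaleError, match="flat_flair"):
            fuse_channels(a, b, np.ones((6, 6, 6), bool))

    def test_mismatched_grids_rejected(self):
        a = _vol(np.zeros((6, 6, 6)))
        b = _vol(np.zeros((7, 6, 6)))
        with pytest.raises(GridMismatchError):
            fuse_channels(a, b, np.ones((6, 6, 6), bool))

    def test_noiseless_phantom_has_one_colour_per_tissue_pair(self):
        spec = TemplateSpec(grid_shape=(40, 40, 40), noise_sd=0.0)
        template, atlas = make_template(spec)
        # render the FLAIR counterpart of the same noiseless label field
        from svdmap.synthetic import render_sequence

        flair = VolumeImage(render_sequence(atlas.data, "flair", spec), template.affine)
        brain = atlas.data > 0
        out = fuse_channels(flair, template, brain)
        distinct = np.unique(out.masked_colors, axis=0)
        tissue_pairs = {
            (spec.tissue_means["flair"][t], spec.tissue_means["t1"][t])
            for t in ("csf", "grey", "white")
        }
        assert len(distinct) == len(tissue_pairs)


class TestQuantizer:
    def test_single_cluster_is_global_mean(self, rng):
        points = rng.integers(0, 255, size=(20, 3))
        counts = rng.integers(1, 5, size=20)
        colors = _colors_from_points(points, counts)
        model, labels = minimum_variance_quantize(colors, 1)
        flat = colors.masked_colors.astype(float)
        assert np.allclose(model.centroids[0], flat.mean(axis=0))
        assert model.objective == pytest.approx(((flat - flat.mean(0)) ** 2).sum())
        assert set(np.unique(labels)) == {1}

    def test_two_well_separated_groups_match_exhaustive_optimum(self):
        pts = np.array(
            [[10, 10, 0], [12, 9, 0], [11, 11, 0], [9, 12, 0], [10, 9, 0],
             [200, 200, 0], [202, 199, 0], [201, 201, 0]],
            dtype=float,
        )
        colors = _colors_from_points(pts.astype(np.uint8), np.ones(len(pts), int))
        model, labels = minimum_variance_quantize(colors, 2)
        oracle = brute_force_quantize(pts, np.ones(len(pts)), 2)
        assert model.objective == pytest.approx(oracle, rel=1e-9)
        # the partition itself separates the two groups
        flat_labels = labels[colors.brain_mask]
        assert len(set(flat_labels[:5])) == 1 and len(set(flat_labels[5:])) == 1
        assert flat_labels[0] != flat_labels[-1]

    def test_uniform_colour_has_zero_objective(self):
        colors = _colors_from_points([[7, 7, 0]], [50])
        model, _ = minimum_variance_quantize(colors, 1)
        assert model.objective == 0.0

    def test_k_reduced_when_fewer_distinct_colours(self, caplog):
        colors = _colors_from_points([[1, 2, 0], [200, 100, 0]], [5, 5])
        with caplog.at_level("WARNING"):
            model, _ = minimum_variance_quantize(colors, 4)
        assert model.k == 2

    def test_near_optimal_on_random_small_instances(self, rng):
        """Objective within 1.0001x of the exhaustive optimum (spot check)."""
        for _ in range(10):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 4))
            pts = rng.integers(0, 256, size=(n, 3)).astype(float)
            pts = np.unique(pts, axis=0)
            w = rng.integers(1, 4, size=len(pts))
            colors = _colors_from_points(pts.astype(np.uint8), w)
            model, _ = minimum_variance_quantize(colors, min(k, len(pts)))
            oracle = brute_force_quantize(pts, w.astype(float), min(k, len(pts)))
            assert model.objective <= oracle * 1.0001 + 1e-9


class TestExtractLesionClass:
    def test_percentile_100_selects_exactly_max_red_cluster(self, rng):
        labels = rng.integers(1, 4, size=(6, 6, 6))
        centroids = np.array([[10.0, 0, 0], [100.0, 0, 0], [250.0, 0, 0]])
        from svdmap.segmentation import QuantizationModel

        model = QuantizationModel(k=3, centroids=centroids, objective=0.0)
        mask = extract_lesion_class(labels, model)
        assert np.array_equal(mask.data.astype(bool), labels == 3)
        assert mask.lesion_class == "wmh"

    def test_infarct_voxels_removed_from_wmh(self, rng):
        labels = np.full((4, 4, 4), 2)
        from svdmap.segmentation import QuantizationModel

        model = QuantizationModel(k=2, centroids=np.array([[0.0, 0, 0], [255.0, 0, 0]]), objective=0.0)
        infarct = np.zeros((4, 4, 4), np.uint8)
        infarct[1, 1, 1] = 1
        mask = extract_lesion_class(labels, model, infarct_mask=infarct)
        assert mask.data[1, 1, 1] == 0
        assert mask.voxel_count == 63

    def test_invariant_under_cluster_relabelling(self, rng):
        """Permuting cluster ids (with centroids) leaves the WMH mask unchanged."""
        labels = rng.integers(1, 5, size=(6, 6, 6))
        centroids = rng.uniform(0, 255, size=(4, 3))
        from svdmap.segmentation import QuantizationModel

        perm = rng.permutation(4)
        relabeled = np.zeros_like(labels)
        for old, new in enumerate(perm):
            relabeled[labels == old + 1] = new + 1
        m1 = extract_lesion_class(labels, QuantizationModel(4, centroids, 0.0))
        m2 = extract_lesion_class(
            relabeled, QuantizationModel(4, centroids[np.argsort(perm)], 0.0)
        )
        assert np.array_equal(m1.data, m2.data)


def _cavity_phantom():
    """White 'brain' ball with CSF-signal cavities of known diameters."""
    shape = (64, 64, 64)
    x, y, z = np.ogrid[:64, :64, :64]
    brain = ((x - 32) ** 2 + (y - 32) ** 2 + (z - 32) ** 2) <= 28**2
    flair = np.where(brain, 100.0, 0.0)
    vent = np.zeros(shape, bool)
    vent[28:36, 28:36, 28:36] = True
    flair[vent] = 40.0

    def cavity(center, diameter):
        cx, cy, cz = center
        r = diameter / 2.0
        ball = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= r**2
        flair[ball] = 40.0
        return ball

    cavity((16, 16, 32), 2.0)
    cavity((48, 16, 32), 4.0)
    cavity((16, 48, 32), 8.0)
    cavity((40, 44, 20), 20.0)
    cavity((32, 36, 38), 5.0)  # contiguous with the ventricle block
    vol = VolumeImage(flair.astype(np.float32), np.eye(4), name="phantom_flair")
    return vol, brain, vent


class TestLacuneDetector:
    def test_diameter_band_and_ventricle_exclusion(self):
        """Cavities of 2/4/8/20 mm plus one ventricle-contiguous: keep 4 and 8."""
        vol, brain, vent = _cavity_phantom()
        mask, comps = detect_lacunes(vol, brain, vent, csf_mean=40.0, grey_mean=100.0)
        assert len(comps) == 2
        diameters = sorted(c.equivalent_diameter_mm for c in comps)
        assert diameters[0] == pytest.approx(4.0, abs=1.0)
        assert diameters[1] == pytest.approx(8.0, abs=1.0)
        assert comps[0].volume_ml >= comps[1].volume_ml  # sorted by volume desc

    def test_small_cavity_alone_yields_nothing(self):
        shape = (32, 32, 32)
        x, y, z = np.ogrid[:32, :32, :32]
        brain = ((x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2) <= 14**2
        flair = np.where(brain, 100.0, 0.0)
        flair[((x - 10) ** 2 + (y - 10) ** 2 + (z - 16) ** 2) <= 1.0] = 40.0  # 2 mm
        vol = VolumeImage(flair.astype(np.float32), np.eye(4))
        _, comps = detect_lacunes(vol, brain, np.zeros(shape), csf_mean=40.0, grey_mean=100.0)
        assert comps == []

    def test_min_diameter_monotonicity(self):
        vol, brain, vent = _cavity_phantom()
        counts = []
        for lo in (3.0, 5.0, 9.0, 16.0):
            _, comps = detect_lacunes(
                vol, brain, vent, min_diam_mm=lo, csf_mean=40.0, grey_mean=100.0
            )
            counts.append(len(comps))
        assert counts == sorted(counts, reverse=True)

    def test_equivalent_diameter_exact_formula(self):
        vol, brain, vent = _cavity_phantom()
        _, comps = detect_lacunes(vol, brain, vent, csf_mean=40.0, grey_mean=100.0)
        for c in comps:
            v = len(c.voxels)
            assert c.equivalent_diameter_mm == (6.0 * v / np.pi) ** (1.0 / 3.0)
            assert equivalent_diameter_mm(v) == c.equivalent_diameter_mm

    def test_empty_brain_mask_rejected(self):
        vol, _, vent = _cavity_phantom()
        with pytest.raises(InputError):
            detect_lacunes(vol, np.zeros(vol.shape, bool), vent)


def test_sphericity_of_digital_sphere_in_calibrated_range():
    ball = np.zeros((20, 20, 20), bool)
    x, y, z = np.ogrid[:20, :20, :20]
    ball[((x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2) <= 36] = True
    area = _surface_area_mm2(ball, 1.0)
    s = sphericity(int(ball.sum()), area)
    assert 0.4 <= s <= 1.0


def test_segmentation_recovers_truth_wmh(subject, template_spec):
    """Dice against truth on a default synthetic subject is high."""
    colors = fuse_channels(subject.seq_flair, subject.seq_t1, subject.brain_mask)
    model, labels = minimum_variance_quantize(colors, 5)
    wmh = extract_lesion_class(
        labels, model, infarct_mask=subject.truth_masks["infarct"], affine=subject.seq_flair.affine
    )
    truth = subject.truth_masks["wmh"].data.astype(bool)
    pred = wmh.data.astype(bool)
    dice = 2 * (truth & pred).sum() / (truth.sum() + pred.sum())
    assert dice >= 0.8
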