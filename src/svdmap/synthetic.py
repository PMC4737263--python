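"""Synthetic cohort generator for small-vessel-disease lesion mapping.

Emulates the data the analysis pipeline assumes: a 1-mm isotropic
population template with a subcortical atlas, and per-subject pairs of
co-registered FLAIR-like / T1-like volumes carrying ground-truth masks for
three lesion classes:

* one recent small subcortical infarct per subject (single connected blob,
  axial diameter capped at 2 cm, centred on a synthetic deep "tract" curve
  standing in for the corticospinal tract / internal capsule);
* multifocal white matter hyperintensities (WMH), weighted toward the
  periventricular white matter, hyperintense on the FLAIR-like sequence;
* lacunes in a configurable fraction of subjects (default 46.5%),
  CSF-like signal on both sequences, 3-15 mm equivalent diameter.

Each subject is misaligned by a known small affine (the ``true_affine``)
so that registration can be validated against ground truth, and carries a
4-vector of volumetric features (intracranial, brain, ventricular and WMH
volumes in ml) used for representative-subject selection.

Grids are scaled-down stand-ins for a real 1-mm brain: the default 64^3
field of view holds a brain of roughly 80 ml rather than 1200 ml, but the
relative geometry (ventricles, deep grey nuclei, tract, periventricular
rim) is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import (
    AffineTransform,
    ConfigurationError,
    GenerationError,
    LesionMask,
    VolumeImage,
)

SEQUENCES = ("flair", "t1")

DEFAULT_TISSUE_MEANS: dict[str, dict[str, float]] = {
    # FLAIR: CSF suppressed, grey > white
    "flair": {"csf": 40.0, "grey": 120.0, "white": 100.0},
    # T1: white > grey > CSF
    "t1": {"csf": 40.0, "grey": 100.0, "white": 140.0},
}

REGION_LABELS: dict[str, int] = {
    "ventricle_left": 1,
    "ventricle_right": 2,
    "tract_left": 3,
    "tract_right": 4,
    "caudate_left": 5,
    "caudate_right": 6,
    "lentiform_left": 7,
    "lentiform_right": 8,
    "thalamus_left": 9,
    "thalamus_right": 10,
    "periventricular_left": 11,
    "periventricular_right": 12,
    "cortex": 13,
    "white_matter": 14,
}

LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}

TISSUE_OF_REGION: dict[str, str] = {
    "ventricle_left": "csf",
    "ventricle_right": "csf",
    "tract_left": "white",
    "tract_right": "white",
    "caudate_left": "grey",
    "caudate_right": "grey",
    "lentiform_left": "grey",
    "lentiform_right": "grey",
    "thalamus_left": "grey",
    "thalamus_right": "grey",
    "periventricular_left": "white",
    "periventricular_right": "white",
    "cortex": "grey",
    "white_matter": "white",
}

VENTRICLE_LABELS = (REGION_LABELS["ventricle_left"], REGION_LABELS["ventricle_right"])

#: fraction of the x-extent used as the tract tube radius
TRACT_RADIUS_FRACTION = 0.030

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of the synthetic template grid and tissue contrast."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tissue_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_TISSUE_MEANS.items()}
    )
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 32 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 axes all >= 32, got {self.grid_shape}")
        if not self.voxel_size_mm > 0:
            raise ConfigurationError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for seq in SEQUENCES:
            if seq not in self.tissue_means:
                raise ConfigurationError(f"tissue_means missing sequence {seq!r}")
            means = [self.tissue_means[seq][t] for t in ("csf", "grey", "white")]
            if len(set(means)) != 3:
                raise ConfigurationError(
                    f"tissue_means for {seq!r} must be distinct (no contrast): {means}"
                )


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of synthetic lesion planting.

    Diameters are equivalent sphere diameters in mm. The infarct cap
    mirrors the <2 cm maximum-axial-diameter definition of a recent small
    subcortical infarct; the lacune prevalence default emulates a cohort
    in which 87/187 subjects carry at least one lacune.
    """

    infarct_diameter_range_mm: tuple[float, float] = (6.0, 14.0)
    infarct_max_axial_diameter_mm: float = 20.0
    wmh_count_mean: float = 8.0
    wmh_diameter_range_mm: tuple[float, float] = (3.0, 9.0)
    wmh_periventricular_weight: float = 0.7
    lacune_prevalence: float = 0.465
    lacune_diameter_range_mm: tuple[float, float] = (3.0, 15.0)
    lacune_diameter_sample_mm: tuple[float, float] = (4.0, 10.0)
    lacune_count_mean: float = 1.3
    flair_lesion_mean: float = 200.0
    t1_lesion_mean: float = 90.0

    def validate(self) -> None:
        if not 0.0 <= self.lacune_prevalence <= 1.0:
            raise ConfigurationError(
                f"lacune_prevalence must be in [0, 1], got {self.lacune_prevalence}"
            )
        if self.lacune_diameter_range_mm[0] < 3.0:
            raise ConfigurationError(
                "lacune_diameter_range_mm low bound must be >= 3 (lacune definition), "
                f"got {self.lacune_diameter_range_mm[0]}"
            )
        if self.infarct_max_axial_diameter_mm > 20.0:
            raise ConfigurationError(
                "infarct_max_axial_diameter_mm must be <= 20 (recent small subcortical "
                f"infarct definition), got {self.infarct_max_axial_diameter_mm}"
            )
        if self.infarct_diameter_range_mm[1] > self.infarct_max_axial_diameter_mm:
            raise ConfigurationError(
                "infarct_diameter_range_mm upper bound exceeds infarct_max_axial_diameter_mm"
            )
        if not 0.0 <= self.wmh_periventricular_weight <= 1.0:
            raise ConfigurationError(
                f"wmh_periventricular_weight must be in [0, 1], got {self.wmh_periventricular_weight}"
            )


@dataclass
class SubjectRecord:
    """One synthetic subject: sequences, truth masks, true affine, volumetrics.

    ``true_affine`` maps template-frame world coordinates to the
    corresponding subject-frame location (the pull-back map a successful
    registration of this subject to the template should recover).
    ``volumetrics`` is (intracranial, brain, ventricular, WMH) in ml.
    """

    subject_id: str
    seq_flair: VolumeImage
    seq_t1: VolumeImage
    truth_masks: dict[str, LesionMask]
    true_affine: AffineTransform
    volumetrics: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------


def _centered_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """1-mm-style RAS+ affine with the world origin at the grid centre."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return affine


def _ellipsoid(shape, center_frac, semi_frac) -> np.ndarray:
    n = np.asarray(shape, dtype=float)
    c = (n - 1) / 2.0 + np.asarray(center_frac) * n
    s = np.asarray(semi_frac) * n
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, s))
    return q <= 1.0


def tract_curve_points(
    grid_shape: tuple[int, int, int], side: str, n_samples: int = 200
) -> tuple[np.ndarray, float]:
    """Sampled centreline of the synthetic deep motor tract, in voxel coords.

    Returns the (n_samples, 3) polyline and the tube radius in voxels.
    The tract runs inferior-to-superior between the deep grey nuclei,
    lateral to the ventricles, one tube per hemisphere.
    """
    n = np.asarray(grid_shape, dtype=float)
    c = (n - 1) / 2.0
    sign = -1.0 if side == "left" else 1.0
    t = np.linspace(0.0, 1.0, n_samples)
    x = c[0] + sign * (0.165 + 0.030 * t) * n[0]
    y = c[1] + (-0.050 + 0.060 * t) * n[1]
    z = c[2] + (-0.180 + 0.360 * t) * n[2]
    return np.stack([x, y, z], axis=1), TRACT_RADIUS_FRACTION * n[0]


def _rasterize_tube(shape, points: np.ndarray, radius: float) -> np.ndarray:
    """Voxels whose centre lies within ``radius`` of the sampled polyline."""
    lo = np.maximum(np.floor(points.min(axis=0) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(points.max(axis=0) + radius + 2).astype(int), shape)
    box = np.zeros(shape, dtype=bool)
    gi, gj, gk = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    vox = np.stack([gi, gj, gk], axis=-1).astype(float)
    min_d2 = np.full(vox.shape[:-1], np.inf)
    for p in points:
        d2 = ((vox - p) ** 2).sum(axis=-1)
        np.minimum(min_d2, d2, out=min_d2)
    box[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = min_d2 <= radius**2
    return box


def make_template(spec: TemplateSpec) -> tuple[VolumeImage, VolumeImage]:
    """Build the synthetic T1-like template volume and its region atlas.

    The atlas is an integer label volume (0 = background) with left/right
    ventricles, deep tracts, caudate / lentiform / thalamic nuclei,
    periventricular rims, a cortical shell and remaining deep white
    matter. Deterministic given ``spec.seed``.
    """
    spec.validate()
    shape = tuple(int(v) for v in spec.grid_shape)
    affine = _centered_affine(shape, spec.voxel_size_mm)

    brain = _ellipsoid(shape, (0, 0, 0), (0.42, 0.45, 0.40))
    inner = _ellipsoid(shape, (0, 0, 0), (0.42 * 0.82, 0.45 * 0.82, 0.40 * 0.82))

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain & ~inner] = REGION_LABELS["cortex"]
    labels[inner] = REGION_LABELS["white_matter"]

    def carve(name: str, mask: np.ndarray) -> None:
        free = mask & inner & (labels == REGION_LABELS["white_matter"])
        labels[free] = REGION_LABELS[name]

    for side, sign in (("left", -1.0), ("right", 1.0)):
        vent = _ellipsoid(shape, (sign * 0.085, 0.02, 0.05), (0.033, 0.150, 0.065))
        labels[vent & inner] = REGION_LABELS[f"ventricle_{side}"]
    for side in ("left", "right"):
        pts, radius = tract_curve_points(shape, side)
        tube = _rasterize_tube(shape, pts, radius)
        carve(f"tract_{side}", tube)
    for side, sign in (("left", -1.0), ("right", 1.0)):
        carve(f"caudate_{side}", _ellipsoid(shape, (sign * 0.125, 0.13, 0.07), (0.040, 0.070, 0.050)))
        carve(f"lentiform_{side}", _ellipsoid(shape, (sign * 0.255, 0.03, 0.01), (0.050, 0.085, 0.060)))
        carve(f"thalamus_{side}", _ellipsoid(shape, (sign * 0.085, -0.135, 0.01), (0.055, 0.070, 0.050)))

    vent_mask = np.isin(labels, VENTRICLE_LABELS)
    pv_dist = ndimage.distance_transform_edt(~vent_mask)
    pv_radius = 3.0 * shape[0] / 64.0
    pv = (pv_dist <= pv_radius) & ~vent_mask
    half = np.arange(shape[0]) < (shape[0] - 1) / 2.0
    for side, in_half in (("left", half), ("right", ~half)):
        carve(f"periventricular_{side}", pv & in_half[:, None, None])

    rng = np.random.default_rng(spec.seed)
    template_data = render_sequence(labels, "t1", spec, rng=rng)
    template = VolumeImage(template_data, affine, name="template_t1")
    atlas = VolumeImage(labels, affine, name="atlas")
    return template, atlas


def render_sequence(
    labels: np.ndarray,
    sequence: str,
    spec: TemplateSpec,
    lesion_masks: dict[str, np.ndarray] | None = None,
    lesion_spec: LesionSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render an intensity volume from region labels and optional lesions.

    Lesions overwrite tissue intensity with a class mean (no
    partial-volume modelling); Gaussian noise of ``spec.noise_sd`` is
    added inside the head only.
    """
    means = spec.tissue_means[sequence]
    data = np.zeros(labels.shape, dtype=np.float32)
    for label, name in LABEL_NAMES.items():
        data[labels == label] = means[TISSUE_OF_REGION[name]]
    if lesion_masks:
        assert lesion_spec is not None
        bright = lesion_spec.flair_lesion_mean if sequence == "flair" else lesion_spec.t1_lesion_mean
        for cls, mask in lesion_masks.items():
            value = means["csf"] if cls == "lacune" else bright
            data[mask.astype(bool)] = value
    if rng is not None and spec.noise_sd > 0:
        head = labels > 0
        data[head] += rng.normal(0.0, spec.noise_sd, size=int(head.sum())).astype(np.float32)
    return data


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------


def _sphere_at(shape, center: np.ndarray, diameter_vox: float) -> np.ndarray:
    r = diameter_vox / 2.0
    lo = np.maximum(np.floor(center - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + r + 2).astype(int), shape)
    out = np.zeros(shape, dtype=bool)
    gi, gj, gk = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = (gi - center[0]) ** 2 + (gj - center[1]) ** 2 + (gk - center[2]) ** 2
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= r**2
    return out


def _random_misalignment(
    rng: np.random.Generator,
    center_world: np.ndarray,
    max_rotation_deg: float,
    max_translation_mm: float,
    scale_range: tuple[float, float],
) -> AffineTransform:
    """Small random affine about the grid-centre world point."""
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, size=3))
    trans = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    scales = rng.uniform(scale_range[0], scale_range[1], size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    linear = rot_z @ rot_y @ rot_x @ np.diag(scales)
    matrix = np.eye(4)
    matrix[:3, :3] = linear
    matrix[:3, 3] = center_world - linear @ center_world + trans
    return AffineTransform(matrix, dof=12)


def _resample(data: np.ndarray, world_map: np.ndarray, affine: np.ndarray, order: int) -> np.ndarray:
    """Pull data back through a world-to-world map onto the same grid."""
    inv_affine = np.linalg.inv(affine)
    vox_map = inv_affine @ world_map @ affine
    return ndimage.affine_transform(
        data.astype(np.float32) if order > 0 else data,
        vox_map[:3, :3],
        offset=vox_map[:3, 3],
        order=order,
        mode="constant",
        cval=0.0,
        output=np.float32 if order > 0 else data.dtype,
    )


def _plant_lesions(
    labels: np.ndarray,
    spec: LesionSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Place infarct, lacune and WMH masks in template space.

    Classes are kept disjoint: the infarct is planted first (on the
    tract), then lacunes (deep white matter clear of ventricles and the
    brain edge), then WMH (everything else is excluded from them).
    """
    shape = labels.shape
    brain = labels > 0
    vent = np.isin(labels, VENTRICLE_LABELS)
    dist_to_vent = ndimage.distance_transform_edt(~vent)
    dist_to_edge = ndimage.distance_transform_edt(brain)

    tract = np.isin(labels, (REGION_LABELS["tract_left"], REGION_LABELS["tract_right"]))
    tract_idx = np.argwhere(tract)

    def sample_sphere(candidates: np.ndarray, diameter: float, clearance: float, tries: int = 100):
        r = diameter / 2.0
        for _ in range(tries):
            center = candidates[rng.integers(len(candidates))].astype(float)
            center += rng.uniform(-1.0, 1.0, size=3)
            ci = tuple(np.clip(np.round(center).astype(int), 0, np.asarray(shape) - 1))
            if dist_to_vent[ci] < r + clearance or dist_to_edge[ci] < r + clearance:
                continue
            return _sphere_at(shape, center, diameter)
        raise GenerationError(
            f"could not place a {diameter:.1f} mm lesion after {tries} attempts"
        )

    masks: dict[str, np.ndarray] = {}

    d_inf = rng.uniform(*spec.infarct_diameter_range_mm)
    masks["infarct"] = sample_sphere(tract_idx, d_inf, clearance=1.0) & brain & ~vent

    lacune = np.zeros(shape, dtype=bool)
    if rng.random() < spec.lacune_prevalence:
        deep_white = labels == REGION_LABELS["white_matter"]
        candidates = np.argwhere(deep_white & ~masks["infarct"])
        n_lac = 1 + rng.poisson(max(spec.lacune_count_mean - 1.0, 0.0))
        lo = max(spec.lacune_diameter_sample_mm[0], spec.lacune_diameter_range_mm[0])
        hi = min(spec.lacune_diameter_sample_mm[1], spec.lacune_diameter_range_mm[1])
        for _ in range(n_lac):
            d = rng.uniform(lo, hi)
            sphere = sample_sphere(candidates, d, clearance=2.5)
            lacune |= sphere & ~masks["infarct"]
    masks["lacune"] = lacune

    pv = np.isin(
        labels,
        (REGION_LABELS["periventricular_left"], REGION_LABELS["periventricular_right"]),
    )
    white_any = np.isin(
        labels,
        (
            REGION_LABELS["white_matter"],
            REGION_LABELS["periventricular_left"],
            REGION_LABELS["periventricular_right"],
        ),
    )
    pv_idx = np.argwhere(pv)
    white_idx = np.argwhere(white_any)
    wmh = np.zeros(shape, dtype=bool)
    n_wmh = 1 + rng.poisson(max(spec.wmh_count_mean - 1.0, 0.0))
    for _ in range(n_wmh):
        d = rng.uniform(*spec.wmh_diameter_range_mm)
        pool = pv_idx if rng.random() < spec.wmh_periventricular_weight else white_idx
        center = pool[rng.integers(len(pool))].astype(float) + rng.uniform(-1.0, 1.0, size=3)
        wmh |= _sphere_at(shape, center, d)
    wmh &= brain & ~vent & ~masks["infarct"] & ~lacune
    if not wmh.any():  # pathological exclusion overlap; extremely unlikely
        raise GenerationError("WMH planting produced an empty mask")
    masks["wmh"] = wmh
    return masks


def make_subject(
    template: VolumeImage,
    atlas: VolumeImage,
    lesion_spec: LesionSpec,
    seed,
    template_spec: TemplateSpec | None = None,
    subject_id: str = "sub-000",
    misalign: bool = True,
    max_rotation_deg: float = 5.0,
    max_translation_mm: float = 5.0,
    scale_range: tuple[float, float] = (0.97, 1.03),
) -> SubjectRecord:
    """Generate one subject: plant lesions, misalign, render, measure.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``. If the
    template was built with non-default tissue contrast, pass the same
    ``template_spec`` here so subject intensities match.
    """
    if not template.same_grid(atlas):
        raise ConfigurationError("template and atlas must share one grid")
    lesion_spec.validate()
    if template_spec is None:
        template_spec = TemplateSpec(
            grid_shape=template.shape, voxel_size_mm=float(template.voxel_size_mm[0])
        )
    rng = np.random.default_rng(seed)
    labels = atlas.data.astype(np.int16)
    affine = template.affine
    center_world = template.world_coordinates((np.asarray(template.shape) - 1) / 2.0)[0]

    for attempt in range(5):
        lesions = _plant_lesions(labels, lesion_spec, rng)
        if misalign:
            true_affine = _random_misalignment(
                rng, center_world, max_rotation_deg, max_translation_mm, scale_range
            )
        else:
            true_affine = AffineTransform.identity(dof=12)
        # subject(v) = ideal(world -> template frame); the pull-back used in
        # generation is the inverse of the template->subject true_affine.
        gen_map = np.linalg.inv(true_affine.matrix)

        subj_labels = _resample(labels, gen_map, affine, order=0)
        subj_lesions = {
            cls: _resample(m.astype(np.uint8), gen_map, affine, order=0).astype(bool)
            for cls, m in lesions.items()
        }
        n_comp = ndimage.label(subj_lesions["infarct"], structure=_CONN26)[1]
        if n_comp == 1:
            break
    else:
        raise GenerationError(f"{subject_id}: infarct fragmented by resampling in 5 attempts")

    seqs = {}
    head = subj_labels > 0
    for seq in SEQUENCES:
        ideal = render_sequence(labels, seq, template_spec, lesions, lesion_spec, rng=None)
        data = _resample(ideal, gen_map, affine, order=1)
        if template_spec.noise_sd > 0:
            data[head] += rng.normal(0.0, template_spec.noise_sd, size=int(head.sum())).astype(
                np.float32
            )
        seqs[seq] = VolumeImage(data, affine, name=f"{subject_id}_{seq}")

    truth_masks = {
        cls: LesionMask(m.astype(np.uint8), affine, lesion_class=cls, subject_id=subject_id)
        for cls, m in subj_lesions.items()
    }

    voxvol_ml = template.voxel_volume_mm3 / 1000.0
    vent_mask = np.isin(subj_labels, VENTRICLE_LABELS)
    icv = float(head.sum()) * voxvol_ml
    ventricular = float(vent_mask.sum()) * voxvol_ml
    brain_vol = icv - ventricular
    wmh_vol = float(truth_masks["wmh"].voxel_count) * voxvol_ml
    volumetrics = np.array([icv, brain_vol, ventricular, wmh_vol])

    return SubjectRecord(
        subject_id=subject_id,
        seq_flair=seqs["flair"],
        seq_t1=seqs["t1"],
        truth_masks=truth_masks,
        true_affine=true_affine,
        volumetrics=volumetrics,
        brain_mask=head,
        ventricle_mask=vent_mask,
    )


def make_cohort(
    n: int,
    template: VolumeImage,
    atlas: VolumeImage,
    lesion_spec: LesionSpec,
    seed: int,
    template_spec: TemplateSpec | None = None,
    misalign: bool = True,
    **subject_kwargs,
) -> list[SubjectRecord]:
    """Generate ``n`` subjects with per-subject streams hashed from the seed.

    Each subject's RNG stream is derived from ``(seed, index)`` so a
    subject is reproducible independently of cohort size or order.
    """
    if n < 2:
        raise ConfigurationError(f"cohort size must be >= 2, got n={n}")
    cohort = []
    for i in range(n):
        record = make_subject(
            template,
            atlas,
            lesion_spec,
            seed=np.random.SeedSequence((int(seed), i)),
            template_spec=template_spec,
            subject_id=f"sub-{i + 1:03d}",
            misalign=misalign,
            **subject_kwargs,
        )
        cohort.append(record)
    prevalence = np.mean([not r.truth_masks["lacune"].is_empty() for r in cohort])
    if n >= 50 and abs(prevalence - lesion_spec.lacune_prevalence) > 0.15:
        warnings.warn(
            f"empirical lacune prevalence {prevalence:.3f} far from specified "
            f"{lesion_spec.lacune_prevalence:.3f}",
            stacklevel=2,
        )
    return cohort


def equivalent_diameter_mm(voxel_count: int, voxel_volume_mm3: float = 1.0) -> float:
    """Diameter of the sphere with the same volume as ``voxel_count`` voxels."""
    return float((6.0 * voxel_count * voxel_volume_mm3 / np.pi) ** (1.0 / 3.0))
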