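"""Multispectral lesion segmentation and lacune detection.

WMH segmentation follows the two-sequence colour-fusion approach: the
FLAIR-like sequence is mapped to the red channel and the T1-like sequence
to green (blue stays 0), and the resulting colour cloud is partitioned by
minimum-variance quantization — a deterministic K-cluster partition of
colour space minimising total within-cluster squared distance. The
cluster(s) with the most FLAIR-hyperintense (reddest) centroids form the
WMH class; any voxels inside a supplied acute-infarct mask are excluded
so the symptomatic lesion is not counted as WMH.

Lacunes are detected by thresholding the FLAIR image at CSF-like
intensity, taking 26-connected components, excluding components that
touch the ventricles or the brain-mask boundary, and keeping components
in a 3-15 mm equivalent-diameter band that are sufficiently spherical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import GridMismatchError, InputError, LesionMask, VolumeImage
from .synthetic import equivalent_diameter_mm

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class RescaleError(ValueError):
    """A sequence could not be intensity-rescaled (constant image)."""


@dataclass
class ColorVolume:
    """Per-voxel RGB triplets in [0, 255]^3, defined inside a brain mask."""

    colors: np.ndarray  # (nx, ny, nz, 3) uint8
    brain_mask: np.ndarray
    affine: np.ndarray

    @property
    def masked_colors(self) -> np.ndarray:
        return self.colors[self.brain_mask.astype(bool)]


@dataclass
class QuantizationModel:
    """Result of minimum-variance quantization of a colour cloud."""

    k: int
    centroids: np.ndarray  # (k, 3)
    objective: float  # total within-cluster squared distance


@dataclass
class LacuneComponent:
    voxels: np.ndarray  # (n, 3) voxel indices
    volume_ml: float
    equivalent_diameter_mm: float
    sphericity: float
    centroid: tuple[float, float, float]


def fuse_channels(
    seq_a: VolumeImage,
    seq_b: VolumeImage,
    brain_mask: np.ndarray,
    clip_percentiles: tuple[float, float] = (0.5, 99.9),
) -> ColorVolume:
    """Fuse two co-registered sequences into RGB: a -> red, b -> green, blue 0.

    Each sequence is percentile-clipped and min-max rescaled to [0, 255]
    over the brain mask. The clip is deliberately wide (0.5/99.9) so that
    sparse hyperintense lesions, often well under 1% of brain voxels, are
    not flattened into the grey-matter range. Deterministic.
    """
    seq_a.require_same_grid(seq_b, "sequences")
    brain_mask = np.asarray(brain_mask).astype(bool)
    if brain_mask.shape != seq_a.shape:
        raise GridMismatchError("brain mask shape does not match the sequences")

    def rescale(seq: VolumeImage) -> np.ndarray:
        values = seq.data[brain_mask].astype(float)
        lo, hi = np.percentile(values, clip_percentiles)
        if hi <= lo:
            raise RescaleError(f"sequence {seq.name or '<unnamed>'} is constant; cannot rescale")
        scaled = np.clip((seq.data.astype(float) - lo) / (hi - lo), 0.0, 1.0) * 255.0
        return np.round(scaled).astype(np.uint8)

    colors = np.zeros(seq_a.shape + (3,), dtype=np.uint8)
    colors[..., 0] = rescale(seq_a)
    colors[..., 1] = rescale(seq_b)
    colors[~brain_mask] = 0
    return ColorVolume(colors=colors, brain_mask=brain_mask, affine=seq_a.affine)


# ---------------------------------------------------------------------------
# minimum-variance quantization
# ---------------------------------------------------------------------------


def _weighted_sse(points: np.ndarray, weights: np.ndarray, assign: np.ndarray, k: int):
    """Per-cluster weighted centroids and the total squared-distance objective."""
    centroids = np.zeros((k, points.shape[1]))
    sse = 0.0
    for j in range(k):
        sel = assign == j
        w = weights[sel]
        if w.sum() == 0:
            continue
        c = np.average(points[sel], axis=0, weights=w)
        centroids[j] = c
        sse += float((w[:, None] * (points[sel] - c) ** 2).sum())
    return centroids, sse


def _lloyd(points, weights, centroids, tol: float = 1e-9, max_iter: int = 100):
    """Deterministic weighted Lloyd refinement from the given centroids."""
    k = len(centroids)
    prev = np.inf
    assign = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)  # ties -> lowest cluster index
        # re-seed empty clusters at the worst-fit point (deterministic)
        for j in range(k):
            if not np.any(assign == j):
                worst = int(np.argmax(d2[np.arange(len(points)), assign]))
                assign[worst] = j
        centroids, sse = _weighted_sse(points, weights, assign, k)
        if prev - sse < tol:
            return centroids, assign, sse
        prev = sse
    return centroids, assign, prev


def _divisive_init(points, weights, k: int) -> np.ndarray:
    """Split the largest-variance cluster along its principal colour axis."""
    assign = np.zeros(len(points), dtype=int)
    centroids, _ = _weighted_sse(points, weights, assign, 1)
    centroids = list(centroids)
    while len(centroids) < k:
        sses = []
        for j in range(len(centroids)):
            sel = assign == j
            if sel.sum() < 2:
                sses.append(-1.0)
                continue
            _, s = _weighted_sse(points[sel], weights[sel], np.zeros(sel.sum(), int), 1)
            sses.append(s)
        j = int(np.argmax(sses))
        sel = assign == j
        sub = points[sel]
        w = weights[sel]
        mean = np.average(sub, axis=0, weights=w)
        cov = np.cov((sub - mean).T, aweights=w) if sel.sum() > 1 else np.eye(3)
        _, vecs = np.linalg.eigh(np.atleast_2d(cov))
        axis = vecs[:, -1]
        side = (sub - mean) @ axis >= 0
        if side.all() or (~side).all():  # degenerate split: peel off extreme point
            side = np.zeros(len(sub), dtype=bool)
            side[np.argmax((sub - mean) @ axis)] = True
        c_hi = np.average(sub[side], axis=0, weights=w[side])
        c_lo = np.average(sub[~side], axis=0, weights=w[~side])
        centroids[j] = c_lo
        centroids.append(c_hi)
        arr = np.asarray(centroids)
        d2 = ((points[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        centroids, _ = _weighted_sse(points, weights, assign, len(arr))
        centroids = list(centroids)
    return np.asarray(centroids)


def minimum_variance_quantize(
    colors: ColorVolume, k: int
) -> tuple[QuantizationModel, np.ndarray]:
    """Partition the brain colour cloud into K minimum-variance clusters.

    Works on the distinct colours weighted by their voxel counts, so the
    cost is independent of image size. For small numbers of distinct
    colours the refinement is restarted from every K-subset of distinct
    colours, which in practice lands on the global optimum; larger clouds
    use a divisive split-and-refine scheme. Both paths are deterministic.

    Returns the model and a label volume with labels 1..K inside the
    brain mask and 0 outside.
    """
    if k < 1:
        raise InputError(f"K must be >= 1, got {k}")
    flat = colors.masked_colors.astype(float)
    if flat.size == 0:
        raise InputError("empty brain mask: no colours to quantize")
    points, inverse, counts = np.unique(flat, axis=0, return_inverse=True, return_counts=True)
    weights = counts.astype(float)
    n_distinct = len(points)
    if n_distinct < k:
        log.warning("only %d distinct colours; reducing K from %d", n_distinct, k)
        k = n_distinct

    if k == 1:
        centroids, sse = _weighted_sse(points, weights, np.zeros(n_distinct, int), 1)
        assign = np.zeros(n_distinct, dtype=int)
    else:
        from math import comb

        best = None
        if n_distinct <= 32 and comb(n_distinct, k) <= 4000:
            for subset in itertools.combinations(range(n_distinct), k):
                c0 = points[list(subset)]
                c, a, s = _lloyd(points, weights, c0.copy())
                if best is None or s < best[2] - 1e-12:
                    best = (c, a, s)
        else:
            c0 = _divisive_init(points, weights, k)
            best = _lloyd(points, weights, c0)
        centroids, assign, sse = best

    # stable cluster order: by red, then green, then blue centroid value
    order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
    centroids = centroids[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assign = relabel[assign]

    model = QuantizationModel(k=k, centroids=centroids, objective=float(sse))

    labels = np.zeros(colors.brain_mask.shape, dtype=np.int16)
    mask = colors.brain_mask.astype(bool)
    labels[mask] = (assign[inverse] + 1).astype(np.int16)
    return model, labels


def extract_lesion_class(
    labels: np.ndarray,
    model: QuantizationModel,
    rule: str = "max_red",
    red_percentile: float = 100.0,
    infarct_mask: LesionMask | np.ndarray | None = None,
    affine: np.ndarray | None = None,
    subject_id: str = "",
) -> LesionMask:
    """Map quantized clusters to the WMH class by FLAIR-hyperintensity.

    Selects clusters whose centroid red value reaches ``red_percentile``
    of the centroid reds (default 100: only the reddest cluster(s)).
    Voxels inside ``infarct_mask`` are removed so the acute symptomatic
    infarct, which is masked separately on FLAIR, is not counted as WMH.
    """
    if rule != "max_red":
        raise InputError(f"unknown class-assignment rule {rule!r}")
    reds = model.centroids[:, 0]
    cutoff = np.percentile(reds, red_percentile)
    chosen = np.flatnonzero(reds >= cutoff - 1e-9) + 1
    if len(chosen) == 0:
        log.warning("no cluster passed the %s rule; returning empty WMH mask", rule)
    mask = np.isin(labels, chosen)
    if len(chosen) == model.k:
        log.warning("WMH rule selected every cluster; check K and contrast")
    if infarct_mask is not None:
        inf = infarct_mask.data if isinstance(infarct_mask, LesionMask) else infarct_mask
        mask &= ~inf.astype(bool)
    if affine is None:
        affine = np.eye(4)
    return LesionMask(mask.astype(np.uint8), affine, lesion_class="wmh", subject_id=subject_id)


# ---------------------------------------------------------------------------
# lacune detection
# ---------------------------------------------------------------------------


def _surface_area_mm2(component: np.ndarray, voxel_size: float) -> float:
    """Exposed-face surface area of a voxel set (crude digital estimate)."""
    padded = np.pad(component, 1)
    faces = 0
    for axis in range(3):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        faces += int(np.abs(diff).sum())
    return faces * voxel_size**2


def sphericity(voxel_count: int, surface_area_mm2: float, voxel_volume_mm3: float = 1.0) -> float:
    """pi^(1/3) (6V)^(2/3) / A — 1 for a perfect sphere, less when irregular.

    With the exposed-face area estimate a digital sphere scores around
    0.6-0.7 rather than 1; thresholds are calibrated to that estimator.
    """
    v = voxel_count * voxel_volume_mm3
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / surface_area_mm2)


def detect_lacunes(
    seq_flair: VolumeImage,
    brain_mask: np.ndarray,
    ventricle_labels: np.ndarray,
    min_diam_mm: float = 3.0,
    max_diam_mm: float = 15.0,
    min_sphericity: float = 0.3,
    threshold: float | None = None,
    csf_mean: float | None = None,
    grey_mean: float | None = None,
) -> tuple[LesionMask, list[LacuneComponent]]:
    """Find round CSF-signal cavities on the FLAIR image by thresholding.

    The CSF cutoff defaults to the midpoint of the CSF and grey tissue
    means when both are supplied, otherwise Otsu's threshold over brain
    voxels. Candidate components (26-connected) are discarded when they
    overlap the ventricles or touch the brain-mask boundary; survivors
    must have an equivalent diameter within [min_diam_mm, max_diam_mm]
    and sphericity >= min_sphericity. Components are returned sorted by
    volume, largest first.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    if not brain_mask.any():
        raise InputError("brain mask is empty")
    if threshold is None:
        if csf_mean is not None and grey_mean is not None:
            threshold = (csf_mean + grey_mean) / 2.0
        else:
            threshold = float(threshold_otsu(seq_flair.data[brain_mask]))

    voxel_size = float(seq_flair.voxel_size_mm[0])
    voxvol = seq_flair.voxel_volume_mm3
    candidate = (seq_flair.data < threshold) & brain_mask
    labels, n = ndimage.label(candidate, structure=_CONN26)

    boundary = brain_mask & ~ndimage.binary_erosion(brain_mask, structure=_CONN26)
    ventricles = np.asarray(ventricle_labels) > 0

    components: list[LacuneComponent] = []
    union = np.zeros(seq_flair.shape, dtype=np.uint8)
    for idx in range(1, n + 1):
        comp = labels == idx
        if (comp & ventricles).any() or (comp & boundary).any():
            continue
        count = int(comp.sum())
        diam = equivalent_diameter_mm(count, voxvol)
        if not (min_diam_mm <= diam <= max_diam_mm):
            continue
        area = _surface_area_mm2(comp, voxel_size)
        sph = sphericity(count, area, voxvol)
        if sph < min_sphericity:
            continue
        voxels = np.argwhere(comp)
        components.append(
            LacuneComponent(
                voxels=voxels,
                volume_ml=count * voxvol / 1000.0,
                equivalent_diameter_mm=diam,
                sphericity=sph,
                centroid=tuple(voxels.mean(axis=0)),
            )
        )
        union[comp] = 1

    components.sort(key=lambda c: -c.volume_ml)
    mask = LesionMask(union, seq_flair.affine, lesion_class="lacune")
    return mask, components
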