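"""Voxel-wise lesion probability-density maps and regional summaries.

A PD map records, at every voxel of the common space, the proportion of
the population whose lesion mask of a given class covers that voxel: if
every subject carries a lesion at a voxel its PD is 1; if half do, 0.5;
a single subject out of N contributes 1/N. The denominator can be the
whole population ("all", used for infarcts and WMH) or only subjects who
carry at least one lesion of the class ("affected_only", used for
lacunes so their PD is not diluted by lacune-free subjects).

Regional values are read with small cubic regions-of-interest placed on
the atlas structures; per-region, per-class values form the region table
that downstream rank statistics consume. Subtraction maps contrast the
spatial distributions of two lesion classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .image import GeometryError, GridMismatchError, InputError, LesionMask, VolumeImage
from .synthetic import LABEL_NAMES, VENTRICLE_LABELS


@dataclass
class PDMap:
    """Voxel-wise lesion probability density plus its denominator."""

    data: np.ndarray  # float64 in [0, 1]
    counts: np.ndarray  # integer lesion counts per voxel
    n: int  # denominator: subjects contributing
    lesion_class: str
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RegionROI:
    """A small cube ROI on a named structure (side in voxels, default 2).

    ``center_voxel`` is the cube's lower-corner voxel; for the default
    even side the geometric centre lies between voxels, so the corner is
    the unambiguous anchor. The cube spans ``center_voxel + [0, side)``
    on each axis.
    """

    name: str
    center_voxel: tuple[int, int, int]
    side_vox: int = 2
    laterality: str = ""  # "left" | "right" | "" (midline / unpaired)


def pd_map(masks: list[LesionMask], denominator_mode: str = "all") -> PDMap:
    """Sum binary masks and divide by the population denominator.

    ``denominator_mode="all"`` divides by the number of masks supplied;
    ``"affected_only"`` divides by the number of non-empty masks (and
    raises if there are none). The voxel values are exact multiples of
    1/N by construction.
    """
    if not masks:
        raise InputError("need at least one mask")
    if denominator_mode not in ("all", "affected_only"):
        raise InputError(f"unknown denominator mode {denominator_mode!r}")
    first = masks[0]
    counts = np.zeros(first.shape, dtype=np.int64)
    classes = {m.lesion_class for m in masks}
    if len(classes) != 1:
        raise InputError(f"masks mix lesion classes: {sorted(classes)}")
    n_nonempty = 0
    for m in masks:
        if not first.same_grid(m):
            raise GridMismatchError("masks are not on a common grid")
        counts += m.data
        n_nonempty += int(not m.is_empty())
    if denominator_mode == "affected_only":
        if n_nonempty == 0:
            raise InputError("affected_only denominator: every mask is empty")
        n = n_nonempty
    else:
        n = len(masks)
    return PDMap(
        data=counts / float(n),
        counts=counts,
        n=n,
        lesion_class=first.lesion_class,
        affine=first.affine.copy(),
    )


def sample_roi(pd: PDMap, roi: RegionROI, summary: str = "mean") -> float:
    """Summarise the PD over the ROI cube (mean by default, or max)."""
    if summary not in ("mean", "max"):
        raise InputError(f"unknown summary {summary!r}")
    lo = np.asarray(roi.center_voxel, dtype=int)
    hi = lo + roi.side_vox
    if np.any(lo < 0) or np.any(hi > np.asarray(pd.shape)):
        raise GeometryError(f"ROI {roi.name} at {roi.center_voxel} falls outside the grid")
    block = pd.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return float(block.mean() if summary == "mean" else block.max())


def default_roiset(atlas: VolumeImage, side_vox: int = 2) -> list[RegionROI]:
    """One ROI per atlas structure, centred on the structure's mass centre.

    The centre voxel is snapped to the nearest voxel of the structure
    when the centroid falls outside it, then clipped so the cube stays
    in-grid. Ventricles are skipped (they are exclusion, not sampling,
    structures).
    """
    labels = atlas.data.astype(int)
    rois = []
    for label in sorted(LABEL_NAMES):
        if label in VENTRICLE_LABELS:
            continue
        name = LABEL_NAMES[label]
        voxels = np.argwhere(labels == label)
        if len(voxels) == 0:
            continue
        centroid = voxels.mean(axis=0)
        nearest = voxels[np.argmin(((voxels - centroid) ** 2).sum(axis=1))]
        corner = nearest - side_vox // 2
        corner = np.clip(corner, 0, np.asarray(atlas.shape) - side_vox)
        laterality = ""
        base = name
        for suffix in ("_left", "_right"):
            if name.endswith(suffix):
                laterality = suffix[1:]
                base = name[: -len(suffix)]
        rois.append(
            RegionROI(
                name=base, center_voxel=tuple(int(v) for v in corner),
                side_vox=side_vox, laterality=laterality,
            )
        )
    return rois


def round_half_up(value: float, decimals: int = 3) -> float:
    """Decimal half-up rounding used for reported tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def region_table(
    pdmaps: dict[str, PDMap],
    roiset: list[RegionROI],
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-(region, laterality) PD summaries, one column per lesion class.

    Values are kept at full precision; use :func:`rounded_table` for the
    3-decimal report form.
    """
    if not pdmaps:
        raise InputError("no PD maps supplied; need one per lesion class of interest")
    grids = list(pdmaps.values())
    for other in grids[1:]:
        if grids[0].shape != other.shape or not np.allclose(grids[0].affine, other.affine):
            raise GridMismatchError("PD maps are not on a common grid")
    for cls, m in pdmaps.items():
        if m.lesion_class != cls:
            raise InputError(f"PD map under key {cls!r} is tagged {m.lesion_class!r}")
    rows = []
    for roi in roiset:
        row: dict[str, object] = {"region": roi.name, "laterality": roi.laterality}
        for cls, m in pdmaps.items():
            row[cls] = sample_roi(m, roi, summary=summary)
        rows.append(row)
    return pd.DataFrame(rows)


def rounded_table(table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: round_half_up(v, decimals))
    return out


def subtract_maps(a: PDMap, b: PDMap) -> tuple[np.ndarray, float]:
    """Voxel-wise a - b plus an overlap summary.

    The overlap fraction is the share of voxels with both maps positive
    among voxels where either is; NaN when neither map has support.
    """
    if a.shape != b.shape or not np.allclose(a.affine, b.affine):
        raise GridMismatchError("PD maps are not on a common grid")
    diff = a.data - b.data
    either = (a.data > 0) | (b.data > 0)
    both = (a.data > 0) & (b.data > 0)
    overlap = float(both.sum() / either.sum()) if either.any() else float("nan")
    return diff, overlap
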