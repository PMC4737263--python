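"""NIfTI-1 and text plumbing: volumes, masks, transforms, PD maps.

Volumes are written as 32-bit float NIfTI, masks as unsigned 8-bit.
Reads reorient to RAS+ when needed (logged) and resample anisotropic
inputs to 1 mm isotropic (logged); masks must be strictly binary.
Transforms round-trip as plain-text 4x4 matrices; PD maps carry their
denominator and lesion class in a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .image import AffineTransform, InputError, LesionMask, VolumeImage
from .pdmap import PDMap

log = logging.getLogger(__name__)


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, path)
    return path


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    canonical = nib.as_closest_canonical(img)
    if canonical is not img:
        log.info("reoriented %s to RAS+ canonical axes", path)
    return canonical


def _isotropize(data: np.ndarray, affine: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample to 1 mm isotropic when voxel sizes are anisotropic."""
    zooms = np.linalg.norm(affine[:3, :3], axis=0)
    if np.allclose(zooms, zooms[0], atol=1e-3):
        return data, affine
    log.info("resampling anisotropic voxels %s to 1 mm isotropic", np.round(zooms, 3))
    factors = zooms / 1.0
    out = ndimage.zoom(data.astype(np.float32), factors, order=order)
    new_affine = affine.copy()
    new_affine[:3, :3] = affine[:3, :3] / zooms[None, :]
    return out, new_affine


def read_volume(path: str | Path, name: str = "") -> VolumeImage:
    img = _load_canonical(path)
    data, affine = _isotropize(np.asanyarray(img.dataobj, dtype=np.float32), img.affine, order=1)
    return VolumeImage(data, affine, name=name or Path(path).stem)


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header["descrip"] = f"lesion_class={mask.lesion_class}".encode()
    nib.save(img, path)
    return path


def read_mask(path: str | Path, lesion_class: str, subject_id: str = "") -> LesionMask:
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        raise InputError(f"mask {path} is not binary; found values {values[:10]}")
    data, affine = _isotropize(data.astype(np.float32), img.affine, order=0)
    return LesionMask(
        (data > 0.5).astype(np.uint8), affine, lesion_class=lesion_class, subject_id=subject_id
    )


def write_transform(transform: AffineTransform, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(transform.to_text() + "\n")
    return path


def read_transform(path: str | Path, dof: int = 12) -> AffineTransform:
    return AffineTransform.from_text(Path(path).read_text(), dof=dof)


def write_pd_map(pdm: PDMap, path: str | Path) -> Path:
    """PD map as float32 NIfTI plus a JSON sidecar with class and denominator."""
    path = Path(path)
    img = nib.Nifti1Image(pdm.data.astype(np.float32), pdm.affine)
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    sidecar = sidecar.parent / (sidecar.name + ".json")
    sidecar.write_text(
        json.dumps({"lesion_class": pdm.lesion_class, "denominator": pdm.n}, indent=2)
    )
    return path


def read_pd_map(path: str | Path) -> PDMap:
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    stem = Path(path)
    sidecar = stem.with_suffix("").with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".json")
    meta = json.loads(sidecar.read_text())
    n = int(meta["denominator"])
    counts = np.rint(data * n).astype(np.int64)
    return PDMap(
        data=data, counts=counts, n=n, lesion_class=meta["lesion_class"], affine=img.affine
    )


def array_sha256(*arrays: np.ndarray) -> str:
    """Content hash of array data (shape, dtype and bytes), file-format free."""
    import hashlib

    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.shape).encode())
        h.update(str(a.dtype).encode())
        h.update(a.tobytes())
    return h.hexdigest()
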