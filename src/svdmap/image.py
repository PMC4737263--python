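"""Core spatial containers: intensity volumes, binary lesion masks, affine transforms.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` tuples;
* world coordinates are RAS+ millimetres;
* every volume carries its own 4x4 voxel-to-world affine;
* grids are isotropic 1 mm by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LESION_CLASSES = ("infarct", "wmh", "lacune")


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class ConfigurationError(ValueError):
    """A specification or configuration field is invalid."""


class InputError(ValueError):
    """An operation received data it cannot act on."""


class GeometryError(ValueError):
    """A geometric object (ROI, transform target) falls outside the grid."""


class NumericalError(ArithmeticError):
    """A numerical precondition (invertibility, positive-definiteness) failed."""


class GenerationError(RuntimeError):
    """Synthetic data generation failed after bounded retries."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ConfigurationError(f"affine must be 4x4, got {affine.shape}")
    if not np.allclose(affine[3], (0.0, 0.0, 0.0, 1.0)):
        raise ConfigurationError("affine last row must be (0, 0, 0, 1)")
    return affine


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel spacing and a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError(f"volume must be 3D, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Length of each voxel edge in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumeImage | LesionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)

    def require_same_grid(self, other: "VolumeImage | LesionMask", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} are not on a common grid: "
                f"{self.shape} vs {other.shape} or differing affines"
            )

    def world_coordinates(self, voxels: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to (N, 3) world coordinates."""
        voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
        return voxels @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LesionMask:
    """Binary 3D grid tagged with a lesion class (infarct | wmh | lacune)."""

    data: np.ndarray
    affine: np.ndarray
    lesion_class: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ConfigurationError(f"mask must be 3D, got shape {data.shape}")
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            raise InputError(f"mask is not binary; found values {values[:10]}")
        self.data = data.astype(np.uint8)
        self.affine = _check_affine(self.affine)
        if self.lesion_class not in LESION_CLASSES:
            raise ConfigurationError(
                f"lesion_class must be one of {LESION_CLASSES}, got {self.lesion_class!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def same_grid(self, other: "VolumeImage | LesionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)


@dataclass
class AffineTransform:
    """A world-to-world homogeneous transform with a degrees-of-freedom tag.

    ``dof=6`` marks a rigid-body transform (orthonormal rotation block with
    determinant +1); ``dof=12`` a full affine. The matrix maps points of the
    *target* (fixed) world frame into the *source* (moving) world frame, i.e.
    it is the pull-back map used directly for resampling.
    """

    matrix: np.ndarray
    dof: int = 12
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = _check_affine(self.matrix)
        if self.dof not in (6, 12):
            raise ConfigurationError(f"dof must be 6 or 12, got {self.dof}")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise NumericalError("transform matrix is singular")
        if self.dof == 6:
            R = self.matrix[:3, :3]
            if not (np.allclose(R @ R.T, np.eye(3), atol=1e-6) and np.linalg.det(R) > 0):
                raise ConfigurationError(
                    "rigid (dof=6) transform requires an orthonormal rotation block with det +1"
                )

    @classmethod
    def identity(cls, dof: int = 12) -> "AffineTransform":
        return cls(np.eye(4), dof=dof)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), dof=self.dof)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform equivalent to applying ``other`` after ``self``.

        As pull-back maps: ``(self.compose(other))(x) = other(self(x))``.
        """
        dof = 6 if (self.dof == 6 and other.dof == 6) else 12
        return AffineTransform(other.matrix @ self.matrix, dof=dof)

    def to_text(self) -> str:
        return "\n".join(" ".join(f"{v: .12g}" for v in row) for row in self.matrix)

    @classmethod
    def from_text(cls, text: str, dof: int = 12) -> "AffineTransform":
        rows = [[float(v) for v in line.split()] for line in text.strip().splitlines()]
        return cls(np.asarray(rows), dof=dof)
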