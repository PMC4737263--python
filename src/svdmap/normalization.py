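"""Representative-subject selection and affine spatial normalization.

The population-representative "average" brain is the subject whose four
volumetric features (intracranial, brain, ventricular, WMH volume in ml)
are jointly closest to the cohort median in Mahalanobis distance under
the cohort's sample covariance.

Registration minimises the mean-squared intensity difference between a
moving and a fixed volume over a 3-level coarse-to-fine pyramid, using a
deterministic derivative-free (Powell) search started at identity. Both
volumes are assumed to share a modality, which holds for the synthetic
cohort; cross-modal registration is out of scope. Transforms are
world-to-world pull-back maps (fixed-frame point -> moving-frame point),
directly usable for resampling moving-frame data onto the fixed grid.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, optimize

from .image import (
    AffineTransform,
    InputError,
    LesionMask,
    NumericalError,
    VolumeImage,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# representative subject
# ---------------------------------------------------------------------------


def mahalanobis_distance(x, center, covariance) -> float:
    """sqrt((x - center)^T Sigma^-1 (x - center)); 0 iff x equals center."""
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance is not symmetric positive-definite") from exc
    diff = x - center
    y = np.linalg.solve(chol, diff)
    return float(np.sqrt(y @ y))


def cohort_covariance(features: np.ndarray, ridge_scale: float = 1e-8) -> np.ndarray:
    """Sample covariance (n-1 denominator) with a trace-scaled ridge."""
    features = np.asarray(features, dtype=float)
    cov = np.cov(features, rowvar=False)
    ridge = ridge_scale * np.trace(cov) / cov.shape[0]
    return cov + ridge * np.eye(cov.shape[0])


def select_representative(cohort_features) -> int:
    """Index of the subject closest to the component-wise cohort median.

    Distance is Mahalanobis under the (ridge-regularised) cohort sample
    covariance; ties break to the lowest index.
    """
    features = np.asarray(cohort_features, dtype=float)
    if features.ndim != 2 or len(features) < 3:
        raise InputError(f"need >= 3 subjects with feature vectors, got shape {features.shape}")
    if not np.all(np.isfinite(features)) or not np.all(features > 0):
        raise InputError("volumetric features must be finite and positive")
    center = np.median(features, axis=0)
    cov = cohort_covariance(features)
    distances = [mahalanobis_distance(f, center, cov) for f in features]
    return int(np.argmin(distances))


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _params_to_matrix(params: np.ndarray, center: np.ndarray, dof: int) -> np.ndarray:
    """(tx,ty,tz mm, rx,ry,rz deg[, scales %, shears %]) -> 4x4 world matrix.

    Rotation/scaling act about ``center`` so translation and rotation
    stay decoupled during optimisation.
    """
    t = params[0:3]
    angles = np.deg2rad(params[3:6])
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    linear = rot_z @ rot_y @ rot_x
    if dof == 12:
        scales = 1.0 + params[6:9] / 100.0
        shears = params[9:12] / 100.0
        shear = np.array(
            [[1.0, shears[0], shears[1]], [0.0, 1.0, shears[2]], [0.0, 0.0, 1.0]]
        )
        linear = linear @ shear @ np.diag(scales)
    matrix = np.eye(4)
    matrix[:3, :3] = linear
    matrix[:3, 3] = center - linear @ center + t
    return matrix


def _downsample(volume: VolumeImage, factor: int) -> VolumeImage:
    if factor == 1:
        return volume
    smoothed = ndimage.gaussian_filter(volume.data.astype(np.float32), sigma=factor / 2.0)
    data = smoothed[::factor, ::factor, ::factor]
    affine = volume.affine.copy()
    affine[:3, :3] *= factor
    return VolumeImage(data, affine, name=volume.name)


def _warp_onto(moving: VolumeImage, fixed: VolumeImage, world_matrix: np.ndarray) -> np.ndarray:
    vox = np.linalg.inv(moving.affine) @ world_matrix @ fixed.affine
    return ndimage.affine_transform(
        moving.data.astype(np.float32),
        vox[:3, :3],
        offset=vox[:3, 3],
        output_shape=fixed.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )


def register_affine(
    moving: VolumeImage,
    fixed: VolumeImage,
    dof: int = 12,
    pyramid_factors: tuple[int, ...] = (4, 2, 1),
) -> AffineTransform:
    """Estimate the world-to-world transform aligning ``moving`` to ``fixed``.

    Returns the pull-back map (fixed-frame point -> moving-frame point);
    resampling ``moving`` data through it reproduces ``fixed``'s anatomy.
    The returned transform's ``meta`` carries the initial and final MSE
    cost and a ``converged`` flag; failure to reduce the cost logs a
    registration-quality warning but still returns the transform.
    """
    if dof not in (6, 12):
        raise InputError(f"dof must be 6 or 12, got {dof}")
    n_params = 6 if dof == 6 else 12
    center = fixed.world_coordinates((np.asarray(fixed.shape) - 1) / 2.0)[0]
    params = np.zeros(n_params)
    initial_cost = final_cost = None

    for level, factor in enumerate(pyramid_factors):
        mov = _downsample(moving, factor)
        fix = _downsample(fixed, factor)
        fix_data = fix.data.astype(np.float32)

        def cost(p):
            matrix = _params_to_matrix(p, center, dof)
            warped = _warp_onto(mov, fix, matrix)
            return float(((warped - fix_data) ** 2).mean())

        if initial_cost is None:
            initial_cost = cost(params)

        stages = [np.arange(n_params)]
        if dof == 12 and level == 0:
            stages = [np.arange(6), np.arange(n_params)]  # rigid first at coarse level
        for active in stages:
            def sub_cost(sub):
                full = params.copy()
                full[active] = sub
                return cost(full)

            result = optimize.minimize(
                sub_cost,
                params[active],
                method="Powell",
                options={
                    "xtol": 1e-3 if factor > 1 else 5e-3,
                    "ftol": 1e-6 if factor > 1 else 1e-4,
                    "maxiter": {1: 2, 2: 8}.get(factor, 20),
                },
            )
            params = params.copy()
            params[active] = result.x
        final_cost = cost(params)

    converged = final_cost is not None and initial_cost is not None and final_cost < initial_cost
    if not converged:
        log.warning(
            "registration of %s to %s did not reduce cost (%.4g -> %.4g); returning transform",
            moving.name,
            fixed.name,
            initial_cost,
            final_cost,
        )
    matrix = _params_to_matrix(params, center, dof)
    return AffineTransform(
        matrix,
        dof=dof,
        meta={
            "initial_cost": initial_cost,
            "final_cost": final_cost,
            "converged": bool(converged),
            "params": params.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_volume(
    volume: VolumeImage, transform: AffineTransform, target: VolumeImage, order: int = 1
) -> VolumeImage:
    """Pull ``volume`` back through ``transform`` onto ``target``'s grid."""
    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise NumericalError("degenerate transform")
    data = _warp_onto(volume, target, transform.matrix) if order == 1 else None
    if order != 1:
        vox = np.linalg.inv(volume.affine) @ transform.matrix @ target.affine
        data = ndimage.affine_transform(
            volume.data,
            vox[:3, :3],
            offset=vox[:3, 3],
            output_shape=target.shape,
            order=order,
            mode="constant",
            cval=0.0,
        )
    return VolumeImage(data, target.affine.copy(), name=volume.name)


def resample_mask(
    mask: LesionMask, transform: AffineTransform, target: VolumeImage
) -> LesionMask:
    """Trilinear pull-back of a binary mask, re-binarised at 0.5."""
    as_volume = VolumeImage(mask.data.astype(np.float32), mask.affine)
    warped = resample_volume(as_volume, transform, target, order=1)
    binary = (warped.data >= 0.5).astype(np.uint8)
    return LesionMask(
        binary, target.affine.copy(), lesion_class=mask.lesion_class, subject_id=mask.subject_id
    )


def displacement_error_voxels(
    estimated: AffineTransform,
    truth: AffineTransform,
    grid: VolumeImage,
    within: np.ndarray | None = None,
) -> float:
    """Mean distance (in voxels) between estimated and true pull-back maps.

    Evaluated at the world coordinates of grid voxels, by default all of
    them, optionally restricted to a boolean region such as the brain.
    """
    if within is None:
        within = np.ones(grid.shape, dtype=bool)
    voxels = np.argwhere(within)
    world = grid.world_coordinates(voxels)
    delta = estimated.apply(world) - truth.apply(world)
    voxel_size = float(grid.voxel_size_mm[0])
    return float(np.linalg.norm(delta, axis=1).mean() / voxel_size)
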