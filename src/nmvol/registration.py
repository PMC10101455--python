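"""Rigid motion correction, series averaging, and ROI mapping.

The repeated NM-MRI measurements of a session differ by small head motion;
each later measurement is registered to the first with a 6-DOF rigid-body
transform minimizing the mean-squared intensity difference after trilinear
resampling, and the realigned series is averaged voxelwise. Standard-space
ROIs and atlases reach native space through a precomputed transform chain
applied in a single composed resampling pass; nonlinear standard-space
registration is deliberately out of scope (chains are supplied, not fitted).

The rigid estimator follows the classic intensity-based realignment recipe:
both images are lightly smoothed, a fixed coarse grid over translations
seeds the search, and a Gauss-Newton / Levenberg-Marquardt refinement with
an analytic image-gradient Jacobian polishes the six parameters, capped at
±5° / ±5 mm. There is no randomness anywhere, so the estimate is
deterministic — scan-rescan reproducibility is the selling point of the
volumetry this supports.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import DegenerateImageError, GridMismatchError
from .image import BinaryMask, ProbabilisticAtlas, VoxelImage, resample
from .transforms import RigidTransform, TransformChain

__all__ = [
    "estimate_rigid",
    "motion_correct_and_average",
    "map_roi_to_native",
    "transform_discrepancy_vox",
]

PARAM_BOUND_DEG = 5.0
PARAM_BOUND_MM = 5.0
_COARSE_STEPS_MM = (-2.0, -1.0, 0.0, 1.0, 2.0)
# Registration-only pre-smoothing, (in-plane, through-plane) FWHM in mm.
# The through-plane kernel is wider because thick slices make trilinear
# interpolation along z both rough and noise-sensitive; smoothing both
# images symmetrically suppresses the interpolation-induced bias there.
_SMOOTH_FWHM_MM = (1.2, 4.0)
_FOV_MARGIN_MM = 2.5  # rim excluded from the cost on both images
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _decimate_steps(shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """In-plane decimation for the registration cost (keeps all slices)."""
    step = 2 if min(shape[0], shape[1]) >= 48 else 1
    return (step, step, 1)


def _smooth_mm(image: VoxelImage, fwhm_mm: tuple[float, float]) -> np.ndarray:
    inplane, through = fwhm_mm
    if inplane <= 0 and through <= 0:
        return image.data.astype(np.float64)
    fwhms = (inplane, inplane, through)
    sigma_vox = [f * _FWHM_TO_SIGMA / d for f, d in zip(fwhms, image.voxel_dims)]
    return ndimage.gaussian_filter(image.data.astype(np.float64), sigma_vox)


def _sample(volume: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(
        volume, coords, order=order, mode="constant", cval=0.0, prefilter=False
    )


def _euler_matrix(angles_deg: np.ndarray) -> np.ndarray:
    return Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()


def _euler_derivatives(angles_deg: np.ndarray, h: float = 1e-6) -> list[np.ndarray]:
    """dR/dθ_i (per degree) by central differences on the 3x3 matrix."""
    derivs = []
    for i in range(3):
        up, dn = angles_deg.copy(), angles_deg.copy()
        up[i] += h
        dn[i] -= h
        derivs.append((_euler_matrix(up) - _euler_matrix(dn)) / (2 * h))
    return derivs


class _RigidCost:
    """Masked MSE between a warped moving image and the fixed image.

    Parameters are p = (3 Euler angles in degrees, 3 translations in mm)
    of the map S(p): fixed world → moving world, y = R(x−c) + c + τ. The
    returned transform is S(p)⁻¹, i.e. the moving→fixed map resampling
    expects. Voxels sampled from outside the moving field of view are
    excluded so the cost compares tissue, not zero-fill.
    """

    def __init__(self, moving: VoxelImage, fixed: VoxelImage, fwhm_mm: float):
        self.center = fixed.world_center()
        steps = _decimate_steps(fixed.shape)
        # exclude a rim where motion brings unseen tissue into either FOV
        margins = [
            min(int(np.ceil(_FOV_MARGIN_MM / d)), (n - 1) // 2)
            for d, n in zip(fixed.voxel_dims, fixed.shape)
        ]
        sel = tuple(
            slice(m, n - m, s) for n, s, m in zip(fixed.shape, steps, margins)
        )

        mov = _smooth_mm(moving, fwhm_mm)
        fix = _smooth_mm(fixed, fwhm_mm)
        self.fixed_values = fix[sel].ravel()

        # world coordinates of the decimated, rim-clipped fixed grid
        idx = np.stack(
            np.meshgrid(
                *[
                    np.arange(m, n - m, s, dtype=float)
                    for n, s, m in zip(fixed.shape, steps, margins)
                ],
                indexing="ij",
            )
        ).reshape(3, -1)
        self.fixed_world = fixed.affine[:3, :3] @ idx + fixed.affine[:3, [3]]

        self.mov_volume = mov
        self.mov_inv_affine = np.linalg.inv(moving.affine)
        # moving-image gradient in world units: ∇_x f = (A⁻¹)ᵀ ∇_index F
        gi = np.gradient(mov)
        ainv = self.mov_inv_affine[:3, :3]
        self.mov_grad = [
            ainv[0, 0] * gi[0] + ainv[1, 0] * gi[1] + ainv[2, 0] * gi[2],
            ainv[0, 1] * gi[0] + ainv[1, 1] * gi[1] + ainv[2, 1] * gi[2],
            ainv[0, 2] * gi[0] + ainv[1, 2] * gi[1] + ainv[2, 2] * gi[2],
        ]
        shape = np.asarray(moving.shape, dtype=float)
        self.index_lo = np.array(margins, dtype=float)
        self.index_hi = shape - 1 - self.index_lo

    def _moving_index(self, params: np.ndarray) -> np.ndarray:
        rot = _euler_matrix(params[:3])
        y = rot @ (self.fixed_world - self.center[:, None])
        y += self.center[:, None] + params[3:][:, None]
        return (
            self.mov_inv_affine[:3, :3] @ y + self.mov_inv_affine[:3, [3]]
        )

    def residual_and_jacobian(self, params: np.ndarray):
        coords = self._moving_index(params)
        inside = np.all(
            (coords >= self.index_lo[:, None]) & (coords <= self.index_hi[:, None]),
            axis=0,
        )
        warped = _sample(self.mov_volume, coords)
        r = np.where(inside, warped - self.fixed_values, 0.0)
        grad = np.stack([_sample(g, coords) for g in self.mov_grad])
        grad[:, ~inside] = 0.0

        derivs = _euler_derivatives(params[:3])
        centered = self.fixed_world - self.center[:, None]
        jac = np.empty((r.size, 6))
        for i in range(3):
            dy = derivs[i] @ centered
            jac[:, i] = np.einsum("ij,ij->j", grad, dy)
        jac[:, 3:] = grad.T
        n = max(int(inside.sum()), 1)
        return r, jac, n

    def cost(self, params: np.ndarray) -> float:
        coords = self._moving_index(params)
        inside = np.all(
            (coords >= self.index_lo[:, None]) & (coords <= self.index_hi[:, None]),
            axis=0,
        )
        warped = _sample(self.mov_volume, coords)
        r = np.where(inside, warped - self.fixed_values, 0.0)
        n = max(int(inside.sum()), 1)
        return float(r @ r) / n


def _levenberg_marquardt(cost: _RigidCost, start: np.ndarray) -> np.ndarray:
    params = start.astype(float).copy()
    lam = 1e-3
    best = cost.cost(params)
    for _ in range(60):
        r, jac, n = cost.residual_and_jacobian(params)
        jtj = jac.T @ jac
        jtr = jac.T @ r
        stepped = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(
                    jtj + lam * np.diag(np.diag(jtj).clip(min=1e-12)), -jtr
                )
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            candidate = np.clip(
                params + delta,
                [-PARAM_BOUND_DEG] * 3 + [-PARAM_BOUND_MM] * 3,
                [PARAM_BOUND_DEG] * 3 + [PARAM_BOUND_MM] * 3,
            )
            c = cost.cost(candidate)
            if c < best:
                params, best = candidate, c
                lam = max(lam / 10, 1e-10)
                stepped = True
                break
            lam *= 10
        if not stepped:
            break
        if np.max(np.abs(delta)) < 1e-6:
            break
    return params


def estimate_rigid(
    moving: VoxelImage,
    fixed: VoxelImage,
    smooth_fwhm_mm: tuple[float, float] = _SMOOTH_FWHM_MM,
) -> RigidTransform:
    """Estimate the 6-DOF transform aligning ``moving`` onto ``fixed``.

    Returns the rigid transform T minimizing the mean-squared intensity
    difference between ``resample(moving, T, fixed)`` and ``fixed``,
    pivoting about the fixed image's world center. A fixed coarse grid over
    translations seeds a Levenberg-Marquardt refinement with an analytic
    image-gradient Jacobian; both images are pre-smoothed (registration
    only) by ``smooth_fwhm_mm``. Deterministic given its inputs. Raises
    :class:`DegenerateImageError` for constant images (no gradient signal).
    """
    if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
        raise DegenerateImageError("constant image: rigid cost has no signal")
    cost = _RigidCost(moving, fixed, smooth_fwhm_mm)

    best_start = np.zeros(6)
    best_cost = cost.cost(best_start)
    for tx in _COARSE_STEPS_MM:
        for ty in _COARSE_STEPS_MM:
            for tz in _COARSE_STEPS_MM:
                if tx == ty == tz == 0.0:
                    continue
                candidate = np.array([0.0, 0.0, 0.0, tx, ty, tz])
                c = cost.cost(candidate)
                if c < best_cost:
                    best_cost, best_start = c, candidate

    params = _levenberg_marquardt(cost, best_start)
    fitted = RigidTransform(
        tuple(params[:3]), tuple(params[3:]), tuple(cost.center)
    )
    return fitted.inverse()


def transform_discrepancy_vox(
    a: RigidTransform,
    b: RigidTransform,
    image: VoxelImage,
    points_world: np.ndarray | None = None,
) -> float:
    """Mean displacement discrepancy between two transforms, in voxel units.

    Each world point is mapped through both transforms; the displacement
    difference is expressed per axis in units of that axis's voxel size and
    its Euclidean norm averaged. By default points span the whole grid;
    pass ``points_world`` (3×N, mm) to evaluate where it matters (e.g. the
    segmented structures).
    """
    if points_world is None:
        idx = np.stack(
            np.meshgrid(
                *[np.linspace(0, n - 1, 5) for n in image.shape], indexing="ij"
            )
        ).reshape(3, -1)
        points_world = image.affine[:3, :3] @ idx + image.affine[:3, [3]]
    homo = np.vstack([points_world, np.ones(points_world.shape[1])])
    diff = (a.as_matrix() - b.as_matrix()) @ homo
    per_axis = diff[:3] / np.asarray(image.voxel_dims)[:, None]
    return float(np.sqrt((per_axis**2).sum(axis=0)).mean())


def motion_correct_and_average(
    measurements: list[VoxelImage],
    transforms: list[RigidTransform] | None = None,
    skip_moco: bool = False,
) -> VoxelImage:
    """Register measurements 2..n to the first and average voxelwise.

    ``transforms`` may supply known motion (e.g. phantom ground truth, one
    transform per measurement, the first ignored); otherwise each transform
    is estimated. With ``skip_moco`` the raw series is averaged unaligned.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    first = measurements[0]
    for m in measurements[1:]:
        if not m.same_grid_as(first):
            raise GridMismatchError("measurements are not on a common grid")
    if len(measurements) == 1:
        return first.copy()

    accum = first.data.astype(np.float64).copy()
    for k, meas in enumerate(measurements[1:], start=1):
        if skip_moco:
            aligned = meas
        elif transforms is not None:
            aligned = resample(meas, transforms[k], first)
        else:
            aligned = resample(meas, estimate_rigid(meas, first), first)
        accum += aligned.data
    return VoxelImage(accum / len(measurements), first.affine.copy())


def map_roi_to_native(
    roi: ProbabilisticAtlas | BinaryMask,
    chain: TransformChain,
    native: VoxelImage,
    source_space: str = "standard",
    native_space: str = "native",
) -> ProbabilisticAtlas | BinaryMask:
    """Map a standard-space ROI/atlas onto the native grid in one pass.

    The chain must connect ``source_space`` to ``native_space``; it is
    composed into a single transform before resampling (trilinear for
    atlases, nearest-neighbour for masks), so multi-link chains cost one
    interpolation.
    """
    chain.require_connects(source_space, native_space)
    return resample(roi, chain, native)
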