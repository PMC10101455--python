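"""Volumetric image containers, NIfTI-1 I/O, and single-pass resampling.

The data model is deliberately small: a :class:`VoxelImage` is a 3D scalar
grid plus a 4x4 voxel-index→world affine (NIfTI RAS convention, 0-based
indices); :class:`BinaryMask` and :class:`ProbabilisticAtlas` are the same
grid with restricted value ranges. All resampling goes through
:func:`resample`, which composes an arbitrary transform chain into one map
and interpolates exactly once (trilinear for scalar data, nearest-neighbour
for masks) so repeated spatial operations do not accumulate smoothing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, TransformError
from .transforms import AffineTransform, RigidTransform, TransformChain, _as_matrix

__all__ = [
    "VoxelImage",
    "BinaryMask",
    "ProbabilisticAtlas",
    "read_image",
    "read_series",
    "read_mask",
    "read_atlas",
    "write_image",
    "resample",
    "mask_volume",
]


def _voxel_dims(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class VoxelImage:
    """3D intensity grid (arbitrary units) with a voxel→world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    _allow_any_values = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(self.affine[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("affine last row must be (0, 0, 0, 1)")
        if min(self.voxel_dims) <= 0:
            raise ValueError("voxel dimensions must be strictly positive")
        self._check_values()

    def _check_values(self) -> None:
        pass

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """(dx, dy, dz) in mm, taken from the affine column norms."""
        return _voxel_dims(self.affine)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def world_center(self) -> np.ndarray:
        """World coordinates (mm) of the grid's geometric center."""
        center_index = (np.asarray(self.shape, dtype=float) - 1) / 2
        return (self.affine @ np.append(center_index, 1.0))[:3]

    def same_grid_as(self, other: "VoxelImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy(self) -> "VoxelImage":
        return type(self)(self.data.copy(), self.affine.copy())


class BinaryMask(VoxelImage):
    """Boolean ROI on an image grid; stored as bool, written as uint8."""

    def _check_values(self) -> None:
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be strictly in {0, 1}")
            self.data = self.data.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


class ProbabilisticAtlas(VoxelImage):
    """Spatial probability map with values in [0, 1]."""

    def _check_values(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.size and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ValueError("atlas values must lie in [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)


def read_image(path: str | os.PathLike) -> VoxelImage:
    """Read a 3D NIfTI-1 volume.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    non-3D image (a 4D measurement series must go through
    :func:`read_series`).
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D "
            "(use read_series for a 4D measurement series)"
        )
    return VoxelImage(np.asarray(data, dtype=np.float32), np.asarray(img.affine))


def read_series(path: str | os.PathLike) -> list[VoxelImage]:
    """Read a 4D NIfTI-1 series as a list of 3D measurements."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    affine = np.asarray(img.affine)
    return [
        VoxelImage(np.asarray(data[..., k], dtype=np.float32), affine.copy())
        for k in range(data.shape[3])
    ]


def read_mask(path: str | os.PathLike) -> BinaryMask:
    img = read_image(path)
    return BinaryMask(img.data > 0.5, img.affine)


def read_atlas(path: str | os.PathLike) -> ProbabilisticAtlas:
    img = read_image(path)
    return ProbabilisticAtlas(img.data, img.affine)


def write_image(image: VoxelImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; masks as uint8, scalars as float32."""
    if isinstance(image, BinaryMask):
        data = image.data.astype(np.uint8)
    else:
        data = np.asarray(image.data, dtype=np.float32)
    nib.save(nib.Nifti1Image(data, image.affine), os.fspath(path))


def write_series(measurements: list[VoxelImage], path: str | os.PathLike) -> None:
    """Write a measurement list as one 4D NIfTI-1 file (common grid required)."""
    first = measurements[0]
    for m in measurements[1:]:
        if not m.same_grid_as(first):
            raise GridMismatchError("series measurements are not on a common grid")
    stacked = np.stack(
        [np.asarray(m.data, dtype=np.float32) for m in measurements], axis=-1
    )
    nib.save(nib.Nifti1Image(stacked, first.affine), os.fspath(path))


def _normalize_transforms(transform) -> list:
    if isinstance(transform, TransformChain):
        return [transform.composed_matrix()]
    if isinstance(transform, (list, tuple)):
        return list(transform)
    return [transform]


def resample(source: VoxelImage, transform, target_grid: VoxelImage) -> VoxelImage:
    """Resample ``source`` onto the grid of ``target_grid``.

    ``transform`` maps source world coordinates to target world coordinates
    and may be a single rigid/affine transform, a list of them (applied in
    order), or a :class:`~nmvol.transforms.TransformChain`. However many
    links, they are composed into a single map and the data is interpolated
    once: trilinear for scalar images and atlases, nearest-neighbour for
    binary masks. Voxels that fall outside the source field of view are 0.
    """
    transforms = _normalize_transforms(transform)
    world_map = np.eye(4)
    for t in transforms:
        world_map = _as_matrix(t) @ world_map

    identity = np.allclose(world_map, np.eye(4), atol=1e-12)
    if identity and source.same_grid_as(target_grid):
        return source.copy()

    # target index -> target world -> source world -> source index
    try:
        full = (
            np.linalg.inv(source.affine)
            @ np.linalg.inv(world_map)
            @ target_grid.affine
        )
    except np.linalg.LinAlgError as exc:
        raise TransformError("transform chain is not invertible") from exc

    is_mask = isinstance(source, BinaryMask)
    order = 0 if is_mask else 1
    src = source.data.astype(np.float32) if is_mask else source.data
    out = ndimage.affine_transform(
        src,
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=target_grid.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if is_mask:
        return BinaryMask(out > 0.5, target_grid.affine.copy())
    if isinstance(source, ProbabilisticAtlas):
        return ProbabilisticAtlas(np.clip(out, 0.0, 1.0), target_grid.affine.copy())
    return VoxelImage(out.astype(source.data.dtype, copy=False), target_grid.affine.copy())


def mask_volume(mask: BinaryMask, voxel_dims: tuple[float, float, float] | None = None) -> float:
    """Volume of a binary mask in mm³: (true voxels) × dx·dy·dz."""
    if voxel_dims is None:
        voxel_dims = mask.voxel_dims
    dx, dy, dz = voxel_dims
    return float(mask.data.sum()) * dx * dy * dz
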