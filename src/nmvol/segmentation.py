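"""Reference-ROI threshold segmentation of SNc and LC and volumetry.

The segmentation rule: measure the mean μ_ref and standard deviation σ_ref
of the signal in a cerebral-peduncle reference ROI, build a search region by
thresholding the structure's probabilistic atlas (in native space) at 5% and
dilating it, then keep search-region voxels whose intensity is strictly
greater than μ_ref + k·σ_ref. The multiplier k is 2.8 for the substantia
nigra pars compacta and 3.9 for the locus coeruleus — the LC threshold is
higher to guard against hyperintense artefact near the fourth ventricle.
Both hemispheres contribute to a single bilateral volume per structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateReferenceError, EmptyRegionError, GridMismatchError
from .image import BinaryMask, ProbabilisticAtlas, VoxelImage, mask_volume

__all__ = [
    "ReferenceStats",
    "SegmentationParams",
    "SegmentationResult",
    "SNC_PARAMS",
    "LC_PARAMS",
    "reference_stats",
    "build_search_region",
    "segment_structure",
    "segment_subject",
]


@dataclass(frozen=True)
class ReferenceStats:
    """Reference-region intensity statistics.

    ``sigma_ref`` is the sample standard deviation with the n−1 denominator;
    with reference regions of hundreds of voxels the denominator choice is
    numerically immaterial, but it is fixed for reproducibility.
    """

    mu_ref: float
    sigma_ref: float
    n_ref: int

    def __post_init__(self) -> None:
        if self.n_ref < 2:
            raise DegenerateReferenceError(
                f"reference region needs >= 2 voxels, got {self.n_ref}"
            )
        # zero spread up to float rounding on the mean magnitude
        if self.sigma_ref <= 1e-12 * max(1.0, abs(self.mu_ref)):
            raise DegenerateReferenceError(
                "reference region has zero intensity spread; "
                "a threshold at mu_ref + k*sigma_ref is undefined"
            )

    def threshold(self, k: float) -> float:
        return self.mu_ref + k * self.sigma_ref


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold multiplier and search-region construction parameters.

    k
        Reference-SD multiplier: 2.8 for SNc, 3.9 for LC.
    atlas_threshold
        Atlas probability cut (default 0.05, i.e. the 5% level).
    dilation_iterations
        Binary dilations (6-connected) applied to the thresholded atlas so
        the search region covers the whole structure; default 2.
    """

    k: float
    atlas_threshold: float = 0.05
    dilation_iterations: int = 2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("threshold multiplier k must be > 0")
        if not 0 < self.atlas_threshold < 1:
            raise ValueError("atlas_threshold must lie in (0, 1)")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")


SNC_PARAMS = SegmentationParams(k=2.8)
LC_PARAMS = SegmentationParams(k=3.9)


@dataclass
class SegmentationResult:
    """Binary segmentation with its voxel count, volume, and provenance."""

    mask: BinaryMask
    voxel_count: int
    volume_mm3: float
    threshold_value: float
    params: SegmentationParams
    ref_stats: ReferenceStats
    n_components: int | None = field(default=None)

    def count_components(self) -> int:
        """Number of 6-connected components (post-hoc report; no filtering)."""
        _, n = ndimage.label(
            self.mask.data, structure=ndimage.generate_binary_structure(3, 1)
        )
        self.n_components = int(n)
        return self.n_components


def reference_stats(image: VoxelImage, ref_mask: BinaryMask) -> ReferenceStats:
    """Sample mean and SD (n−1 denominator) of intensities under ``ref_mask``."""
    if not image.same_grid_as(ref_mask):
        raise GridMismatchError("reference mask is not on the image grid")
    values = image.data[ref_mask.data]
    n = int(values.size)
    if n < 2:
        raise DegenerateReferenceError(f"reference region has {n} voxel(s), need >= 2")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    return ReferenceStats(mu_ref=mu, sigma_ref=sigma, n_ref=n)


def build_search_region(
    atlas: ProbabilisticAtlas, params: SegmentationParams
) -> BinaryMask:
    """Threshold a native-space atlas at ``atlas_threshold`` and dilate.

    Dilation uses the 3D 6-connected structuring element, applied
    ``dilation_iterations`` times. Raises :class:`EmptyRegionError` if no
    voxel exceeds the probability cut.
    """
    core = atlas.data > params.atlas_threshold
    if not core.any():
        raise EmptyRegionError(
            f"no atlas voxel exceeds probability {params.atlas_threshold}"
        )
    if params.dilation_iterations > 0:
        core = ndimage.binary_dilation(
            core,
            structure=ndimage.generate_binary_structure(3, 1),
            iterations=params.dilation_iterations,
        )
    return BinaryMask(core, atlas.affine.copy())


def segment_structure(
    image: VoxelImage,
    search: BinaryMask,
    ref: ReferenceStats,
    params: SegmentationParams,
) -> SegmentationResult:
    """Keep search-region voxels with intensity strictly above μ_ref + k·σ_ref.

    The inequality is strict; a voxel exactly at the threshold is excluded.
    An empty result is a valid outcome (volume 0), not an error.
    """
    if not image.same_grid_as(search):
        raise GridMismatchError("search region is not on the image grid")
    if not search.data.any():
        raise EmptyRegionError("search region is empty")
    threshold = ref.threshold(params.k)
    selected = search.data & (image.data > threshold)
    mask = BinaryMask(selected, image.affine.copy())
    return SegmentationResult(
        mask=mask,
        voxel_count=int(selected.sum()),
        volume_mm3=mask_volume(mask),
        threshold_value=float(threshold),
        params=params,
        ref_stats=ref,
    )


def segment_subject(
    averaged: VoxelImage,
    snc_atlas: ProbabilisticAtlas,
    lc_atlas: ProbabilisticAtlas,
    ref_mask: BinaryMask,
    params_snc: SegmentationParams = SNC_PARAMS,
    params_lc: SegmentationParams = LC_PARAMS,
) -> tuple[SegmentationResult, SegmentationResult]:
    """Full per-subject procedure on a motion-corrected average image.

    Reference statistics are computed once and shared; each structure gets
    its own search region and threshold. All inputs must already be in
    native space on the image grid. Returns ``(SNc result, LC result)``,
    each a single bilateral volume.
    """
    ref = reference_stats(averaged, ref_mask)
    snc_search = build_search_region(snc_atlas, params_snc)
    lc_search = build_search_region(lc_atlas, params_lc)
    snc = segment_structure(averaged, snc_search, ref, params_snc)
    lc = segment_structure(averaged, lc_search, ref, params_lc)
    return snc, lc
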