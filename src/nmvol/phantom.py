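"""Synthetic NM-MRI phantom subjects and cohorts with known ground truth.

A phantom subject emulates the structure of a neuromelanin-sensitive
acquisition: a 0.39×0.39 mm in-plane / 3 mm slice grid, a series of 7
repeated measurements differing by small rigid head motion and independent
noise, bilateral hyperintense structures — a crescent-shaped substantia
nigra pars compacta (SNc) in the upper slices and a rod-shaped locus
coeruleus (LC, ≈2 mm diameter, ≤15 mm long) below it — over a homogeneous
background, plus a bilateral cerebral-peduncle-like reference region.
Contrast is parametric (intensity units above background), not biophysical;
no pulse-sequence physics is simulated.

Ground-truth masks are voxelized by ranking voxels with an analytic shape
score and keeping exactly ``round(volume / voxel_volume)`` of them, split
evenly across hemispheres, so the mask volume matches the requested volume
to within one voxel.

Cohort generation draws per-subject true volumes from group-specific normal
distributions whose defaults reproduce a published two-group summary (SNc
429 vs 329 mm³, LC 8.0 vs 5.2 mm³ at n = 33 controls / 39 patients, with
per-subject SDs recovered from the printed standard errors as SE·√n).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SpecificationError
from .image import BinaryMask, ProbabilisticAtlas, VoxelImage, mask_volume, resample
from .transforms import RigidTransform

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_subject",
    "generate_cohort",
    "iter_cohort_subjects",
    "sample_cohort_table",
    "make_atlases",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Schematic brainstem geometry (mm, relative to the grid's world center).
# The SNc is a pair of medial-facing crescents in the upper slices; the LC a
# pair of thin vertical rods below; the reference region two lateral
# cylinders at the SNc slice level, clear of both structures and of the
# dilated search regions.
_SNC_Z_CENTER = 6.0
_SNC_ARC_CENTER_X = 10.0  # hemisphere arc-circle center offset (±x)
_SNC_ARC_RADIUS = 6.0
_SNC_ARC_HALFSPAN_DEG = 60.0  # arc spans 120°..240° toward the midline
_SNC_HALF_THICKNESS = 1.6
_SNC_HALF_HEIGHT = 4.5
_LC_Z_CENTER = -7.5
_LC_CENTER_X = 4.0
_REF_CENTER_X = 13.5
_REF_RADIUS = 2.5
_REF_HALF_HEIGHT = 4.6


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic subject.

    Intensity units are arbitrary. ``snc_contrast`` / ``lc_contrast`` are
    added on top of ``background_mean`` inside the structures, so the
    structure contrast-to-noise ratio is contrast / noise SD. Defaults put
    each structure's segmentation threshold (2.8 resp. 3.9 reference SDs on
    the 7-measurement average) at about half the structure contrast, the
    half-maximum criterion under blur.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 15)
    voxel_dims: tuple[float, float, float] = (0.39, 0.39, 3.0)
    n_measurements: int = 7
    background_mean: float = 100.0
    background_sd: float = 10.0
    ref_region_mean: float = 100.0
    ref_region_sd: float = 10.0
    snc_contrast: float = 21.0
    lc_contrast: float = 29.0
    snc_volume_true: float = 429.0
    lc_volume_true: float = 8.0
    lc_diameter: float = 2.0
    lc_length: float = 15.0
    blur_fwhm: float = 0.5
    texture_amplitude: float = 10.0
    texture_fwhm: float = 4.0
    noise_model: str = "gaussian"
    motion_sd: tuple[float, float] = (0.5, 0.5)  # (degrees, mm) per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_measurements < 1:
            raise SpecificationError("n_measurements must be >= 1")
        if self.snc_volume_true <= 0 or self.lc_volume_true <= 0:
            raise SpecificationError("structure volumes must be positive")
        if not 0 < self.lc_length <= 15.0:
            raise SpecificationError("lc_length must lie in (0, 15] mm")
        if self.lc_diameter <= 0:
            raise SpecificationError("lc_diameter must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise SpecificationError(f"unknown noise model {self.noise_model!r}")
        if min(self.grid_shape) < 1 or min(self.voxel_dims) <= 0:
            raise SpecificationError("grid_shape and voxel_dims must be positive")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def affine(self) -> np.ndarray:
        """RAS affine centering the grid on the world origin."""
        aff = np.diag(list(self.voxel_dims) + [1.0])
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2 * np.asarray(
            self.voxel_dims
        )
        return aff


@dataclass
class GroundTruth:
    """Per-subject truth: structure and reference masks, motion, volumes.

    ``true_transforms[k]`` maps measurement ``k`` into the frame of
    measurement 0, i.e. it is the transform a perfect motion-correction step
    would recover (identity for measurement 0).
    """

    snc_mask: BinaryMask
    lc_mask: BinaryMask
    ref_mask: BinaryMask
    true_transforms: list[RigidTransform]
    true_volumes: dict[str, float]


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    affine = spec.affine()
    idx = [np.arange(n, dtype=float) for n in spec.grid_shape]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    x = affine[0, 0] * ii + affine[0, 3]
    y = affine[1, 1] * jj + affine[1, 3]
    z = affine[2, 2] * kk + affine[2, 3]
    return x, y, z


def _best_n_voxels(score: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the n smallest-score voxels (stable index tie-break)."""
    flat = score.ravel()
    order = np.argsort(flat, kind="stable")
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:n]] = True
    return mask.reshape(score.shape)


def _snc_score(x: np.ndarray, y: np.ndarray, z: np.ndarray, side: int) -> np.ndarray:
    """Anisotropic distance to a medial-facing crescent arc on one side."""
    cx = side * _SNC_ARC_CENTER_X
    dx, dy = x - cx, y
    r = np.hypot(dx, dy)
    d_arc = np.abs(r - _SNC_ARC_RADIUS)
    # angular distance beyond the arc span, measured from the midline-facing
    # direction (pointing from the arc center toward the midline)
    theta = np.degrees(np.arctan2(dy, -side * dx))  # 0° = toward midline
    d_angle = np.clip(np.abs(theta) - _SNC_ARC_HALFSPAN_DEG, 0.0, None)
    arc_overshoot = np.radians(d_angle) * _SNC_ARC_RADIUS
    planar = np.hypot(d_arc, arc_overshoot)
    dz = z - _SNC_Z_CENTER
    return np.hypot(planar / _SNC_HALF_THICKNESS, dz / _SNC_HALF_HEIGHT)


def _lc_score(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, side: int, spec: PhantomSpec
) -> np.ndarray:
    """Ellipsoidal distance to a vertical rod on one side."""
    r = np.hypot(x - side * _LC_CENTER_X, y)
    dz = z - _LC_Z_CENTER
    return np.hypot(r / (spec.lc_diameter / 2.0), dz / (spec.lc_length / 2.0))


def _bilateral_mask(spec: PhantomSpec, volume_mm3: float, score_fn) -> np.ndarray:
    n_total = int(round(volume_mm3 / spec.voxel_volume))
    if n_total < 1:
        raise SpecificationError(
            f"requested volume {volume_mm3} mm3 is below one voxel"
        )
    if n_total > np.prod(spec.grid_shape) // 4:
        raise SpecificationError(
            f"requested volume {volume_mm3} mm3 is too large for the grid"
        )
    x, y, z = _world_grids(spec)
    n_left = n_total // 2
    n_right = n_total - n_left
    mask = _best_n_voxels(score_fn(x, y, z, +1), n_right)
    mask |= _best_n_voxels(score_fn(x, y, z, -1), n_left)
    return mask


def _ref_mask_array(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _world_grids(spec)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for side in (+1, -1):
        r = np.hypot(x - side * _REF_CENTER_X, y)
        mask |= (r <= _REF_RADIUS) & (np.abs(z - _SNC_Z_CENTER) <= _REF_HALF_HEIGHT)
    return mask


def build_ground_truth_masks(
    spec: PhantomSpec,
) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Voxelized SNc, LC and reference masks on the spec grid."""
    affine = spec.affine()
    snc = _bilateral_mask(spec, spec.snc_volume_true, _snc_score)
    lc = _bilateral_mask(
        spec, spec.lc_volume_true, lambda x, y, z, s: _lc_score(x, y, z, s, spec)
    )
    ref = _ref_mask_array(spec)
    if (snc & ref).any() or (lc & ref).any() or (snc & lc).any():
        raise SpecificationError(
            "phantom structures overlap; reduce requested volumes"
        )
    return (
        BinaryMask(snc, affine.copy()),
        BinaryMask(lc, affine.copy()),
        BinaryMask(ref, affine.copy()),
    )


def _ideal_image(
    spec: PhantomSpec,
    snc: BinaryMask,
    lc: BinaryMask,
    ref: BinaryMask,
    rng: np.random.Generator,
) -> VoxelImage:
    data = np.full(spec.grid_shape, spec.background_mean, dtype=np.float64)
    if spec.texture_amplitude > 0:
        # smooth anatomical texture: fixed for the subject, so it moves with
        # the head and gives motion correction realistic traction; tapered
        # out inside the nuclei and the homogeneous reference region
        sigma_vox = [spec.texture_fwhm * FWHM_TO_SIGMA / d for d in spec.voxel_dims]
        texture = ndimage.gaussian_filter(
            rng.standard_normal(spec.grid_shape), sigma_vox
        )
        sd = texture.std()
        if sd > 0:
            texture *= spec.texture_amplitude / sd
        # keep the neighbourhood that atlas-based search regions can reach
        # (thresholded atlas plus dilation, including adjacent thick slices)
        # homogeneous, then ramp the texture up to full amplitude
        protected = ndimage.binary_dilation(
            snc.data | lc.data | ref.data,
            structure=ndimage.generate_binary_structure(3, 1),
            iterations=4,
        )
        dist_mm = ndimage.distance_transform_edt(
            ~protected, sampling=spec.voxel_dims
        )
        taper = np.clip((dist_mm - 1.0) / 3.0, 0.0, 1.0)
        data += texture * taper
    data[snc.data] = spec.background_mean + spec.snc_contrast
    data[lc.data] = spec.background_mean + spec.lc_contrast
    data[ref.data] = spec.ref_region_mean
    if spec.blur_fwhm > 0:
        sigma_vox = [
            spec.blur_fwhm * FWHM_TO_SIGMA / d for d in spec.voxel_dims
        ]
        data = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    return VoxelImage(data, spec.affine())


def _noise_sd_map(spec: PhantomSpec, ref: BinaryMask) -> np.ndarray:
    sd = np.full(spec.grid_shape, spec.background_sd, dtype=np.float64)
    sd[ref.data] = spec.ref_region_sd
    return sd


def _add_noise(
    data: np.ndarray, sd_map: np.ndarray, model: str, rng: np.random.Generator
) -> np.ndarray:
    if model == "gaussian":
        return data + rng.standard_normal(data.shape) * sd_map
    # Rician: magnitude of a complex signal with iid Gaussian noise in each
    # channel — the correct model for magnitude MRI at low SNR.
    re = data + rng.standard_normal(data.shape) * sd_map
    im = rng.standard_normal(data.shape) * sd_map
    return np.hypot(re, im)


def generate_subject(spec: PhantomSpec) -> tuple[list[VoxelImage], GroundTruth]:
    """Simulate one subject: ``n_measurements`` noisy, jittered volumes.

    Measurement 0 has identity motion; measurements 1..n−1 are resampled
    through independent small rigid transforms (per-axis normal jitter with
    the ``motion_sd`` scales, pivoting about the grid center). Noise is
    independent per measurement: ``background_sd`` everywhere except the
    reference region, which uses ``ref_region_sd``. Identical seeds yield
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    snc, lc, ref = build_ground_truth_masks(spec)
    ideal = _ideal_image(spec, snc, lc, ref, rng)
    sd_map = _noise_sd_map(spec, ref)
    center = tuple(ideal.world_center())

    measurements: list[VoxelImage] = []
    true_transforms: list[RigidTransform] = []
    rot_sd, trans_sd = spec.motion_sd
    for k in range(spec.n_measurements):
        if k == 0 or (rot_sd == 0 and trans_sd == 0):
            motion = RigidTransform(center=center)
            moved = ideal.copy()
        else:
            motion = RigidTransform(
                rotation=tuple(rng.normal(0.0, rot_sd, 3)),
                translation=tuple(rng.normal(0.0, trans_sd, 3)),
                center=center,
            )
            # the phantom surround is homogeneous background, so head motion
            # brings background (not zeros) into the field of view
            shifted = resample(
                VoxelImage(ideal.data - spec.background_mean, ideal.affine.copy()),
                motion,
                ideal,
            )
            moved = VoxelImage(
                shifted.data + spec.background_mean, ideal.affine.copy()
            )
        noisy = moved.data
        if spec.background_sd > 0 or spec.ref_region_sd > 0:
            noisy = _add_noise(noisy, sd_map, spec.noise_model, rng)
        measurements.append(VoxelImage(noisy, ideal.affine.copy()))
        true_transforms.append(motion.inverse())

    truth = GroundTruth(
        snc_mask=snc,
        lc_mask=lc,
        ref_mask=ref,
        true_transforms=true_transforms,
        true_volumes={
            "snc": mask_volume(snc),
            "lc": mask_volume(lc),
        },
    )
    return measurements, truth


def make_atlases(
    spec: PhantomSpec, fwhm_mm: float = 1.5
) -> tuple[ProbabilisticAtlas, ProbabilisticAtlas, BinaryMask]:
    """Simulator-supplied 'standard-space' atlas pair and reference ROI.

    Smoothed, peak-normalized versions of the canonical ground-truth masks
    on the phantom grid; with identity transform chains these play the role
    of probabilistic atlases already mapped to native space. Build them from
    a control-mean spec so the thresholded-and-dilated search region covers
    the per-subject volume variation of both groups.
    """
    snc, lc, ref = build_ground_truth_masks(spec)

    def smooth(mask: BinaryMask) -> ProbabilisticAtlas:
        sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / d for d in spec.voxel_dims]
        prob = ndimage.gaussian_filter(mask.data.astype(np.float64), sigma=sigma_vox)
        peak = prob.max()
        if peak <= 0:
            raise SpecificationError("empty mask cannot be made into an atlas")
        return ProbabilisticAtlas(prob / peak, mask.affine.copy())

    return smooth(snc), smooth(lc), ref


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort distributional parameters.

    Defaults reproduce the published cohort-2 summary statistics: group
    means straight from the printed table, per-subject SDs recovered from
    the printed standard errors as SE·√n (SNc: 20·√33 and 17·√39; LC:
    0.6·√33 and 0.6·√39; age SE 1.6 in both groups).
    """

    n_control: int = 33
    n_pd: int = 39
    snc_mean_control: float = 429.0
    snc_sd_control: float = 20.0 * np.sqrt(33)
    snc_mean_pd: float = 329.0
    snc_sd_pd: float = 17.0 * np.sqrt(39)
    lc_mean_control: float = 8.0
    lc_sd_control: float = 0.6 * np.sqrt(33)
    lc_mean_pd: float = 5.2
    lc_sd_pd: float = 0.6 * np.sqrt(39)
    age_control: tuple[float, float] = (63.5, 1.6 * np.sqrt(33))
    age_pd: tuple[float, float] = (63.8, 1.6 * np.sqrt(39))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_pd < 0:
            raise SpecificationError("group sizes must be nonnegative")
        for name in (
            "snc_sd_control",
            "snc_sd_pd",
            "lc_sd_control",
            "lc_sd_pd",
        ):
            if getattr(self, name) < 0:
                raise SpecificationError(f"{name} must be nonnegative")


# Clinical-score group summaries (mean, SE) and group sizes used to recover
# per-subject SDs, from the same published cohort-2 table. Scores are drawn
# independently of the volumes; the published clinical correlations with
# volume are weak-to-null, and the null is the honest default.
_CLINICAL_COHORT2 = {
    "education": {"control": (16.7, 0.4), "pd": (17.0, 0.6), "floor": 0.0},
    "updrs3": {"control": (1.8, 1.9), "pd": (18.9, 1.1), "floor": 0.0},
    "moca": {"control": (28.0, 0.3), "pd": (27.8, 0.3), "floor": 0.0, "cap": 30.0},
    "nmsq": {"control": (3.2, 0.5), "pd": (6.6, 0.7), "floor": 0.0},
    "rbdsq": {"control": (2.7, 0.4), "pd": (3.7, 0.4), "floor": 0.0},
    "disease_duration": {"control": None, "pd": (3.5, 0.6), "floor": 0.0},
    "ledd": {"control": None, "pd": (623.3, 70.8), "floor": 0.0},
}
_MALE_FRACTION = {"control": 11 / 33, "pd": 22 / 39}
_REFERENCE_N = {"control": 33, "pd": 39}

VOLUME_FLOOR_FRACTION = 0.05  # truncation floor as a fraction of the group mean


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, floor: float
) -> np.ndarray:
    """Normal draws redrawn until above ``floor`` (rejection sampling)."""
    if sd == 0:
        return np.full(size, max(mean, floor))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise SpecificationError(
        f"truncated sampling at floor {floor} did not converge "
        f"(mean {mean}, sd {sd})"
    )


def _subject_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def sample_cohort_table(cspec: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject ground-truth table (no imaging).

    Columns: subject_id, group, age, sex, education, disease_duration,
    updrs3, ledd, moca, nmsq, rbdsq, snc_volume_true, lc_volume_true.
    Volumes are normal draws truncated at 5% of the group mean.
    """
    rng = np.random.default_rng(cspec.seed)
    rows: list[dict] = []
    groups = [
        (
            "control",
            cspec.n_control,
            (cspec.snc_mean_control, cspec.snc_sd_control),
            (cspec.lc_mean_control, cspec.lc_sd_control),
            cspec.age_control,
        ),
        (
            "pd",
            cspec.n_pd,
            (cspec.snc_mean_pd, cspec.snc_sd_pd),
            (cspec.lc_mean_pd, cspec.lc_sd_pd),
            cspec.age_pd,
        ),
    ]
    for group, n, (snc_m, snc_sd), (lc_m, lc_sd), (age_m, age_sd) in groups:
        if n == 0:
            continue
        snc = _truncated_normal(rng, snc_m, snc_sd, n, VOLUME_FLOOR_FRACTION * snc_m)
        lc = _truncated_normal(rng, lc_m, lc_sd, n, VOLUME_FLOOR_FRACTION * lc_m)
        age = rng.normal(age_m, age_sd, n)
        sex = np.where(rng.random(n) < _MALE_FRACTION[group], "M", "F")
        n_ref = _REFERENCE_N[group]
        clinical: dict[str, np.ndarray] = {}
        for name, summary in _CLINICAL_COHORT2.items():
            params = summary[group]
            if params is None:
                clinical[name] = np.full(n, np.nan)
                continue
            mean, se = params
            values = _truncated_normal(
                rng, mean, se * np.sqrt(n_ref), n, summary.get("floor", -np.inf)
            )
            if "cap" in summary:
                values = np.minimum(values, summary["cap"])
            clinical[name] = values
        prefix = "C" if group == "control" else "P"
        for i, sid in enumerate(_subject_ids(prefix, n)):
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": float(age[i]),
                    "sex": str(sex[i]),
                    "education": float(clinical["education"][i]),
                    "disease_duration": float(clinical["disease_duration"][i]),
                    "updrs3": float(clinical["updrs3"][i]),
                    "ledd": float(clinical["ledd"][i]),
                    "moca": float(clinical["moca"][i]),
                    "nmsq": float(clinical["nmsq"][i]),
                    "rbdsq": float(clinical["rbdsq"][i]),
                    "snc_volume_true": float(snc[i]),
                    "lc_volume_true": float(lc[i]),
                }
            )
    columns = [
        "subject_id",
        "group",
        "age",
        "sex",
        "education",
        "disease_duration",
        "updrs3",
        "ledd",
        "moca",
        "nmsq",
        "rbdsq",
        "snc_volume_true",
        "lc_volume_true",
    ]
    return pd.DataFrame(rows, columns=columns)


def iter_cohort_subjects(cspec: CohortSpec, pspec: PhantomSpec, table: pd.DataFrame):
    """Yield (subject_id, measurements, GroundTruth) for each table row.

    Each subject's phantom uses that subject's true volumes and a seed
    derived deterministically from the cohort seed.
    """
    seed_rng = np.random.default_rng(cspec.seed + 1)
    seeds = seed_rng.integers(0, 2**31 - 1, size=len(table))
    for (_, row), subject_seed in zip(table.iterrows(), seeds):
        spec = replace(
            pspec,
            snc_volume_true=float(row["snc_volume_true"]),
            lc_volume_true=float(row["lc_volume_true"]),
            seed=int(subject_seed),
        )
        measurements, truth = generate_subject(spec)
        yield str(row["subject_id"]), measurements, truth


def generate_cohort(
    cspec: CohortSpec, pspec: PhantomSpec
) -> tuple[list[tuple[str, list[VoxelImage], GroundTruth]], pd.DataFrame]:
    """Materialize a full imaging cohort in memory.

    For large cohorts prefer :func:`iter_cohort_subjects` (streaming) or the
    pipeline's simulate command, which writes subjects to disk one at a time.
    """
    table = sample_cohort_table(cspec)
    subjects = list(iter_cohort_subjects(cspec, pspec, table))
    return subjects, table
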