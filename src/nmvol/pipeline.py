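"""End-to-end orchestration: simulate, segment, stats, with a run manifest.

The three stages are plain functions over a :class:`PipelineConfig` (loaded
from YAML); the CLI in :mod:`nmvol.cli` is a thin wrapper around them. Every
stage appends to a JSON run manifest recording the config snapshot, package
version, per-stage wall-clock and SHA-256 checksums of its outputs, so a
run is reproducible and any silent-default drift is visible.

On-disk cohort layout (produced by :func:`cmd_simulate`, consumed by
:func:`cmd_segment`):

    <data_dir>/
      subjects.csv                    # demographics + true volumes
      atlases/{snc,lc}_atlas.nii.gz   # simulator standard-space atlases
      atlases/ref_roi.nii.gz          # cerebral-peduncle-like reference ROI
      subjects/<id>/series.nii.gz     # 4D measurement series
      subjects/<id>/truth_*.nii.gz    # ground-truth masks (simulated data)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EmptyRegionError, NmvolError, SpecificationError
from .image import read_atlas, read_mask, read_series, write_image, write_series
from .phantom import CohortSpec, PhantomSpec, iter_cohort_subjects, make_atlases, sample_cohort_table
from .registration import map_roi_to_native, motion_correct_and_average
from .segmentation import SegmentationParams, segment_subject
from .stats import cohort_report, report_markdown
from .transforms import TransformChain

logger = logging.getLogger("nmvol")

VOLUME_COLUMNS = [
    "subject_id",
    "structure",
    "voxel_count",
    "volume_mm3",
    "mu_ref",
    "sigma_ref",
    "threshold_value",
    "k",
    "dilation_iterations",
]


@dataclass
class PipelineConfig:
    """Typed pipeline configuration with published defaults.

    Threshold multipliers default to 2.8 (SNc) and 3.9 (LC); the atlas cut
    to 5%; α to 0.05. All fields are echoed into the manifest.
    """

    data_dir: str = "nmvol_data"
    output_dir: str = "nmvol_out"
    seed: int = 0
    # segmentation
    k_snc: float = 2.8
    k_lc: float = 3.9
    atlas_threshold: float = 0.05
    dilation_iterations: int = 2
    # registration
    moco: bool = True
    transforms_dir: str | None = None  # per-subject <id>.json chains; else identity
    write_masks: bool = False
    # statistics
    covariates: list[str] = field(default_factory=lambda: ["age", "education"])
    alpha: float = 0.05
    roc_se_method: str = "hanley-mcneil"
    # simulation overrides (field name -> value) for CohortSpec / PhantomSpec
    cohort: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_snc <= 0 or self.k_lc <= 0:
            raise SpecificationError("threshold multipliers must be positive")
        if not 0 < self.atlas_threshold < 1:
            raise SpecificationError("atlas_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise SpecificationError("alpha must lie in (0, 1)")
        if self.roc_se_method not in ("hanley-mcneil", "delong"):
            raise SpecificationError(f"unknown roc_se_method {self.roc_se_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SpecificationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def snc_params(self) -> SegmentationParams:
        return SegmentationParams(
            self.k_snc, self.atlas_threshold, self.dilation_iterations
        )

    def lc_params(self) -> SegmentationParams:
        return SegmentationParams(
            self.k_lc, self.atlas_threshold, self.dilation_iterations
        )

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**{"seed": self.seed, **self.cohort})

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(**self.phantom)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Append-only record of a pipeline run, persisted as JSON."""

    def __init__(self, path: Path, config: PipelineConfig):
        self.path = Path(path)
        if self.path.exists():
            self.payload = json.loads(self.path.read_text())
        else:
            self.payload = {"nmvol_version": __version__, "stages": {}}
        self.payload["config"] = dataclasses.asdict(config)

    def record_stage(self, name: str, outputs: list[Path], seconds: float) -> None:
        self.payload["stages"][name] = {
            "wall_clock_s": round(seconds, 3),
            "outputs": {
                str(p): _sha256(p) for p in outputs if Path(p).is_file()
            },
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.payload, indent=2, sort_keys=True))


def cmd_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate a phantom cohort on disk under ``config.data_dir``."""
    t0 = time.monotonic()
    data_dir = Path(config.data_dir)
    (data_dir / "atlases").mkdir(parents=True, exist_ok=True)
    cspec = config.cohort_spec()
    pspec = config.phantom_spec()

    snc_atlas, lc_atlas, ref_roi = make_atlases(pspec)
    write_image(snc_atlas, data_dir / "atlases" / "snc_atlas.nii.gz")
    write_image(lc_atlas, data_dir / "atlases" / "lc_atlas.nii.gz")
    write_image(ref_roi, data_dir / "atlases" / "ref_roi.nii.gz")

    table = sample_cohort_table(cspec)
    outputs = [data_dir / "atlases" / n for n in (
        "snc_atlas.nii.gz", "lc_atlas.nii.gz", "ref_roi.nii.gz")]
    for subject_id, measurements, truth in iter_cohort_subjects(
        cspec, pspec, table
    ):
        sub_dir = data_dir / "subjects" / subject_id
        sub_dir.mkdir(parents=True, exist_ok=True)
        write_series(measurements, sub_dir / "series.nii.gz")
        write_image(truth.snc_mask, sub_dir / "truth_snc.nii.gz")
        write_image(truth.lc_mask, sub_dir / "truth_lc.nii.gz")
        write_image(truth.ref_mask, sub_dir / "truth_ref.nii.gz")
        chain = TransformChain.identity("standard").append(
            np.eye(4), "native"
        )
        (sub_dir / "standard_to_native.json").write_text(
            json.dumps(chain.to_json_dict())
        )
        outputs.append(sub_dir / "series.nii.gz")
        logger.info("simulated subject %s", subject_id)
    table.to_csv(data_dir / "subjects.csv", index=False)
    outputs.append(data_dir / "subjects.csv")

    manifest = RunManifest(data_dir / "manifest.json", config)
    manifest.record_stage("simulate", outputs, time.monotonic() - t0)
    return table


def _load_chain(config: PipelineConfig, sub_dir: Path, subject_id: str) -> TransformChain:
    if config.transforms_dir is not None:
        path = Path(config.transforms_dir) / f"{subject_id}.json"
    else:
        path = sub_dir / "standard_to_native.json"
    if path.is_file():
        return TransformChain.from_json_dict(json.loads(path.read_text()))
    return TransformChain(links=[np.eye(4)], spaces=["standard", "native"])


def cmd_segment(config: PipelineConfig) -> pd.DataFrame:
    """Motion-correct, average, map ROIs, and segment every subject.

    Subjects that fail are logged and skipped; the volumes CSV covers the
    rest. Raises :class:`EmptyRegionError` only if no subject is found.
    """
    t0 = time.monotonic()
    data_dir = Path(config.data_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    snc_atlas = read_atlas(data_dir / "atlases" / "snc_atlas.nii.gz")
    lc_atlas = read_atlas(data_dir / "atlases" / "lc_atlas.nii.gz")
    ref_roi = read_mask(data_dir / "atlases" / "ref_roi.nii.gz")

    subject_dirs = sorted(
        p for p in (data_dir / "subjects").glob("*") if (p / "series.nii.gz").is_file()
    )
    if not subject_dirs:
        raise EmptyRegionError(f"no subjects found under {data_dir / 'subjects'}")

    rows: list[dict] = []
    failures: list[str] = []
    for sub_dir in subject_dirs:
        subject_id = sub_dir.name
        try:
            measurements = read_series(sub_dir / "series.nii.gz")
            averaged = motion_correct_and_average(
                measurements, skip_moco=not config.moco
            )
            chain = _load_chain(config, sub_dir, subject_id)
            snc_native = map_roi_to_native(snc_atlas, chain, averaged)
            lc_native = map_roi_to_native(lc_atlas, chain, averaged)
            ref_native = map_roi_to_native(ref_roi, chain, averaged)
            snc, lc = segment_subject(
                averaged,
                snc_native,
                lc_native,
                ref_native,
                config.snc_params(),
                config.lc_params(),
            )
            for structure, res in (("snc", snc), ("lc", lc)):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "structure": structure,
                        "voxel_count": res.voxel_count,
                        "volume_mm3": res.volume_mm3,
                        "mu_ref": res.ref_stats.mu_ref,
                        "sigma_ref": res.ref_stats.sigma_ref,
                        "threshold_value": res.threshold_value,
                        "k": res.params.k,
                        "dilation_iterations": res.params.dilation_iterations,
                    }
                )
                if config.write_masks:
                    mask_dir = out_dir / "masks"
                    mask_dir.mkdir(exist_ok=True)
                    write_image(
                        res.mask, mask_dir / f"{subject_id}_{structure}.nii.gz"
                    )
            logger.info(
                "segmented %s: SNc %.1f mm3, LC %.1f mm3",
                subject_id,
                snc.volume_mm3,
                lc.volume_mm3,
            )
        except NmvolError as exc:
            failures.append(subject_id)
            logger.warning("subject %s failed: %s", subject_id, exc)

    volumes = pd.DataFrame(rows, columns=VOLUME_COLUMNS)
    volumes.to_csv(out_dir / "volumes.csv", index=False)
    manifest = RunManifest(out_dir / "manifest.json", config)
    manifest.record_stage(
        "segment", [out_dir / "volumes.csv"], time.monotonic() - t0
    )
    if failures:
        logger.warning("%d subject(s) failed: %s", len(failures), failures)
    volumes.attrs["failures"] = failures
    return volumes


def merge_volumes_demographics(
    volumes: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Pivot the long volumes CSV to wide and join the subject table."""
    wide = volumes.pivot(
        index="subject_id", columns="structure", values="volume_mm3"
    ).rename(columns={"snc": "snc_volume", "lc": "lc_volume"})
    return demographics.merge(wide.reset_index(), on="subject_id", how="inner")


def cmd_stats(config: PipelineConfig) -> dict:
    """Run the cohort statistics on measured volumes and write the report."""
    t0 = time.monotonic()
    out_dir = Path(config.output_dir)
    volumes = pd.read_csv(out_dir / "volumes.csv")
    demographics = pd.read_csv(Path(config.data_dir) / "subjects.csv")
    required = {"subject_id", "group", "age"}
    missing = required - set(demographics.columns)
    if missing:
        raise SpecificationError(f"demographics CSV lacks columns: {sorted(missing)}")
    merged = merge_volumes_demographics(volumes, demographics)

    report = cohort_report(
        merged,
        covariates=config.covariates,
        alpha=config.alpha,
        roc_se_method=config.roc_se_method,
    )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    (out_dir / "report.md").write_text(report_markdown(report))
    curves = []
    for label, block in report.get("roc", {}).items():
        for fpr, tpr in zip(block["curve"]["fpr"], block["curve"]["tpr"]):
            curves.append({"marker": label, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(curves).to_csv(out_dir / "roc_points.csv", index=False)

    manifest = RunManifest(out_dir / "manifest.json", config)
    manifest.record_stage(
        "stats",
        [out_dir / "report.json", out_dir / "report.md", out_dir / "roc_points.csv"],
        time.monotonic() - t0,
    )
    return report


def cmd_run_all(config: PipelineConfig) -> dict:
    """simulate → segment → stats."""
    cmd_simulate(config)
    cmd_segment(config)
    return cmd_stats(config)
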