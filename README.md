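# nmvol — neuromelanin-sensitive MRI volumetry of SNc and LC

Parkinson's disease depletes the melanized neurons of the substantia nigra
pars compacta (SNc) and locus coeruleus (LC). On neuromelanin-sensitive MRI
(NM-MRI, a gradient-echo acquisition with an explicit magnetization-transfer
preparation), both nuclei appear as small hyperintense structures against
the brainstem, and their apparent volumes shrink with disease. `nmvol`
implements the full measurement pipeline and its cohort analysis for
researchers who want to study, stress-test, or reuse this volumetry:

1. **Motion-corrected averaging** — the 7 repeated NM-MRI measurements of a
   session are rigidly realigned to the first (6-DOF, mean-squared-error
   cost, deterministic Levenberg–Marquardt with an analytic image-gradient
   Jacobian) and averaged voxelwise, reducing noise by ≈ √7.
2. **Reference-ROI threshold segmentation** — with μ_ref, σ_ref the mean and
   SD of the signal in a cerebral-peduncle reference ROI, a voxel inside an
   atlas-derived search region (probabilistic atlas mapped to native space,
   thresholded at 5%, dilated) belongs to a structure when

   I(v) > μ_ref + k·σ_ref,  with k = 2.8 (SNc) and k = 3.9 (LC),

   and the bilateral suprathreshold volume in mm³ is the biomarker.
3. **Cohort statistics** — Shapiro–Wilk normality, two-tailed Welch's *t*
   (from raw samples or printed mean ± SE summaries), ANCOVA for the group
   effect with age/education covariates, Pearson correlations with age
   partialled out, and ROC/AUC with Hanley–McNeil (or DeLong) standard
   errors, including a combined SNc + LC logistic marker.
4. **Phantom simulator** — since clinical scans cannot be redistributed, a
   synthetic NM-MRI cohort generator reproduces the acquisition grid
   (0.39 × 0.39 mm in-plane, 3 mm slices), a 7-measurement series with
   small rigid jitter, bilateral crescent (SNc) and ≈2 mm × 15 mm rod (LC)
   structures with known ground-truth masks, Gaussian or Rician noise, and
   group-level volume distributions calibrated to published two-group
   summaries (SNc 429 vs 329 mm³, LC 8.0 vs 5.2 mm³ at n = 33/39).

## Worked example

Simulate a 12-subject cohort, segment it, and analyse it:

```bash
nmvol run-all --data-dir demo_data --output-dir demo_out --seed 42
```

or equivalently from Python:

```python
from nmvol.pipeline import PipelineConfig, cmd_run_all

cfg = PipelineConfig(data_dir="demo_data", output_dir="demo_out", seed=42,
                     cohort={"n_control": 6, "n_pd": 6})
report = cmd_run_all(cfg)
```

`demo_out/report.md` then contains (among other blocks):

```
## Group comparisons

- SNc Welch t = 0.583, df = 9.9, p = 0.5726 (control: 444.4 ± 56.2, pd: 399.9 ± 51.5)
- LC Welch t = 3.334, df = 9.4, p = 0.008199 (control: 8.4 ± 0.9, pd: 3.3 ± 1.2)

## ROC analysis

- SNc: AUC = 0.583 (SE 0.171, 95% CI 0.249–0.918, p = 0.631)
- LC: AUC = 0.889 (SE 0.103, 95% CI 0.687–1.000, p = 0.025)
- combined: AUC = 0.917 (SE 0.090, 95% CI 0.741–1.000, p = 0.0163)
```

Reading: each line is a group comparison of the measured bilateral volumes
(mean ± standard error, mm³). At n = 6 + 6 the LC deficit built into the
simulated cohort is detected (t = 3.33, p = 0.008; AUC 0.89) while the SNc
difference is not — with six subjects per arm a ~100 mm³ SNc effect against
a ~115 mm³ between-subject SD is underpowered, which is exactly the kind of
design question the simulator is for. Volumes per subject are in
`demo_out/volumes.csv` together with μ_ref, σ_ref and the threshold used;
`demo_out/manifest.json` records the config, package version, per-stage
wall-clock and output checksums.

The pipeline also runs on real data: point `data_dir` at a tree with
`subjects/<id>/series.nii.gz` (4D NM-MRI series), `atlases/{snc,lc}_atlas.nii.gz`,
`atlases/ref_roi.nii.gz`, and per-subject `standard_to_native.json`
transform chains (rigid/affine links; nonlinear warps are accepted as
precomputed chains, never fitted here). `--no-moco` bypasses motion
correction for degraded-input testing; `--k-snc/--k-lc/--dilation-iters`
expose the segmentation parameters.

## Layout

- `nmvol.image` — `VoxelImage`/`BinaryMask`/`ProbabilisticAtlas`, NIfTI-1
  I/O, single-pass resampling through composed transform chains.
- `nmvol.transforms` — rigid/affine world transforms, labelled chains, JSON
  serialization.
- `nmvol.registration` — rigid estimation, motion-corrected averaging,
  ROI mapping to native space.
- `nmvol.segmentation` — reference statistics, search regions, threshold
  segmentation, per-subject volumetry.
- `nmvol.stats` — Welch/ANCOVA/partial correlation/ROC and the cohort
  report.
- `nmvol.phantom` — phantom subjects, atlases, and cohort tables.
- `nmvol.pipeline` / `nmvol.cli` — configuration, manifest, and the
  `simulate` / `segment` / `stats` / `run-all` commands.

See `docs/methods.md` for the model, parameter defaults, numerical choices,
and known limitations.
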