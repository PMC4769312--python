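# neuropet

Quantitative multimodal PET/MR analysis for studies where regional
physiology must be extracted automatically from dynamic PET and
structural MR — including brains with focal lesions, where standard
spatial normalization fails.  The package covers the full chain a
tracer-kinetics group needs at desk scale:

- **CBF mapping from dynamic ¹⁵O-water PET.**  One-tissue model
  `dC_T/dt = K1·C_b − k2·C_T`, `C_ROI = C_T + Vb·C_b`, with grid-search
  correction of arterial delay and dispersion and a spatially constrained
  ridge estimator for voxel-wise maps; CBF = K1/E × 100 (E = 0.85).
- **Relative perfusion from early-phase ¹⁸F-FDDNP PET.**  Simplified
  reference tissue model `C_T = R_I·C_R + (k2 − R_I·θ)(C_R ⊗ e^{−θt})`,
  θ = k2/(1+BP), solved by the basis-function method over 100 log-spaced
  θ values (0.00636–1 min⁻¹), plus the normalized early-summed image R_P.
- **Registration.**  Mutual-information rigid alignment of summed PET to
  structural images, and greedy symmetric diffeomorphic normalization
  with a localized cross-correlation metric, exact inverses, and
  constrained cost-function masking that treats focal lesions as missing
  data.
- **Atlas ROI analysis and agreement statistics.**  Nearest-neighbor
  label propagation through concatenated transforms, regional
  mean/SD/CV, gray/white ratios, Bland–Altman limits of agreement.
- **A digital brain phantom** that synthesizes every input the pipeline
  consumes (labelled geometry, arterial input, noisy dynamic frames for
  both tracers, smooth invertible deformations, lesions), so the entire
  workflow is testable without patient data.

## Worked example

Generate a complete synthetic study (template, lesioned subject MR,
dynamic water and FDDNP scans on a rigidly shifted grid, measured blood
curve) and run the full workflow:

```python
from neuropet.pipeline import WorkflowConfig, run_workflow, write_phantom_bundle

bundle = write_phantom_bundle("study/", seed=0, noise_percent=5.0)
result = run_workflow(WorkflowConfig.from_yaml(bundle["config"]))
print(f"gray/white CBF ratio: {result['gray_white_ratio']:.3f}")
print(result["stats"]["CBF"].table.to_string(index=False))
```

```
gray/white CBF ratio: 1.587
region    n      mean       sd       units
   FRT 1429 32.163188 2.960048 mL/100g/min
   PAR 1421 31.590793 4.549834 mL/100g/min
   OCC  848 31.377708 5.209845 mL/100g/min
  TEMP 1327 32.062504 3.551068 mL/100g/min
   CAU  109 31.884288 1.555910 mL/100g/min
  THAL  134 31.237317 2.347532 mL/100g/min
   CGM  492 37.503685 1.535562 mL/100g/min
   SWM 3823 19.986559 1.209563 mL/100g/min
  WBGM    6 31.719300 0.376179 mL/100g/min
```

The phantom generates gray matter at 33, cerebellar gray at 38.4 and
white matter at 20 mL/100 g/min.  The recovered regional means land
within a few percent of those values — the residual underestimation of
gray regions comes from boundary voxels mislabeled by atlas propagation —
and the whole-brain gray/white ratio of 1.59 sits within 5 % of the
generating 1.65.  The output directory also contains the K1/k2/Vb/CBF and
nCBF maps, the SRTM R_I/BP maps and R_P image, the deformation fields,
per-region TSV tables, Bland–Altman reports of R_I and R_P against nCBF,
and a machine-readable log of every transform and parameter applied.

The same stages are scriptable from the shell:

```bash
neuropet phantom study/ --seed 0
neuropet run study/config.yaml
neuropet register moving.nii.gz fixed.nii.gz --mode syn --out warp.nii.gz
neuropet fit-water dyn.nii.gz timing.tsv blood.tsv --out CBF.nii.gz
neuropet fit-srtm dyn.nii.gz timing.tsv labels.nii.gz --out RI.nii.gz
```

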