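# strokeflow

4D modelling of ischemic stroke lesion evolution from longitudinal MR surfaces.

Acute stroke imaging yields a handful of snapshots: a diffusion (DWI) lesion —
conventionally read as the infarct core — nested inside a larger perfusion (MTT)
lesion — tissue at risk — at a few timepoints days apart, and a final T2 lesion
a month or more later. `strokeflow` turns those snapshots into a *continuous*,
patient-specific simulation of how the lesion boundary moved, so that expansion
and contraction can be localized in space and resolved in time (3-hourly), and
the moment the evolving lesion best matched the final damage can be identified.

## The model

Each lesion boundary is a closed triangulated surface. A surface `S` is
represented as a **current**: face centers `x_p` carrying area-weighted normals
`n_p`, compared through a Gaussian reproducing-kernel inner product

    <A, B>_W = Σ_ij exp(-|x_i^A - x_j^B|² / λ_W²) (n_i^A · n_j^B),

so no point correspondence between meshes is ever needed and geometry below the
scale λ_W is ignored. The evolution is a diffeomorphic flow `dχ_t/dt = v_t(χ_t)`
whose velocity field is a kernel convolution of momentum vectors `α_k(t)` at the
moving control points `x_k(t)` (Gaussian scale λ_V):

    v_t(x) = Σ_k exp(-|x_k(t) - x|² / λ_V²) α_k(t).

Fitting a time series `S_1 … S_n` minimizes, per inter-observation interval,

    J(α) = γ · E(α) + Σ_i dist_W²( χ_{t_i}(S_1), S_i ),

where `E` is the kinetic energy of the flow (regularity) and `dist_W` the
currents distance (fidelity). Gradient descent with backtracking line search runs
from zero momenta; the gradient is an exact adjoint sweep through the Euler steps
of the flow, preconditioned by the velocity-space kernel. Defaults: γ = 1e-4,
δt = 3 h, λ_W = 5 mm (with a coarse 35 mm first pass), λ_V = 30 % of the lesions'
bounding box.

On top of the fitted scenarios the package computes: signed per-face speeds
(cm/3h, positive = expansion); automatic extraction of highly contracting /
expanding areas (beyond mean ± SD of each subset); transport of those areas back
to the acute baseline and across modalities through the DWI→MTT correspondence
map φ; and time-resolved concordance with the final T2 lesion (Dice overlap and
symmetric surface distance at every 3 h step, with best-match times).

Because the original patient MRI data are not publicly deposited, the package
ships a first-class synthetic-lesion generator (`strokeflow.synthetic`) that
emulates the study conditions — nested solitary lesions, mismatch > 3 cm³,
acquisitions at ~5 h / ~5 d / ~10.5 d, anisotropic lobed growth and shrinkage,
a T2 surface crossed at a known time — with complete ground truth for every
downstream quantity.

## Worked example

```python
from strokeflow.synthetic import PatientParams, generate_patient
from strokeflow.regression import RegressionConfig
from strokeflow.pipeline import PatientRun, run_patient

patient = generate_patient(PatientParams(subdivisions=1), seed=0)
report = run_patient(PatientRun.from_patient(patient, RegressionConfig()))
print(round(report["dwi_fit"]["dice_t2"], 3), round(report["dwi_fit"]["dice_t3"], 3))
print(report["outcome"]["dwi"]["t_dice"], patient.truth["t2_cross_hours"])
```

prints

```
1.0 1.0
141.0 150.0
```

— the fitted DWI scenario reproduces the observed surfaces at the second and
third acquisitions (Dice 1.000 at 1 mm voxels), and the time at which the
evolving DWI lesion best matches the final T2 surface (141 h from onset) lands
within three grid steps of the generator's true crossing time (150 h) despite
0.3 mm delineation noise on every observed surface.

The cohort-level analysis lives in `analysis/` as numbered drivers:

```bash
python analysis/01_simulate_cohort.py   # 8 synthetic patients -> results/cohort
python analysis/02_run_pipeline.py      # fits + kinetics + outcome -> results/analysis
python analysis/03_kinetics_summary.py  # cohort mean-speed table + figure
python analysis/04_outcome_summary.py   # T2 concordance table (best-match times)
```

A `strokeflow` CLI (`simulate`, `fit`, `kinetics`, `outcome`, `run`, `report`)
exposes the same pipeline for on-disk data (NIfTI masks, PLY/VTK surfaces).

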