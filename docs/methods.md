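# Methods

## Problem setting

The package estimates a continuous spatiotemporal evolution of ischemic stroke
lesion boundaries from three time-indexed observations per modality (DWI and
MTT), plus a static final-outcome T2 surface. The deliverables per patient are:
a fitted evolution scenario per modality sampled every δt = 3 h; per-face signed
speeds and automatically extracted highly contracting/expanding areas, mapped
back to the acute baseline and across modalities; and Dice / symmetric-distance
concordance curves against the T2 surface with best-match times.

## Surfaces, masks, preprocessing

Lesion masks are NIfTI volumes; the emulated acquisition has 6 mm axial slabs
(with a 0.97 mm interslice gap folded into the slab thickness, i.e. slices are
treated as contiguous), which `z_subsample` splits into 6 subvoxels so the
foreground count and physical volume are conserved exactly. Surfaces are
extracted by marching cubes at level 0.5 in physical mm, followed by 2
iterations of Laplacian smoothing (factor 0.2). The smoothing removes voxel
staircase artifacts that the currents metric at λ_W ≥ 5 mm cannot see anyway but
that destabilize face normals. Every surface must be a closed, outward-oriented
2-manifold without degenerate faces; a validator enforces this everywhere.

## The currents metric

A surface is encoded by face barycenters carrying **area-weighted** normals
½(e₁×e₂). The test-space kernel is `exp(-|x-y|²/λ_W²)` — no ½ factor, and the
identical convention is used for the deformation kernel, so stated λ values mean
the same thing in both spaces. Area weighting (rather than unit normals) makes
the metric stable under retriangulation: subdividing faces changes inner
products by < 1 % once triangle diameters are well below λ_W (property-tested).
A `unit_normals` switch exists for comparison. Inner products are evaluated as
dense vectorized kernel sums — exact, no truncation — which is well within
budget at the mesh sizes used (hundreds to a few thousand faces).

## Flow model and regression

Deformation velocity fields are kernel convolutions of momenta attached to the
baseline face centers; control points advect with the flow, mesh vertices ride
along as passive tracers, so connectivity never changes and face identity is
preserved through time (this is what makes region transport and cross-modality
transfer trivial and exact). Integration is explicit Euler on the δt grid, the
discretization the momenta are estimated under; a 2nd-order midpoint integrator
exists for convergence checks. The inverse flow solves each backward step
`q_t = q_{t+1} − δt·v_t(q_t)` by fixed-point iteration (5 iterations), making it
the essentially exact inverse of the forward Euler map for stable flows. A
stability guard rejects any step that moves a point by more than λ_V.

The regression functional is `J = γ·E + Σ_i dist_W²(χ_{t_i}(S₁), S_i)` with
γ = 1e-4 multiplying the (numerically much larger) energy term. Its exact form
is a reconstruction — the reference formulation defers to an appendix that is
not part of the source text — chosen so that "trade-off between regularity and
fidelity" is meaningful at the stated γ. Momenta are optimized per
inter-observation interval, sequentially: interval *i* starts from the deformed
state at t_i, so the scenario is continuous in position by construction
("piecewise geodesic"); velocity continuity across knots is not enforced.

### Optimizer

Gradient descent with backtracking line search from zero momenta (fully
deterministic; the config seed only affects synthetic data). Two numerical
choices matter:

* **Adjoint gradient.** dJ/dα is computed by an exact reverse sweep through the
  Euler steps (control points, tracers, energy and fidelity terms), validated
  against central finite differences to < 1e-4 relative error in the tests.
* **RKHS preconditioning.** The descent direction is the gradient multiplied by
  the inverse kernel matrix per time step (ridge 1e-6), i.e. steepest descent in
  the velocity-space metric. The Euclidean gradient carries a kernel factor that
  makes the problem extremely ill-conditioned; preconditioning reduced the
  objective on identical problems by 2–3 orders of magnitude at the same
  iteration count.
* **Coarse-to-fine fidelity scale.** With λ_W = 5 mm, two surfaces separated by
  more than a few kernel widths (e.g. a 20 mm DWI sphere inside a 33 mm MTT
  sphere) do not attract: the cross term of the currents distance vanishes and
  descent collapses the source surface instead. Every fit therefore runs a
  coarse pass at λ_W = 35 mm (the model's own alternative scale; iteration cap
  one quarter of the budget, minimum 30) and warm-starts the λ_W fit from it.
  Disable with `lambda_w_coarse=None`.

Iteration cap 200 per interval and scale, stopping at a relative J decrease
below 1e-6. λ_V defaults to 30 % of the longest edge of the axis-aligned
bounding box of all observed lesion vertices; λ_W defaults to 5 mm with 35 mm
selectable (the choice rule by "observed shape regularity" is not specified in
the source, so it is exposed, not automated).

The correspondence map φ between DWI(t₁) and MTT(t₁) uses the same machinery
over a unit pseudo-time split into 10 Euler steps. The MTT scenario is fitted
from φ(S_DWI(t₁)) as its baseline, so DWI and MTT scenarios share face identity.

## Kinetics

Signed speed per face and step is |v| at the face center, signed by v·n̂ with
the outward unit normal, reported in cm/3h (internal mm/h × 0.3). Highly
contracting (expanding) areas at a chosen step — default the first — are faces
strictly beyond mean − SD of the contracting subset (mean + SD of the expanding
subset); statistics are per-subset, SD uses population (N) normalization to
match the thresholding convention of the worked examples. An empty subset yields
an empty flag set, not an error. Mapping flags to the baseline or across φ is by
face index, exact because connectivity is preserved.

## Outcome timing

Enclosed volumes are rasterized by a vertical-ray-parity voxelizer (1 mm
isotropic default, matching the preprocessed resolution) on a grid shared
between the evolving surface and the T2 surface; Dice is computed on voxel
counts. The symmetric distance averages exact point-to-triangle distances from
each surface's vertices to the other surface (vectorized all-pairs closest-point
computation, tested against an independent per-pair oracle to 1e-9). Best-match
times are the grid argmax of Dice and argmin of d_sym; ties break toward the
earliest time (first-attainment reading). The Dice curve need not reach 1 — a
front can merely cross the final boundary — and the test suite includes a
scenario constructed so max Dice < 1 to confirm the pipeline reports it
faithfully.

## Synthetic cohort

The generator emulates the study conditions: per patient one solitary DWI lesion
(icosphere, default r₀ = 20 mm) strictly inside one solitary MTT lesion
(r₀ = 28 mm; mismatch ≈ 58 cm³ ≫ 3 cm³), observed at t₁ = 5 h, t₂ = 120 ± 24 h,
t₃ = 252 ± 60 h (snapped to the 3 h grid), evolving with an expansion lobe and a
roughly antipodal contraction lobe (Gaussian lobes of 45° width). Default rates
(mm/h at the baseline surface): DWI base 0.012, lobe +0.030 / −0.020; MTT base
0.006, lobe +0.060 / −0.035 — MTT changes faster than DWI, and the DWI
contraction lobe emulates diffusion-reversal. These give lesion volumes of tens
of cm³ and boundary speeds of order 0.01 cm/3h, the scale of subacute lesion
evolution. Observation noise (default 0.3 mm, roughly manual-delineation
jitter at the preprocessed 1 mm resolution) is applied along vertex normals,
which keeps meshes closed.

In-family ("kernel") dynamics solve ridge-regularized kernel interpolation
(ridge 1e-2) for momenta reproducing the prescribed lobed radial speed field at
the baseline face centers, then flow forward with the package's own integrator;
the recorded truth (momenta, frames, achieved per-face speeds, lobe membership)
regenerates the emitted surfaces exactly before jitter, enabling exact-recovery
tests. The ridge is essential: the kernel matrix on densely sampled face centers
is near-singular, and an unregularized solve produces oscillating momenta and
unstable, jagged truth surfaces. The achieved speeds (recorded, mildly smoothed
by the ridge) are the ground truth, not the prescribed profile. An out-of-family
"radial" mode moves vertices radially at the lobed rate, outside the kernel-flow
family, to probe fit quality where the model can only approximate. The T2
surface is the true DWI frame at a configured crossing time (optionally
translated by `t2_offset_mm` to cap the attainable Dice below 1).

What the generator does *not* emulate: vascular-territory lesion shapes,
multi-component or merging/splitting lesions, anatomical constraints (sulci,
ventricles), tissue-parameter heterogeneity, and scanner/coregistration
artifacts beyond isotropic boundary jitter. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's assumptions,
not clinical validity on real MRI.

## Problem sizes and determinism

The test suite and the acceptance script run the cohort analyses on
subdivision-1 icospheres (80 faces, 42 vertices per lesion) with 4–8 patients,
and the cohort reproducibility check caps descent at 60 iterations; the analysis
drivers default to the same mesh resolution with the full iteration budget.
These sizes were chosen so a complete desk run finishes in minutes while leaving
every scientific condition of the generator unchanged; the mesh resolution and
iteration budget are stated in each driver's options. All computations are
deterministic given the master seed: cohort seeds derive from it, fitting has no
random element, and re-running a cohort reproduces summary tables bit for bit.

## Known limitations

* Sequential per-interval fitting cannot trade error between intervals the way
  a joint spacetime optimization could.
* The constant-in-time momenta of each fitted interval make each piece
  geodesic-like under the advected-kernel parameterization, not an exact LDDMM
  geodesic (no Hamiltonian momentum evolution, no adjoint shooting).
* Dice at 1 mm voxels saturates for near-perfect fits on decimeter-scale
  lesions; distinguishing fits beyond Dice ≈ 0.999 needs the symmetric distance.
* The voxelizer's ray-parity test assumes generic position; a deterministic
  sub-voxel ray offset avoids vertex/edge degeneracies on the meshes used but is
  not a formally robust geometric predicate.
* Multi-component lesions are rejected by design (single solitary lesion
  assumption), and image intensities play no role — only the boundary geometry.
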