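"""Synthetic stroke-lesion time series with full ground truth.

Emulates the study conditions the analysis assumes: per patient, one solitary DWI
lesion strictly inside one solitary MTT lesion at the first acquisition (~5 h from
onset, mismatch > 3 cm^3), re-imaged at ~5 d and ~10.5 d, plus a final-outcome T2
surface that the evolving DWI front crosses at a known time. Lesions start as
icospheres and evolve anisotropically: an expansion lobe and a contraction lobe
with configured rates, the MTT lesion changing faster than the DWI lesion.

Two dynamics families:

* "kernel" (default, in-family): momenta are solved so the kernel velocity field
  reproduces a prescribed lobed radial speed profile at the baseline face centers,
  then the surfaces are flowed forward with the package's own integrator. The
  recorded momenta regenerate the emitted surfaces exactly (before jitter), so the
  regression can be tested as exact recovery.
* "radial" (out-of-family): vertices move radially with the lobed speed profile,
  outside the kernel-flow family, to probe fit quality on dynamics the model can
  only approximate.

Observation noise is vertex jitter along vertex normals (keeps meshes closed at
small sd), emulating manual-delineation variability.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh

from strokeflow.flow import MomentaField, flow_forward
from strokeflow.kinetics import MM_PER_H_TO_CM_PER_3H
from strokeflow.surface_io import TriangleSurface, validate_surface, write_mask, write_surface

__all__ = [
    "SyntheticPatient",
    "PatientParams",
    "make_icosphere",
    "generate_patient",
    "generate_cohort",
    "truth_scenario",
    "radial_growth_scenario",
    "write_patient",
]


def make_icosphere(radius: float, subdivisions: int = 2, t_hours: float = 0.0) -> TriangleSurface:
    """Closed outward-oriented icosphere; area converges to 4 pi r^2 with subdivisions."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces), t_hours)


@dataclasses.dataclass
class PatientParams:
    """Generator configuration; defaults are the emulated study conditions.

    Radii in mm, rates in mm/h (at the baseline surface), angles in degrees,
    times in hours from onset.
    """

    dwi_r0: float = 20.0
    mtt_r0: float = 28.0
    t1_hours: float = 5.0
    t2_hours: float = 120.0          # ~5 d, jittered +-24 h in cohorts
    t3_hours: float = 252.0          # ~10.5 d, jittered +-60 h in cohorts
    dt_hours: float = 3.0
    subdivisions: int = 2
    lobe_sigma_deg: float = 45.0
    dwi_base_rate: float = 0.012     # slow overall DWI growth
    dwi_expand_rate: float = 0.030   # extra outward speed in the expansion lobe
    dwi_contract_rate: float = 0.020  # inward speed in the contraction lobe (DWI reversal)
    mtt_base_rate: float = 0.006
    mtt_expand_rate: float = 0.060   # MTT changes faster than DWI
    mtt_contract_rate: float = 0.035
    noise_sd: float = 0.3            # mm, along vertex normals
    t2_cross_hours: float = 150.0    # true time the DWI front matches the T2 surface
    t2_offset_mm: float = 0.0        # translate T2 to make max dice < 1 (0 = exact crossing)
    dynamics: str = "kernel"         # "kernel" (in-family) or "radial" (out-of-family)
    lambda_v: float | None = None    # kernel dynamics scale; default 30% of the MTT box


@dataclasses.dataclass
class SyntheticPatient:
    """One synthetic patient: observed surfaces plus the generating truth."""

    dwi_surfaces: list[TriangleSurface]
    mtt_surfaces: list[TriangleSurface]
    t2_surface: TriangleSurface
    truth: dict
    seed: int
    params: PatientParams

    @property
    def times_hours(self) -> np.ndarray:
        return np.array([s.t_hours for s in self.dwi_surfaces])

    @property
    def mismatch_cm3(self) -> float:
        return (self.mtt_surfaces[0].volume - self.dwi_surfaces[0].volume) / 1000.0


def _lobed_speed(directions: np.ndarray, u_expand, u_contract, params_prefix, p: PatientParams):
    """Signed radial speed profile (mm/h) per unit direction: base + expansion lobe
    - contraction lobe, each lobe a Gaussian in the angle to its axis."""
    base, expand, contract = params_prefix
    sigma = np.deg2rad(p.lobe_sigma_deg)
    th_e = np.arccos(np.clip(directions @ u_expand, -1, 1))
    th_c = np.arccos(np.clip(directions @ u_contract, -1, 1))
    return base + expand * np.exp(-((th_e / sigma) ** 2)) - contract * np.exp(-((th_c / sigma) ** 2))


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _solve_momenta(x0: np.ndarray, v_des: np.ndarray, lambda_v: float) -> np.ndarray:
    """Ridge-regularized kernel interpolation of the desired velocity field.

    The Gaussian kernel matrix on densely sampled face centers is severely
    ill-conditioned, so a plain solve produces huge oscillating momenta and an
    unstable flow; the ridge trades exact interpolation of the prescribed speeds
    for smooth momenta. Truth speeds recorded downstream are the achieved field,
    not the prescribed one.
    """
    from scipy.spatial.distance import cdist

    k = np.exp(-cdist(x0, x0, "sqeuclidean") / lambda_v**2)
    k[np.diag_indices_from(k)] += 1e-2
    return np.linalg.solve(k, v_des)


def _kernel_truth(surface: TriangleSurface, speed_fn, lambda_v, n_steps, dt, t0):
    """Solve momenta reproducing the desired speed field at t0, then flow."""
    x0 = surface.face_centers
    normals = surface.face_normals
    n_hat = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    center = surface.vertices.mean(axis=0)
    dirs = x0 - center
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    v_des = speed_fn(dirs)[:, None] * n_hat
    alpha = _solve_momenta(x0, v_des, lambda_v)
    momenta_t = np.broadcast_to(alpha, (n_steps,) + alpha.shape).copy()
    mom = MomentaField.from_momenta(x0, momenta_t, lambda_v, dt, t0_hours=t0)
    frames = flow_forward(surface.vertices, mom).point_trajectories
    # record the achieved (post-ridge) signed normal speed, not the prescribed one
    from scipy.spatial.distance import cdist as _cdist

    v_achieved = np.exp(-_cdist(x0, x0, "sqeuclidean") / lambda_v**2) @ alpha
    return mom, frames, np.einsum("ij,ij->i", v_achieved, n_hat)


def _radial_truth(surface: TriangleSurface, speed_fn, n_steps, dt):
    """Out-of-family dynamics: vertices march radially at the lobed speed."""
    center = surface.vertices.mean(axis=0)
    rel = surface.vertices - center
    r = np.linalg.norm(rel, axis=1, keepdims=True)
    dirs = rel / r
    rates = speed_fn(dirs)[:, None]
    frames = np.stack([center + dirs * (r + rates * dt * s) for s in range(n_steps + 1)])
    face_dirs = surface.face_centers - center
    face_dirs /= np.linalg.norm(face_dirs, axis=1, keepdims=True)
    return None, frames, speed_fn(face_dirs)


def generate_patient(params: PatientParams | None = None, seed: int = 0, **overrides) -> SyntheticPatient:
    """Generate one synthetic patient; identical seed and params give identical output."""
    p = dataclasses.replace(params or PatientParams(), **overrides)
    if p.mtt_r0 <= p.dwi_r0:
        raise ValueError("MTT lesion must enclose the DWI lesion (mtt_r0 > dwi_r0)")
    mismatch_cm3 = 4.0 / 3.0 * np.pi * (p.mtt_r0**3 - p.dwi_r0**3) / 1000.0
    if mismatch_cm3 <= 3.0:
        raise ValueError(f"MTT/DWI mismatch {mismatch_cm3:.2f} cm^3 must exceed 3 cm^3")
    rng = np.random.default_rng(seed)
    dt = p.dt_hours
    t1 = _snap(p.t1_hours, dt)
    t2 = _snap(p.t2_hours, dt)
    t3 = _snap(p.t3_hours, dt)
    if not t1 < t2 < t3:
        raise ValueError("acquisition times must be strictly increasing")
    lambda_v = p.lambda_v or 0.30 * (2.0 * p.mtt_r0)

    u_expand = rng.normal(size=3)
    u_expand /= np.linalg.norm(u_expand)
    # contraction lobe roughly antipodal, with a random tilt
    tilt = rng.normal(scale=0.3, size=3)
    u_contract = -u_expand + tilt
    u_contract /= np.linalg.norm(u_contract)

    n_steps = int(round((t3 - t1) / dt))
    s2 = int(round((t2 - t1) / dt))
    s_cross = int(round((_snap(p.t2_cross_hours, dt) - t1) / dt))
    if not 0 <= s_cross <= n_steps:
        raise ValueError("t2_cross_hours must lie within [t1, t3]")

    out = {}
    truth: dict = {
        "lambda_v": lambda_v,
        "dt_hours": dt,
        "times_hours": [t1, t2, t3],
        "u_expand": u_expand,
        "u_contract": u_contract,
        "dynamics": p.dynamics,
        "t2_cross_hours": t1 + s_cross * dt,
    }
    for name, r0, rates in (
        ("dwi", p.dwi_r0, (p.dwi_base_rate, p.dwi_expand_rate, p.dwi_contract_rate)),
        ("mtt", p.mtt_r0, (p.mtt_base_rate, p.mtt_expand_rate, p.mtt_contract_rate)),
    ):
        sphere = make_icosphere(r0, p.subdivisions, t_hours=t1)
        speed_fn = lambda dirs, rates=rates: _lobed_speed(dirs, u_expand, u_contract, rates, p)
        if p.dynamics == "kernel":
            mom, frames, face_speeds = _kernel_truth(sphere, speed_fn, lambda_v, n_steps, dt, t1)
        elif p.dynamics == "radial":
            mom, frames, face_speeds = _radial_truth(sphere, speed_fn, n_steps, dt)
        else:
            raise ValueError(f"unknown dynamics '{p.dynamics}'")
        clean = [
            sphere.with_vertices(frames[0], t_hours=t1),
            sphere.with_vertices(frames[s2], t_hours=t2),
            sphere.with_vertices(frames[-1], t_hours=t3),
        ]
        # lobe membership of baseline faces (within one lobe width of each axis)
        center = sphere.vertices.mean(axis=0)
        fdirs = sphere.face_centers - center
        fdirs /= np.linalg.norm(fdirs, axis=1, keepdims=True)
        sigma = np.deg2rad(p.lobe_sigma_deg)
        truth[name] = {
            "momenta": mom,
            "frames": frames,
            "clean_surfaces": clean,
            "face_speeds_cm_per_3h": face_speeds * MM_PER_H_TO_CM_PER_3H,
            "expansion_lobe": np.arccos(np.clip(fdirs @ u_expand, -1, 1)) < sigma,
            "contraction_lobe": np.arccos(np.clip(fdirs @ u_contract, -1, 1)) < sigma,
        }
        observed = []
        for s in clean:
            verts = s.vertices
            if p.noise_sd > 0:
                mesh = s.to_trimesh()
                vn = np.asarray(mesh.vertex_normals)
                verts = verts + rng.normal(scale=p.noise_sd, size=(verts.shape[0], 1)) * vn
            observed.append(s.with_vertices(verts))
        out[name] = observed

    dwi_frames = truth["dwi"]["frames"]
    t2_surf = TriangleSurface(dwi_frames[s_cross].copy(), out["dwi"][0].faces, t_hours=720.0)
    if p.t2_offset_mm != 0.0:
        shift = rng.normal(size=3)
        shift *= p.t2_offset_mm / np.linalg.norm(shift)
        t2_surf = t2_surf.with_vertices(t2_surf.vertices + shift)
    patient = SyntheticPatient(
        dwi_surfaces=out["dwi"],
        mtt_surfaces=out["mtt"],
        t2_surface=t2_surf,
        truth=truth,
        seed=seed,
        params=p,
    )
    for s in patient.dwi_surfaces + patient.mtt_surfaces + [patient.t2_surface]:
        validate_surface(s)
    if patient.mismatch_cm3 <= 3.0:
        raise ValueError("generated mismatch fell below 3 cm^3")
    return patient


def radial_growth_scenario(
    rate_mm_per_h: float = 1.0,
    radius: float = 10.0,
    n_steps: int = 5,
    *,
    subdivisions: int = 2,
    lambda_v: float = 30.0,
    dt_hours: float = 1.0,
    flip_orientation: bool = False,
):
    """Ball growing radially at a known constant rate r(t) = r0 + rate * t.

    Momenta are re-solved at every step for the current control-point positions so
    the kernel velocity field keeps the prescribed radial speed as the sphere
    grows — the analytic oracle for signed-speed checks.
    """
    from scipy.spatial.distance import cdist

    from strokeflow.regression import EvolutionScenario

    sphere = make_icosphere(radius, subdivisions)
    if flip_orientation:
        sphere = TriangleSurface(sphere.vertices, sphere.faces[:, ::-1])
    x = sphere.face_centers.copy()
    momenta, ctrl = [], [x.copy()]
    for _ in range(n_steps):
        dirs = x / np.linalg.norm(x, axis=1, keepdims=True)
        alpha = _solve_momenta(x, rate_mm_per_h * dirs, lambda_v)
        k = np.exp(-cdist(x, x, "sqeuclidean") / lambda_v**2)
        x = x + dt_hours * (k @ alpha)
        momenta.append(alpha)
        ctrl.append(x.copy())
    mom = MomentaField(np.stack(momenta), np.stack(ctrl), lambda_v, dt_hours)
    frames = flow_forward(sphere.vertices, mom).point_trajectories
    surfaces = [sphere.with_vertices(f, t_hours=i * dt_hours) for i, f in enumerate(frames)]
    return EvolutionScenario(
        baseline=sphere, momenta=mom, surfaces_t=surfaces,
        obs_times_hours=np.array([0.0, n_steps * dt_hours]),
    )


def truth_scenario(patient: SyntheticPatient, modality: str = "dwi"):
    """Package the generator's true frames as an EvolutionScenario (kernel dynamics only).

    Gives downstream analyses (kinetics, outcome timing) a ground-truth scenario to
    run on, independent of any fitting.
    """
    from strokeflow.regression import EvolutionScenario

    tr = patient.truth[modality]
    mom = tr["momenta"]
    if mom is None:
        raise ValueError("truth momenta unavailable for out-of-family (radial) dynamics")
    base = tr["clean_surfaces"][0]
    surfaces_t = [
        base.with_vertices(f, t_hours=mom.t0_hours + i * mom.dt_hours)
        for i, f in enumerate(tr["frames"])
    ]
    return EvolutionScenario(
        baseline=base,
        momenta=mom,
        surfaces_t=surfaces_t,
        obs_times_hours=np.array(patient.truth["times_hours"], dtype=float),
        fit_info={"truth": True},
    )


def generate_cohort(n: int, seed: int = 0, params: PatientParams | None = None, *, jitter: bool = True) -> list[SyntheticPatient]:
    """Generate n patients; per-patient seeds and parameter jitter derive
    deterministically from the master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = params or PatientParams()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    patients = []
    for i in range(n):
        prng = np.random.default_rng(child_seeds[i])
        over = {}
        if jitter:
            dwi_r0 = float(prng.uniform(16.0, 24.0))
            t3_hours = base.t3_hours + float(prng.uniform(-60.0, 60.0))
            over = {
                "dwi_r0": dwi_r0,
                "mtt_r0": dwi_r0 + float(prng.uniform(6.0, 10.0)),
                "t2_hours": base.t2_hours + float(prng.uniform(-24.0, 24.0)),
                "t3_hours": t3_hours,
                "t2_cross_hours": float(prng.uniform(60.0, t3_hours - 12.0)),
                "dwi_expand_rate": base.dwi_expand_rate * float(prng.uniform(0.7, 1.3)),
                "mtt_expand_rate": base.mtt_expand_rate * float(prng.uniform(0.7, 1.3)),
                "dwi_contract_rate": base.dwi_contract_rate * float(prng.uniform(0.7, 1.3)),
                "mtt_contract_rate": base.mtt_contract_rate * float(prng.uniform(0.7, 1.3)),
            }
        patients.append(generate_patient(base, seed=int(child_seeds[i]), **over))
    return patients


def write_patient(patient: SyntheticPatient, outdir: str | Path, *, mask_spacing: float = 1.0) -> None:
    """Write a patient to disk: PLY + VTK surfaces, NIfTI masks, truth summary JSON."""
    from strokeflow.outcome import voxelize

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, surfaces in (("dwi", patient.dwi_surfaces), ("mtt", patient.mtt_surfaces)):
        for i, s in enumerate(surfaces, start=1):
            write_surface(s, outdir / f"{name}_t{i}.ply")
            write_surface(s, outdir / f"{name}_t{i}.vtk")
            write_mask(voxelize(s, mask_spacing), outdir / f"{name}_t{i}.nii.gz")
    write_surface(patient.t2_surface, outdir / "t2.ply")
    write_mask(voxelize(patient.t2_surface, mask_spacing), outdir / "t2.nii.gz")
    summary = {
        "seed": patient.seed,
        "times_hours": [float(t) for t in patient.times_hours],
        "t2_cross_hours": float(patient.truth["t2_cross_hours"]),
        "mismatch_cm3": float(patient.mismatch_cm3),
        "dynamics": patient.truth["dynamics"],
        "lambda_v": float(patient.truth["lambda_v"]),
    }
    (outdir / "truth.json").write_text(json.dumps(summary, indent=2))
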