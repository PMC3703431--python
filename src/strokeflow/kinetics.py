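"""Contraction/expansion kinetics of an estimated lesion evolution scenario.

Per face and per time step, the signed speed is the velocity magnitude at the face
center signed by the direction relative to the outward surface normal: positive =
outward motion (expansion), negative = inward motion (contraction). Speeds are
reported in cm per 3 h, the natural unit of a 3-hourly evolution scenario.

Highly contracting (resp. expanding) areas are flagged automatically: within the
contracting (resp. expanding) face subset at a chosen step, faces whose speed lies
strictly beyond mean - SD (resp. mean + SD) of that subset. Because the fitted flow
advects a fixed mesh, face identity is preserved through time and across the
DWI -> MTT correspondence map, so flagged areas can be mapped back to the baseline
shape ("lighting up" the upcoming changes on the acute lesion) and transferred
between modalities without any point matching.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from strokeflow.flow import velocity_at
from strokeflow.regression import CorrespondenceMap, EvolutionScenario

__all__ = [
    "SpeedField",
    "RegionLabels",
    "signed_speed",
    "extract_regions",
    "map_regions_to_baseline",
    "transfer_dwi_to_mtt",
    "mean_speed_curves",
]

MM_PER_H_TO_CM_PER_3H = 0.3  # mm/h * 3 h / (10 mm/cm)


@dataclasses.dataclass
class SpeedField:
    """Per-face signed speeds (cm/3h) at every Euler step of a scenario; shape (S, M)."""

    speeds: np.ndarray
    times_hours: np.ndarray

    def __post_init__(self):
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.speeds.ndim != 2:
            raise ValueError("speeds must be (S, M)")
        if not np.all(np.isfinite(self.speeds)):
            raise ValueError("speeds contain non-finite values")


@dataclasses.dataclass
class RegionLabels:
    """Boolean per-face flags for highly contracting / expanding areas at one step."""

    high_contraction: np.ndarray
    high_expansion: np.ndarray
    at_step: int

    def __post_init__(self):
        self.high_contraction = np.asarray(self.high_contraction, dtype=bool)
        self.high_expansion = np.asarray(self.high_expansion, dtype=bool)
        if self.high_contraction.shape != self.high_expansion.shape:
            raise ValueError("flag arrays must have equal shape")
        if np.any(self.high_contraction & self.high_expansion):
            raise ValueError("a face cannot be both highly contracting and highly expanding")


def signed_speed(scn: EvolutionScenario) -> SpeedField:
    """Signed speed per face per step: |v| at the face center, signed by v . n_outward."""
    mom = scn.momenta
    out = np.empty((mom.n_steps, scn.baseline.n_faces))
    for step in range(mom.n_steps):
        surf = scn.surfaces_t[step]
        normals = surf.face_normals
        areas = np.linalg.norm(normals, axis=1)
        if np.any(areas < 1e-12):
            raise ValueError(f"degenerate faces at step {step}")
        v = velocity_at(surf.face_centers, step, mom)  # mm/h
        speed = np.linalg.norm(v, axis=1)
        sign = np.sign(np.einsum("ij,ij->i", v, normals / areas[:, None]))
        out[step] = speed * sign * MM_PER_H_TO_CM_PER_3H
    return SpeedField(speeds=out, times_hours=mom.times_hours[:-1])


def extract_regions(sp: SpeedField, at_step: int = 0, *, ddof: int = 0) -> RegionLabels:
    """Flag highly contracting/expanding faces at one step.

    Mean and SD are computed separately over the contracting (speed < 0) and
    expanding (speed > 0) subsets; a face is flagged when strictly beyond
    mean - SD (contraction) or mean + SD (expansion). An empty subset yields an
    empty flag set. SD uses population normalization by default.
    """
    if not 0 <= at_step < sp.speeds.shape[0]:
        raise IndexError(f"step {at_step} out of range")
    s = sp.speeds[at_step]
    contracting = s < 0
    expanding = s > 0
    high_c = np.zeros_like(contracting)
    high_e = np.zeros_like(expanding)
    if contracting.any():
        mu, sd = s[contracting].mean(), s[contracting].std(ddof=ddof)
        high_c = contracting & (s < mu - sd)
    if expanding.any():
        mu, sd = s[expanding].mean(), s[expanding].std(ddof=ddof)
        high_e = expanding & (s > mu + sd)
    return RegionLabels(high_contraction=high_c, high_expansion=high_e, at_step=at_step)


def map_regions_to_baseline(scn: EvolutionScenario, labels: RegionLabels) -> RegionLabels:
    """Transport flags from any step back onto the baseline mesh (inverse evolution).

    The fitted flow preserves connectivity, so the inverse evolution function acts
    on labels as the identity on face indices; the source step is retained so a
    sequence of mapped label sets reproduces the "lighting up" rendering.
    """
    if labels.high_contraction.shape[0] != scn.baseline.n_faces:
        raise ValueError("label set does not match the scenario's face count")
    return RegionLabels(
        high_contraction=labels.high_contraction.copy(),
        high_expansion=labels.high_expansion.copy(),
        at_step=labels.at_step,
    )


def transfer_dwi_to_mtt(phi: CorrespondenceMap, labels: RegionLabels) -> RegionLabels:
    """Carry DWI-baseline flags onto the MTT baseline through phi.

    The MTT scenario is built on phi(S_DWI(t1)), which shares the DWI baseline's
    connectivity, so the transfer is by face identity after checking shapes.
    """
    if labels.high_contraction.shape[0] != phi.source.n_faces:
        raise ValueError("labels do not match phi's source surface")
    if phi.deformed_source.n_faces != phi.source.n_faces:
        raise ValueError("correspondence map does not preserve connectivity")
    return RegionLabels(
        high_contraction=labels.high_contraction.copy(),
        high_expansion=labels.high_expansion.copy(),
        at_step=labels.at_step,
    )


def mean_speed_curves(scn: EvolutionScenario, labels: RegionLabels) -> pd.DataFrame:
    """Mean signed speed (cm/3h) of the flagged face sets at every step.

    Returns a DataFrame with columns (time_hours, mean_speed_contracting,
    mean_speed_expanding); an empty flag set yields a NaN column with a warning.
    """
    sp = signed_speed(scn)
    rows = {"time_hours": sp.times_hours}
    for name, flags in (
        ("mean_speed_contracting", labels.high_contraction),
        ("mean_speed_expanding", labels.high_expansion),
    ):
        if flags.any():
            rows[name] = sp.speeds[:, flags].mean(axis=1)
        else:
            warnings.warn(f"no faces flagged for {name}; column is NaN", stacklevel=2)
            rows[name] = np.full(sp.speeds.shape[0], np.nan)
    return pd.DataFrame(rows)
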