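"""Per-patient and cohort orchestration of the full 4D lesion analysis.

The per-patient sequence mirrors the analysis protocol: (1) fit the DWI evolution
scenario from its three time-indexed surfaces; (2) estimate the correspondence map
phi from DWI(t1) to MTT(t1); (3) fit the MTT scenario starting from phi(DWI(t1)) so
face identity links the two modalities; (4) kinetics — signed speeds, automatic
extraction of highly contracting/expanding areas on the DWI baseline, transfer to
MTT, mean-speed curves; (5) time-resolved concordance of both scenarios with the
final T2 surface.

`run_patient`/`run_cohort` are the library interface; the click CLI
(`strokeflow simulate|fit|kinetics|outcome|run|report`) is a thin shell over them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from strokeflow.kinetics import (
    extract_regions,
    map_regions_to_baseline,
    mean_speed_curves,
    signed_speed,
    transfer_dwi_to_mtt,
)
from strokeflow.outcome import concordance_curves, dice_index, voxelize
from strokeflow.regression import (
    EvolutionScenario,
    RegressionConfig,
    fit_pairwise,
    fit_timeseries,
    sample_surface,
)
from strokeflow.surface_io import TriangleSurface, read_surface, write_surface
from strokeflow.synthetic import PatientParams, SyntheticPatient, generate_cohort, write_patient

__all__ = ["PatientRun", "run_patient", "run_cohort", "fit_dice", "cli"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PatientRun:
    """Inputs of one patient analysis: 3 surfaces per modality, optional T2, config."""

    dwi_surfaces: list[TriangleSurface]
    mtt_surfaces: list[TriangleSurface]
    t2_surface: TriangleSurface | None
    config: RegressionConfig = dataclasses.field(default_factory=RegressionConfig)
    patient_id: str = "patient"

    def __post_init__(self):
        for name, surfaces in (("DWI", self.dwi_surfaces), ("MTT", self.mtt_surfaces)):
            if len(surfaces) != 3:
                raise ValueError(f"{name} needs exactly 3 timepoints, got {len(surfaces)}")
            times = [s.t_hours for s in surfaces]
            if not all(a < b for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} acquisition times must be strictly increasing")

    @classmethod
    def from_patient(cls, patient: SyntheticPatient, config: RegressionConfig | None = None,
                     patient_id: str = "patient") -> "PatientRun":
        return cls(
            dwi_surfaces=list(patient.dwi_surfaces),
            mtt_surfaces=list(patient.mtt_surfaces),
            t2_surface=patient.t2_surface,
            config=config or RegressionConfig(),
            patient_id=patient_id,
        )


def fit_dice(scn: EvolutionScenario, observed: TriangleSurface, spacing: float = 1.0) -> float:
    """Dice between the estimated surface at an observation time and the observed one."""
    est = sample_surface(scn, observed.t_hours)
    pts = np.vstack([est.vertices, observed.vertices])
    origin = pts.min(axis=0) - spacing
    shape = tuple(int(np.ceil((pts.max(axis=0)[k] - origin[k]) / spacing)) + 2 for k in range(3))
    return dice_index(
        voxelize(est, spacing, origin=origin, shape=shape),
        voxelize(observed, spacing, origin=origin, shape=shape),
    )


def run_patient(run: PatientRun, outdir: str | Path | None = None) -> dict:
    """Execute the full per-patient analysis; returns the report dict.

    Any stage failure raises with the stage name; outputs written so far remain.
    """
    cfg = run.config
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"patient_id": run.patient_id, "config": dataclasses.asdict(cfg)}

    stage = "fit_dwi_scenario"
    try:
        dwi_scn = fit_timeseries(run.dwi_surfaces, cfg)
        report["dwi_fit"] = {
            "lambda_v": dwi_scn.fit_info["lambda_v"],
            "dice_t2": fit_dice(dwi_scn, run.dwi_surfaces[1]),
            "dice_t3": fit_dice(dwi_scn, run.dwi_surfaces[2]),
            "intervals": dwi_scn.fit_info["intervals"],
        }

        stage = "fit_correspondence_phi"
        phi = fit_pairwise(run.dwi_surfaces[0], run.mtt_surfaces[0], cfg)
        pts = np.vstack([phi.deformed_source.vertices, run.mtt_surfaces[0].vertices])
        origin = pts.min(axis=0) - 1.0
        shape = tuple(int(np.ceil((pts.max(axis=0)[k] - origin[k]) / 1.0)) + 2 for k in range(3))
        report["phi_fit"] = {
            "lambda_v": phi.fit_info["lambda_v"],
            "dice": dice_index(
                voxelize(phi.deformed_source, 1.0, origin=origin, shape=shape),
                voxelize(run.mtt_surfaces[0], 1.0, origin=origin, shape=shape),
            ),
            "iterations": phi.fit_info["iterations"],
        }

        stage = "fit_mtt_scenario"
        mtt_baseline = phi.deformed_source.with_vertices(
            phi.deformed_source.vertices, t_hours=run.mtt_surfaces[0].t_hours
        )
        mtt_scn = fit_timeseries([mtt_baseline] + run.mtt_surfaces[1:], cfg)
        report["mtt_fit"] = {
            "lambda_v": mtt_scn.fit_info["lambda_v"],
            "dice_t2": fit_dice(mtt_scn, run.mtt_surfaces[1]),
            "dice_t3": fit_dice(mtt_scn, run.mtt_surfaces[2]),
            "intervals": mtt_scn.fit_info["intervals"],
        }

        stage = "kinetics"
        dwi_speed = signed_speed(dwi_scn)
        mtt_speed = signed_speed(mtt_scn)
        labels = extract_regions(dwi_speed, at_step=0)
        labels_base = map_regions_to_baseline(dwi_scn, labels)
        labels_mtt = transfer_dwi_to_mtt(phi, labels_base)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dwi_curves = mean_speed_curves(dwi_scn, labels_base)
            mtt_curves = mean_speed_curves(mtt_scn, labels_mtt)
        def _mean(col):
            col = np.asarray(col, dtype=float)
            return float(np.nanmean(col)) if np.isfinite(col).any() else float("nan")

        report["kinetics"] = {
            "n_high_contraction": int(labels.high_contraction.sum()),
            "n_high_expansion": int(labels.high_expansion.sum()),
            "dwi_mean_expansion_speed": _mean(dwi_curves["mean_speed_expanding"]),
            "mtt_mean_expansion_speed": _mean(mtt_curves["mean_speed_expanding"]),
            "dwi_mean_contraction_speed": _mean(dwi_curves["mean_speed_contracting"]),
            "mtt_mean_contraction_speed": _mean(mtt_curves["mean_speed_contracting"]),
        }
        if out is not None:
            dwi_curves.to_csv(out / "dwi_mean_speed_curves.csv", index=False)
            mtt_curves.to_csv(out / "mtt_mean_speed_curves.csv", index=False)
            write_surface(
                dwi_scn.baseline, out / "dwi_baseline_labels.vtk",
                face_scalars={
                    "signed_speed_cm_per_3h": dwi_speed.speeds[0],
                    "high_expansion": labels_base.high_expansion.astype(float),
                    "high_contraction": labels_base.high_contraction.astype(float),
                },
            )
            write_surface(
                mtt_scn.baseline, out / "mtt_baseline_labels.vtk",
                face_scalars={
                    "signed_speed_cm_per_3h": mtt_speed.speeds[0],
                    "high_expansion": labels_mtt.high_expansion.astype(float),
                    "high_contraction": labels_mtt.high_contraction.astype(float),
                },
            )

        stage = "outcome_timing"
        if run.t2_surface is None:
            warnings.warn("no T2 surface provided; outcome stage skipped", stacklevel=2)
            report["outcome"] = None
        else:
            report["outcome"] = {}
            for name, scn in (("dwi", dwi_scn), ("mtt", mtt_scn)):
                curves = concordance_curves(scn, run.t2_surface)
                report["outcome"][name] = curves.summary()
                if out is not None:
                    pd.DataFrame(
                        {"time_hours": curves.times_hours, "dice": curves.dice_t, "dsym_mm": curves.dsym_t}
                    ).to_csv(out / f"{name}_concordance.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"patient {run.patient_id} failed at stage '{stage}': {exc}") from exc

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_cohort(
    patients: list[SyntheticPatient] | list[PatientRun],
    config: RegressionConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """Analyse a cohort; returns per-patient reports and a cohort summary table.

    Failed patients are recorded and the rest complete; an empty list is an error.
    """
    if len(patients) == 0:
        raise ValueError("empty patient list")
    config = config or RegressionConfig()
    reports, rows = [], []
    for i, patient in enumerate(patients):
        pid = f"patient_{i:02d}"
        run = (
            patient
            if isinstance(patient, PatientRun)
            else PatientRun.from_patient(patient, config, patient_id=pid)
        )
        p_out = Path(outdir) / pid if outdir is not None else None
        try:
            report = run_patient(run, p_out)
        except RuntimeError as exc:
            logger.error("%s", exc)
            reports.append({"patient_id": pid, "error": str(exc)})
            continue
        reports.append(report)
        row = {
            "patient_id": pid,
            "dwi_dice_t2": report["dwi_fit"]["dice_t2"],
            "dwi_dice_t3": report["dwi_fit"]["dice_t3"],
            "phi_dice": report["phi_fit"]["dice"],
            "mtt_dice_t2": report["mtt_fit"]["dice_t2"],
            "mtt_dice_t3": report["mtt_fit"]["dice_t3"],
            **{f"kin_{k}": v for k, v in report["kinetics"].items()},
        }
        if report.get("outcome"):
            for name in ("dwi", "mtt"):
                for k, v in report["outcome"][name].items():
                    row[f"{name}_{k}"] = v
        rows.append(row)
    summary = pd.DataFrame(rows)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(outdir) / "cohort_summary.csv", index=False)
    return reports, summary


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

import click


def _load_config(path: str | None) -> RegressionConfig:
    if path is None:
        return RegressionConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RegressionConfig(**data.get("regression", data))


def _load_patient_dir(d: Path) -> PatientRun:
    truth = json.loads((d / "truth.json").read_text())
    times = truth["times_hours"]
    dwi = [read_surface(d / f"dwi_t{i}.ply", t_hours=times[i - 1])[0] for i in (1, 2, 3)]
    mtt = [read_surface(d / f"mtt_t{i}.ply", t_hours=times[i - 1])[0] for i in (1, 2, 3)]
    t2_path = d / "t2.ply"
    t2 = read_surface(t2_path, t_hours=720.0)[0] if t2_path.exists() else None
    return PatientRun(dwi, mtt, t2, patient_id=d.name)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="log optimizer iterations")
def cli(verbose):
    """4D currents-based analysis of stroke lesion evolution."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--n", default=8, show_default=True, help="number of synthetic patients")
@click.option("--seed", default=0, show_default=True)
@click.option("--subdivisions", default=2, show_default=True)
@click.option("--out", required=True, type=click.Path())
def simulate(n, seed, subdivisions, out):
    """Generate a synthetic cohort (surfaces, masks, truth records)."""
    patients = generate_cohort(n, seed, PatientParams(subdivisions=subdivisions))
    for i, p in enumerate(patients):
        write_patient(p, Path(out) / f"patient_{i:02d}")
    click.echo(f"wrote {n} patients to {out}")


@cli.command()
@click.option("--patient-dir", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def run(patient_dir, config_path, out):
    """Full per-patient pipeline: fit both scenarios, kinetics, outcome timing."""
    p_run = _load_patient_dir(Path(patient_dir))
    p_run.config = _load_config(config_path)
    report = run_patient(p_run, out)
    click.echo(json.dumps({k: report[k] for k in ("dwi_fit", "phi_fit", "mtt_fit")},
                          indent=2, default=float))


@cli.command()
@click.option("--patient-dir", required=True, type=click.Path(exists=True))
@click.option("--modality", type=click.Choice(["dwi", "mtt"]), default="dwi", show_default=True)
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def fit(patient_dir, modality, config_path, out):
    """Fit one modality's evolution scenario and save momenta + deformed meshes."""
    p_run = _load_patient_dir(Path(patient_dir))
    cfg = _load_config(config_path)
    surfaces = p_run.dwi_surfaces if modality == "dwi" else p_run.mtt_surfaces
    scn = fit_timeseries(surfaces, cfg)
    outp = Path(out)
    outp.mkdir(parents=True, exist_ok=True)
    mom = scn.momenta
    s, n, _ = mom.momenta_t.shape
    table = pd.DataFrame({
        "step": np.repeat(np.arange(s), n),
        "control_point": np.tile(np.arange(n), s),
        "ax": mom.momenta_t[:, :, 0].ravel(),
        "ay": mom.momenta_t[:, :, 1].ravel(),
        "az": mom.momenta_t[:, :, 2].ravel(),
    })
    table.to_csv(outp / f"{modality}_momenta.csv", index=False)
    (outp / f"{modality}_momenta.json").write_text(json.dumps({
        "lambda_v": mom.lambda_v, "lambda_w": cfg.lambda_w, "dt_hours": mom.dt_hours,
        "t0_hours": mom.t0_hours, "n_steps": s, "n_control_points": n,
        "obs_times_hours": [float(t) for t in scn.obs_times_hours],
    }, indent=2))
    for i, t in enumerate(scn.obs_times_hours):
        write_surface(sample_surface(scn, t), outp / f"{modality}_estimated_t{i + 1}.ply")
    click.echo(f"fitted {modality} scenario: J per interval "
               f"{[iv['J'] for iv in scn.fit_info['intervals']]}")


@cli.command()
@click.option("--patient-dir", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def kinetics(patient_dir, config_path, out):
    """Speeds, high-contraction/expansion areas and mean-speed curves."""
    p_run = _load_patient_dir(Path(patient_dir))
    p_run.config = _load_config(config_path)
    report = run_patient(p_run, out)
    click.echo(json.dumps(report["kinetics"], indent=2, default=float))


@cli.command()
@click.option("--patient-dir", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def outcome(patient_dir, config_path, out):
    """Time-resolved concordance with the final T2 lesion."""
    p_run = _load_patient_dir(Path(patient_dir))
    p_run.config = _load_config(config_path)
    report = run_patient(p_run, out)
    click.echo(json.dumps(report["outcome"], indent=2, default=float))


@cli.command()
@click.option("--cohort-dir", required=True, type=click.Path(exists=True),
              help="directory of per-patient output directories (run results)")
def report(cohort_dir):
    """Aggregate per-patient reports into a cohort summary table."""
    rows = []
    for rep_path in sorted(Path(cohort_dir).glob("*/report.json")):
        rep = json.loads(rep_path.read_text())
        row = {"patient_id": rep["patient_id"],
               "dwi_dice_t2": rep["dwi_fit"]["dice_t2"], "dwi_dice_t3": rep["dwi_fit"]["dice_t3"],
               "mtt_dice_t2": rep["mtt_fit"]["dice_t2"], "mtt_dice_t3": rep["mtt_fit"]["dice_t3"]}
        if rep.get("outcome"):
            row.update({f"{m}_{k}": v for m in ("dwi", "mtt") for k, v in rep["outcome"][m].items()})
        rows.append(row)
    if not rows:
        raise click.ClickException(f"no report.json files under {cohort_dir}")
    df = pd.DataFrame(rows)
    df.to_csv(Path(cohort_dir) / "cohort_summary.csv", index=False)
    click.echo(df.to_string(index=False))


if __name__ == "__main__":
    cli()
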