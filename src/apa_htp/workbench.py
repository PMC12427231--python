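"""End-to-end orchestration: reference fixture generation, run configuration,
and the full pipeline (fields -> threshold sweep -> optimizers -> SAR metrics
-> thermal solve -> reports).

The reference fixture is a deterministic desk-scale recreation of a layered
cylindrical neck phantom with an 8-element ring at 434 MHz and a 6 mm
spherical tumor at (-18, -18, -15) mm, with a 18 mm transition radius.  The
non-tumor layer radii and tissue property values are fixture choices (typical
published tissue data at 434 MHz), shipped in the default tissue table.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .apa import PowerMask, StoppingConfig, run_apa
from .bioheat import BoundaryCondition, calibrate_input_power, solve_pennes_steady, thermal_estimators
from .errors import ConfigurationError
from .fields import AntennaRing, FieldMatrix, dominant_component, synthesize_surrogate_fields, write_field_container
from .phantom import (
    CylinderLayer,
    PhantomConfig,
    RegionPartition,
    Tissue,
    TissuePhantom,
    TissueTable,
    build_layered_cylinder_phantom,
    partition_regions,
)
from .pso_benchmark import PSOConfig, run_pso
from .sar_metrics import (
    DEFAULT_SCOPE,
    MetricReport,
    compute_htq,
    compute_sar,
    vchi_curve,
    write_metric_report_csv,
    write_normalized_sar_nifti,
)
from .threshold_search import (
    GaussianTargetSpec,
    ParetoCandidate,
    build_gaussian_target,
    default_candidates,
    derive_mask_levels,
    run_threshold_sweep,
    select_knee,
)

logger = logging.getLogger(__name__)

# Fixture tissue values: typical published dielectric/thermal data at 434 MHz.
# These are fixture choices, not reference values; the tumor dielectrics are
# the tailored pair (eps_r = 59, sigma = 0.89 S/m).
DEFAULT_TISSUES = [
    Tissue("spinal_cord", 35.4, 0.46, 1075.0, 0.51, 3630.0, 160.0),
    Tissue("bone", 13.1, 0.09, 1908.0, 0.32, 1313.0, 10.0),
    Tissue("muscle", 56.9, 0.80, 1090.0, 0.49, 3421.0, 39.0),
    Tissue("fat", 11.6, 0.08, 911.0, 0.21, 2348.0, 33.0),
    Tissue("skin", 46.1, 0.70, 1109.0, 0.37, 3391.0, 106.0),
    Tissue("tumor", 59.0, 0.89, 1090.0, 0.52, 3421.0, 72.0),
]

TUMOR_CENTER_MM = (-18.0, -18.0, -15.0)
TUMOR_RT_MM = 6.0
TRANSITION_RH_MM = 18.0
RING_FREQUENCY_HZ = 434e6


def default_tissue_table() -> TissueTable:
    return TissueTable(DEFAULT_TISSUES)


def reference_phantom_config(
    spacing_mm: float = 5.0,
    table: TissueTable | None = None,
) -> PhantomConfig:
    """Layered cylinder standing in for a neck: cord/bone/muscle/fat/skin."""
    return PhantomConfig(
        layers=[
            CylinderLayer(10.0, "spinal_cord"),
            CylinderLayer(25.0, "bone"),
            CylinderLayer(53.0, "muscle"),
            CylinderLayer(58.0, "fat"),
            CylinderLayer(60.0, "skin"),
        ],
        height_mm=100.0,
        spacing_mm=spacing_mm,
        table=table or default_tissue_table(),
        tumor_center_mm=TUMOR_CENTER_MM,
        tumor_radius_mm=TUMOR_RT_MM,
    )


def generate_reference_fixture(
    seed: int = 0,
    spacing_mm: float = 5.0,
    n_antennas: int = 8,
) -> tuple[TissuePhantom, FieldMatrix, RegionPartition]:
    """Deterministic phantom + surrogate field matrix + region partition.

    The seed is accepted for interface uniformity; the construction is fully
    deterministic, so any seed yields bit-identical output.
    """
    del seed  # deterministic construction
    phantom = build_layered_cylinder_phantom(reference_phantom_config(spacing_mm))
    ring = AntennaRing(
        n_antennas=n_antennas,
        radius_mm=90.0,
        height_mm=TUMOR_CENTER_MM[2],
        frequency_hz=RING_FREQUENCY_HZ,
    )
    matrix = synthesize_surrogate_fields(phantom, ring, reference_tissue="muscle",
                                         amplitude=1.0, leakage=0.1)
    partition = partition_regions(phantom, TUMOR_CENTER_MM, TUMOR_RT_MM, TRANSITION_RH_MM)
    return phantom, matrix, partition


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run (fully serializable)."""

    seed: int = 0
    spacing_mm: float = 5.0
    n_antennas: int = 8
    a0: float = 1e4
    n_candidates: int = 10
    p0_watt: float = 1.0
    r0_ohm: float = 50.0
    max_iter: int = 4000
    pso_swarm: int = 100
    pso_max_iter: int = 200
    target_t90: float = 42.0
    bolus_h: float = 82.0
    bolus_text: float = 20.0
    healthy_scope: str = DEFAULT_SCOPE
    out_dir: str = "pipeline_out"

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.digest(), "seed": cfg.seed, "package_version": __version__}


def _excitation_record(exc) -> dict:
    return {
        "amplitudes_V": [float(a) for a in exc.amplitudes()],
        "phases_deg": [float(p) for p in exc.phases_deg()],
        "p0_watt": exc.p0_watt,
        "r0_ohm": exc.r0_ohm,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full planning chain and write every declared artifact.

    Returns a manifest mapping artifact names to paths plus headline numbers.
    Stage failures raise with a stage-tagged message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"provenance": _provenance(cfg), "artifacts": {}, "summary": {}}
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Stage()

    with stage("fixture"):
        phantom, matrix, partition = generate_reference_fixture(
            cfg.seed, cfg.spacing_mm, cfg.n_antennas
        )
        fields_path = out / "EN.h5"
        write_field_container(matrix, fields_path)
        manifest["artifacts"]["fields"] = str(fields_path)

    stopping = StoppingConfig(max_iter=cfg.max_iter)

    with stage("sweep"):
        candidates = default_candidates(cfg.a0, cfg.n_candidates)
        sweep = run_threshold_sweep(
            matrix, partition, phantom, cfg.a0, candidates,
            p0_watt=cfg.p0_watt, r0_ohm=cfg.r0_ohm, stop=stopping,
            healthy_scope=cfg.healthy_scope,
        )
        front = select_knee(sweep)
        sweep_path = out / "sweep.csv"
        write_sweep_csv(sweep, front, sweep_path)
        manifest["artifacts"]["sweep"] = str(sweep_path)
        knee = front.knee
        manifest["summary"]["knee_thup"] = knee.thup
        manifest["summary"]["knee_thlow"] = knee.thlow

    with stage("apa"):
        axis = dominant_component(matrix)
        spec = GaussianTargetSpec(cfg.a0, knee.sigma0_mm, partition.centroid, axis)
        target = build_gaussian_target(spec, matrix.grid, matrix.voxel_index)
        mask = PowerMask(partition, knee.thlow, knee.thup)
        apa_result = run_apa(
            matrix, target, mask, phantom, partition=partition,
            p0_watt=cfg.p0_watt, r0_ohm=cfg.r0_ohm, stop=stopping,
        )
        apa_json = out / "apa_result.json"
        _write_optimizer_json(apa_json, "apa", apa_result.best_excitation,
                              apa_result.best_htq, apa_result.iterations_run,
                              apa_result.stop_reason.value, cfg)
        _write_trace_csv(out / "apa_trace.csv",
                         htq=apa_result.htq_trace, out_of_mask=apa_result.oom_trace)
        manifest["artifacts"]["apa_result"] = str(apa_json)
        manifest["summary"]["apa_htq"] = apa_result.best_htq

    with stage("pso"):
        pso_result = run_pso(
            matrix, partition, phantom, p0_watt=cfg.p0_watt, r0_ohm=cfg.r0_ohm,
            cfg=PSOConfig(swarm_size=cfg.pso_swarm, max_iter=cfg.pso_max_iter, seed=cfg.seed),
        )
        pso_json = out / "pso_result.json"
        _write_optimizer_json(pso_json, "pso", pso_result.best_excitation,
                              pso_result.best_htq, pso_result.iterations_run, "converged", cfg)
        _write_trace_csv(out / "pso_trace.csv", best_htq=pso_result.best_htq_trace)
        manifest["artifacts"]["pso_result"] = str(pso_json)
        manifest["summary"]["pso_htq"] = pso_result.best_htq

    with stage("metrics"):
        from .fields import superpose_field

        reports = {}
        for name, exc in (("apa", apa_result.best_excitation),
                          ("pso", pso_result.best_excitation)):
            sar = compute_sar(superpose_field(matrix, exc.coefficients), phantom, "peak")
            curve = vchi_curve(sar, partition, healthy_scope=cfg.healthy_scope)
            report = MetricReport(
                htq=compute_htq(sar, partition), vchi_curve=curve,
                scope=cfg.healthy_scope, notes=[f"method={name}"],
            )
            path = out / f"vchi_{name}.csv"
            write_metric_report_csv(report, path)
            nii = out / f"sar_norm_{name}.nii.gz"
            write_normalized_sar_nifti(sar, partition, phantom, nii)
            manifest["artifacts"][f"vchi_{name}"] = str(path)
            manifest["artifacts"][f"sar_norm_{name}"] = str(nii)
            reports[name] = (sar, report)

    with stage("thermal"):
        import nibabel as nib

        bcs = [BoundaryCondition("exterior", cfg.bolus_h, cfg.bolus_text)]
        est_rows = []
        for name, (sar, _) in reports.items():
            p0, temps = calibrate_input_power(
                phantom, sar, bcs, cfg.target_t90, partition.tumor_mask,
            )
            t90, t50, t10 = thermal_estimators(temps, partition.tumor_mask)
            est_rows.append((name, p0, t90, t50, t10))
            vol = temps.volume(phantom.grid.shape, fill=np.nan).astype(np.float32)
            affine = np.diag(list(phantom.grid.spacing) + [1.0])
            affine[:3, 3] = phantom.grid.origin
            nii = out / f"temperature_{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), str(nii))
            manifest["artifacts"][f"temperature_{name}"] = str(nii)
            manifest["summary"][f"{name}_p0_watt"] = p0
        est_path = out / "thermal_estimators.csv"
        with open(est_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["method", "p0_watt", "t90_C", "t50_C", "t10_C"])
            for row in est_rows:
                w.writerow([row[0]] + [f"{v:.4f}" for v in row[1:]])
        manifest["artifacts"]["thermal_estimators"] = str(est_path)

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["resolved_config"] = asdict(cfg)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest


def write_sweep_csv(sweep: Sequence[ParetoCandidate], front, path: str | Path) -> None:
    nd = set(front.nondominated_ids)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["thup", "thlow", "sigma0_mm", "v10_pct", "v50_pct", "htq",
                    "nondominated", "knee"])
        for i, c in enumerate(sweep):
            w.writerow([
                f"{c.thup:.6g}", f"{c.thlow:.6g}", f"{c.sigma0_mm:.6g}",
                f"{c.v10:.6g}", f"{c.v50:.6g}", f"{c.htq:.6g}",
                int(i in nd), int(i == front.knee_id),
            ])


def _write_optimizer_json(path, method, exc, htq, iterations, stop_reason, cfg) -> None:
    Path(path).write_text(json.dumps({
        "method": method,
        "excitation": _excitation_record(exc),
        "final_htq": htq,
        "iterations": int(iterations),
        "stop_reason": stop_reason,
        "provenance": _provenance(cfg),
    }, indent=2))


def _write_trace_csv(path, **columns) -> None:
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration"] + names)
        for i in range(max(len(a) for a in arrays)):
            w.writerow([i] + [a[i] if i < len(a) else "" for a in arrays])
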