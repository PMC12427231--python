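"""SAR computation and the planning metrics derived from it.

SAR is ``0.5 * sigma / rho * |E|^2`` per voxel under the peak-phasor
convention (the 1/2 prefactor drops for RMS phasors).  The hotspot-to-target
quotient (HTQ) is the mean SAR over the hottest 1% of non-tumor tissue
divided by the mean tumor SAR; the Vchi%H family counts the fraction of
healthy volume whose SAR exceeds chi% of the tumor maximum.  Both are
invariant under global power rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .fields import FieldMatrix, TotalField
from .phantom import RegionPartition, TissuePhantom

__all__ = [
    "SARMap",
    "MetricReport",
    "compute_sar",
    "compute_htq",
    "compute_vchi",
    "vchi_curve",
    "write_metric_report_csv",
    "write_normalized_sar_nifti",
]

HealthyScope = Literal["healthy_only", "healthy_plus_transition"]

DEFAULT_SCOPE: HealthyScope = "healthy_plus_transition"


@dataclass
class SARMap:
    """Per-voxel SAR (W/kg) on the M sampled voxels."""

    values: np.ndarray
    voxel_index: np.ndarray
    phasor_convention: Literal["peak", "rms"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SAR must be nonnegative")

    @property
    def m_voxels(self) -> int:
        return int(self.values.shape[0])


@dataclass
class MetricReport:
    htq: float
    vchi_curve: list[tuple[float, float]]
    scope: HealthyScope
    notes: list[str] = field(default_factory=list)


def compute_sar(
    e_field: TotalField,
    phantom: TissuePhantom,
    phasor_convention: Literal["peak", "rms"] | None = "peak",
) -> SARMap:
    """SAR per sampled voxel from the total field and tissue properties.

    ``|E|^2`` sums the squared magnitudes of the three complex components;
    sigma and rho are looked up from the voxel labels.
    """
    if phasor_convention not in ("peak", "rms"):
        raise ConfigurationError(
            f"phasor convention must be 'peak' or 'rms', got {phasor_convention!r}"
        )
    i, j, k = np.asarray(e_field.voxel_index).T
    labels = phantom.labels[i, j, k]
    sigma = phantom.table.map_property(labels, "sigma")
    rho = phantom.table.map_property(labels, "rho")
    if np.any(rho == 0):
        raise ConfigurationError("field sampled on exterior voxels (rho = 0)")
    prefactor = 0.5 if phasor_convention == "peak" else 1.0
    sar = prefactor * sigma / rho * e_field.intensity()
    return SARMap(values=sar, voxel_index=e_field.voxel_index, phasor_convention=phasor_convention)


def _region_selectors(sar: SARMap, partition: RegionPartition) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i, j, k = np.asarray(sar.voxel_index).T
    return (
        partition.tumor_mask[i, j, k],
        partition.transition_mask[i, j, k],
        partition.healthy_mask[i, j, k],
    )


def compute_htq(sar: SARMap, partition: RegionPartition) -> float:
    """Hotspot-to-target quotient.

    The healthy set here includes the transition shell (every non-tumor
    tissue voxel).  The hotspot volume V1 is the ceil(1%) highest-SAR voxels
    of that set; HTQ = mean(SAR over V1) / mean(SAR over tumor).
    """
    tumor_sel, trans_sel, healthy_sel = _region_selectors(sar, partition)
    non_tumor = trans_sel | healthy_sel
    if not tumor_sel.any():
        raise DegenerateInputError("empty tumor region in SAR map")
    if not non_tumor.any():
        raise DegenerateInputError("empty healthy region in SAR map")
    tumor_mean = float(np.mean(sar.values[tumor_sel]))
    if tumor_mean == 0:
        raise DegenerateInputError("zero mean tumor SAR: HTQ undefined")
    healthy_vals = sar.values[non_tumor]
    n_top = math.ceil(0.01 * healthy_vals.size)
    top = np.sort(np.partition(healthy_vals, healthy_vals.size - n_top)[-n_top:])[::-1]
    return float(np.mean(top) / tumor_mean)


def compute_vchi(
    sar: SARMap,
    partition: RegionPartition,
    chi: float,
    healthy_scope: HealthyScope = DEFAULT_SCOPE,
) -> float:
    """Percentage of healthy volume with SAR above chi% of the tumor maximum."""
    if not 0 < chi <= 100:
        raise ValueError(f"chi must be in (0, 100], got {chi}")
    tumor_sel, trans_sel, healthy_sel = _region_selectors(sar, partition)
    if not tumor_sel.any():
        raise DegenerateInputError("empty tumor region in SAR map")
    tumor_max = float(np.max(sar.values[tumor_sel]))
    if tumor_max == 0:
        raise DegenerateInputError("zero maximum tumor SAR: Vchi undefined")
    if healthy_scope == "healthy_only":
        sel = healthy_sel
    elif healthy_scope == "healthy_plus_transition":
        sel = healthy_sel | trans_sel
    else:
        raise ConfigurationError(f"unknown healthy scope {healthy_scope!r}")
    healthy_vals = sar.values[sel]
    if healthy_vals.size == 0:
        raise DegenerateInputError("empty healthy region for Vchi")
    threshold = chi / 100.0 * tumor_max
    return float(100.0 * np.count_nonzero(healthy_vals > threshold) / healthy_vals.size)


def vchi_curve(
    sar: SARMap,
    partition: RegionPartition,
    chis: Sequence[float] = tuple(range(10, 100, 10)),
    healthy_scope: HealthyScope = DEFAULT_SCOPE,
) -> list[tuple[float, float]]:
    """(chi, Vchi%) pairs; non-increasing in chi by construction."""
    return [(float(c), compute_vchi(sar, partition, c, healthy_scope)) for c in chis]


def write_metric_report_csv(report: MetricReport, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "chi_percent", "value", "scope"])
        w.writerow(["htq", "", f"{report.htq:.6g}", report.scope])
        for chi, v in report.vchi_curve:
            w.writerow(["vchi", chi, f"{v:.6g}", report.scope])


def write_normalized_sar_nifti(
    sar: SARMap, partition: RegionPartition, phantom: TissuePhantom, path: str | Path
) -> None:
    """SAR / max-tumor-SAR volume export for visual inspection."""
    import nibabel as nib

    tumor_sel, _, _ = _region_selectors(sar, partition)
    tumor_max = float(np.max(sar.values[tumor_sel])) if tumor_sel.any() else 0.0
    if tumor_max == 0:
        raise DegenerateInputError("zero maximum tumor SAR: cannot normalize")
    vol = np.zeros(phantom.grid.shape, dtype=np.float32)
    i, j, k = np.asarray(sar.voxel_index).T
    vol[i, j, k] = sar.values / tumor_max
    affine = np.diag(list(phantom.grid.spacing) + [1.0])
    affine[:3, 3] = phantom.grid.origin
    nib.save(nib.Nifti1Image(vol, affine), str(path))
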