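"""Alternating-projections optimizer for phased-array power deposition.

One iteration alternates two projections: clip the reconstructed field onto
the feasible set of a two-level power mask (raise tumor voxels below the
lower intensity threshold, cap non-transition healthy voxels above the upper
one), then project back onto the column space of the stacked antenna-field
matrix via its cached pseudo-inverse.  Every iterate is renormalized so the
total input power is fixed; the iterate with the lowest hotspot-to-target
quotient is returned.

Two printed-formula corrections are deliberate and documented:

* the power normalization scales by ``sqrt(2 R0 P0) / ||b||`` so that
  ``||b||^2 / (2 R0)`` equals ``P0`` exactly (a linear scale by the power
  ratio itself would not),
* clipping scales a voxel's vector by ``sqrt(th) / |E|`` so its *intensity*
  ``|E|^2`` lands on the threshold, consistent with thresholds carrying
  V^2/m^2 units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from .errors import DegenerateInputError, NumericalError
from .fields import FieldMatrix, TotalField, superpose_field
from .phantom import RegionPartition, TissuePhantom
from .sar_metrics import compute_htq, compute_sar

__all__ = [
    "ExcitationVector",
    "PowerMask",
    "StoppingConfig",
    "StopReason",
    "APAResult",
    "Projector",
    "build_projector",
    "normalize_power",
    "clip_to_mask",
    "run_apa",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExcitationVector:
    """Complex antenna feedings with their power-normalization contract:
    ``||coefficients||^2 / (2 R0) == P0``."""

    coefficients: np.ndarray
    p0_watt: float
    r0_ohm: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=np.complex128).reshape(-1)
        )

    @property
    def n_antennas(self) -> int:
        return int(self.coefficients.shape[0])

    @property
    def input_power_watt(self) -> float:
        return float(np.sum(np.abs(self.coefficients) ** 2) / (2.0 * self.r0_ohm))

    def amplitudes(self) -> np.ndarray:
        """Per-antenna amplitudes (V)."""
        return np.abs(self.coefficients)

    def phases_deg(self) -> np.ndarray:
        """Per-antenna phases in [0, 360) degrees."""
        return np.rad2deg(np.angle(self.coefficients)) % 360.0


@dataclass
class PowerMask:
    """Region partition plus the two intensity thresholds (V^2/m^2).

    ``thlow`` is enforced (as a floor) inside the tumor; ``thup`` is a cap in
    the outer healthy region; the transition shell is unconstrained.
    """

    partition: RegionPartition
    thlow: float
    thup: float

    def __post_init__(self) -> None:
        if self.thlow <= 0 or self.thup <= 0:
            raise ValueError(f"thresholds must be > 0, got ({self.thlow}, {self.thup})")


class StopReason(str, Enum):
    PLATEAU = "htq_plateau"
    OUT_OF_MASK_GROWTH = "out_of_mask_growth"
    MAX_ITER = "max_iterations"
    FEASIBLE = "mask_satisfied"


@dataclass(frozen=True)
class StoppingConfig:
    max_iter: int = 4000
    plateau_window: int = 50
    plateau_tol: float = 1e-4
    oom_persistence: int = 20

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.plateau_window < 1 or self.oom_persistence < 1:
            raise ValueError("plateau_window and oom_persistence must be >= 1")


@dataclass
class APAResult:
    best_excitation: ExcitationVector
    htq_trace: np.ndarray
    oom_trace: np.ndarray
    iterations_run: int
    stop_reason: StopReason
    final_field: TotalField
    best_iteration: int

    @property
    def best_htq(self) -> float:
        return float(self.htq_trace[self.best_iteration])


class Projector:
    """Cached pseudo-inverse of the field matrix; applies the least-squares
    coefficient solve and the column-space projection."""

    def __init__(self, matrix: FieldMatrix, rcond: float = 1e-10):
        values = matrix.values
        if values.size == 0 or not np.any(values):
            raise DegenerateInputError("cannot build a projector from an all-zero matrix")
        self._matrix = matrix
        self._pinv = np.linalg.pinv(values, rcond=rcond)
        if np.linalg.matrix_rank(values, tol=rcond * np.linalg.norm(values, 2)) == 0:
            raise DegenerateInputError("field matrix has rank 0")

    @property
    def matrix(self) -> FieldMatrix:
        return self._matrix

    def coefficients(self, stacked_field: np.ndarray) -> np.ndarray:
        """Least-squares antenna coefficients reproducing a stacked field."""
        return self._pinv @ np.asarray(stacked_field).reshape(-1)

    def project(self, stacked_field: np.ndarray) -> np.ndarray:
        """Orthogonal projection of a stacked field onto the column space."""
        return self._matrix.values @ self.coefficients(stacked_field)


def build_projector(matrix: FieldMatrix, rcond: float = 1e-10) -> Projector:
    return Projector(matrix, rcond=rcond)


def normalize_power(b: np.ndarray, p0_watt: float, r0_ohm: float) -> ExcitationVector:
    """Scale coefficients so the total input power ``||b||^2/(2 R0)`` is P0."""
    b = np.asarray(b, dtype=np.complex128).reshape(-1)
    norm_sq = float(np.sum(np.abs(b) ** 2))
    if norm_sq == 0:
        raise DegenerateInputError("cannot power-normalize a zero excitation vector")
    scale = np.sqrt(2.0 * r0_ohm * p0_watt / norm_sq)
    return ExcitationVector(coefficients=scale * b, p0_watt=p0_watt, r0_ohm=r0_ohm)


def clip_to_mask(e_field: TotalField, mask: PowerMask, matrix: FieldMatrix) -> tuple[TotalField, int]:
    """Project a field onto the mask-feasible set by magnitude clipping.

    Tumor voxels with intensity below ``thlow`` are rescaled up to it;
    healthy voxels (outer region only — the transition shell is never
    touched) above ``thup`` are rescaled down.  Scaling is a real positive
    factor per voxel, so directions and per-component phases are preserved.
    Returns the clipped field and the out-of-mask voxel count.
    """
    tumor_sel = matrix.sample_selector(mask.partition.tumor_mask)
    healthy_sel = matrix.sample_selector(mask.partition.healthy_mask)

    values = e_field.values.copy()
    intensity = np.sum(np.abs(values) ** 2, axis=1)

    low = tumor_sel & (intensity < mask.thlow)
    high = healthy_sel & (intensity > mask.thup)
    count = int(np.count_nonzero(low) + np.count_nonzero(high))

    zero_low = low & (intensity == 0)
    if np.any(zero_low):
        # no direction to scale along: leave unchanged but keep in the count
        logger.debug("%d zero-magnitude tumor voxels below thlow left unchanged",
                     int(np.count_nonzero(zero_low)))
        low &= intensity > 0

    if np.any(low):
        values[low] *= np.sqrt(mask.thlow / intensity[low])[:, None]
    if np.any(high):
        values[high] *= np.sqrt(mask.thup / intensity[high])[:, None]

    return TotalField(values=values, grid=e_field.grid, voxel_index=e_field.voxel_index), count


def run_apa(
    matrix: FieldMatrix,
    target: TotalField,
    mask: PowerMask,
    phantom: TissuePhantom,
    partition: RegionPartition | None = None,
    p0_watt: float = 1.0,
    r0_ohm: float | None = None,
    stop: StoppingConfig | None = None,
    rcond: float = 1e-10,
    projector: Projector | None = None,
) -> APAResult:
    """Run the alternating-projections loop from a target field.

    The target is first projected onto the antenna column space and power
    normalized; each subsequent iteration clips the reconstructed field to
    the mask, re-projects, renormalizes, and evaluates the HTQ of the
    physically realizable (projected) field.  Stops on an HTQ plateau,
    persistent growth of the out-of-mask count, or the iteration cap; the
    returned excitation is the recorded-minimum-HTQ iterate.
    """
    if partition is None:
        partition = mask.partition
    if r0_ohm is None:
        r0_ohm = matrix.r0_ohm
    if stop is None:
        stop = StoppingConfig()
    if projector is None:
        projector = build_projector(matrix, rcond=rcond)

    def reconstruct(b_raw: np.ndarray) -> tuple[ExcitationVector, TotalField]:
        exc = normalize_power(b_raw, p0_watt, r0_ohm)
        return exc, superpose_field(matrix, exc.coefficients)

    exc, e_rec = reconstruct(projector.coefficients(target.stacked()))

    htq_trace: list[float] = []
    oom_trace: list[int] = []
    best_htq = np.inf
    best_iter = -1
    best_exc = exc
    best_field = e_rec
    stop_reason = StopReason.MAX_ITER
    oom_rises = 0

    for it in range(stop.max_iter):
        sar = compute_sar(e_rec, phantom, phasor_convention="peak")
        htq = compute_htq(sar, partition)
        if not np.isfinite(htq):
            raise NumericalError(f"non-finite HTQ at iteration {it}")
        clipped, oom = clip_to_mask(e_rec, mask, matrix)
        htq_trace.append(htq)
        oom_trace.append(oom)

        if htq < best_htq:
            best_htq, best_iter, best_exc, best_field = htq, it, exc, e_rec

        if oom == 0:
            stop_reason = StopReason.FEASIBLE
            break
        if it >= 1 and oom > oom_trace[-2]:
            oom_rises += 1
        else:
            oom_rises = 0
        if oom_rises >= stop.oom_persistence:
            stop_reason = StopReason.OUT_OF_MASK_GROWTH
            break
        if it - best_iter >= stop.plateau_window and it >= stop.plateau_window:
            window_best = min(htq_trace[-stop.plateau_window:])
            if window_best > best_htq * (1.0 - stop.plateau_tol):
                stop_reason = StopReason.PLATEAU
                break

        exc, e_rec = reconstruct(projector.coefficients(clipped.stacked()))

    return APAResult(
        best_excitation=best_exc,
        htq_trace=np.asarray(htq_trace),
        oom_trace=np.asarray(oom_trace),
        iterations_run=len(htq_trace),
        stop_reason=stop_reason,
        final_field=best_field,
        best_iteration=best_iter,
    )
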