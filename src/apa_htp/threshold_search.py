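"""Adaptive two-threshold search: Gaussian target construction, closed-form
threshold derivation, candidate sweep, and Pareto-knee selection.

For a candidate upper threshold ``thup`` the Gaussian intensity profile with
peak ``A0`` at the tumor centroid is forced through ``thup`` at the outer
transition radius ``rh``; the lower threshold is the same profile evaluated
at the tumor radius ``rt``:

    sigma0 = rh * (2 ln(A0 / thup))^(-1/2)
    thlow  = A0 * exp(-rt^2 / (2 sigma0^2))

Each candidate drives one alternating-projections run; the resulting V10%H /
V50%H pairs form a two-objective front whose knee (largest normalized
distance to the extreme chord) picks the operating thresholds.

The Gaussian ``A0 exp(-d^2 / (2 sigma0^2))`` is an *intensity* profile
(V^2/m^2): the target field component is its square root with zero phase,
so the squared field magnitude traces the profile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .apa import APAResult, StoppingConfig, build_projector, run_apa, PowerMask
from .errors import DegenerateInputError
from .fields import FieldMatrix, TotalField, dominant_component, superpose_field
from .phantom import RegionPartition, TissuePhantom, VoxelGrid
from .sar_metrics import DEFAULT_SCOPE, HealthyScope, compute_sar, compute_vchi

__all__ = [
    "GaussianTargetSpec",
    "ParetoCandidate",
    "ParetoFront",
    "derive_mask_levels",
    "build_gaussian_target",
    "estimate_peak_intensity_bound",
    "default_candidates",
    "run_threshold_sweep",
    "select_knee",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class GaussianTargetSpec:
    """Gaussian intensity target: peak ``a0`` (V^2/m^2), width ``sigma0``
    (mm), centered at ``centroid``, polarized along ``axis``."""

    a0: float
    sigma0: float
    centroid: tuple[float, float, float]
    axis: str

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.sigma0 <= 0:
            raise ValueError("a0 and sigma0 must be > 0")
        if self.axis not in _AXIS_INDEX:
            raise ValueError(f"axis must be one of x/y/z, got {self.axis!r}")


@dataclass
class ParetoCandidate:
    thup: float
    thlow: float
    sigma0_mm: float
    v10: float
    v50: float
    htq: float
    result: APAResult | None = None


@dataclass
class ParetoFront:
    candidates: list[ParetoCandidate]
    nondominated_ids: list[int]
    knee_id: int

    @property
    def knee(self) -> ParetoCandidate:
        return self.candidates[self.knee_id]


def derive_mask_levels(a0: float, thup: float, rt: float, rh: float) -> tuple[float, float]:
    """Closed-form (sigma0, thlow) for a candidate upper threshold.

    By construction the Gaussian intensity equals ``thup`` at distance ``rh``
    and ``thlow`` at ``rt``.
    """
    if not 0 < thup < a0:
        raise ValueError(f"thup must be in (0, A0), got thup={thup}, A0={a0}")
    if not 0 < rt < rh:
        raise ValueError(f"need 0 < rt < rh, got rt={rt}, rh={rh}")
    sigma0 = rh / np.sqrt(2.0 * np.log(a0 / thup))
    thlow = a0 * np.exp(-(rt**2) / (2.0 * sigma0**2))
    return float(sigma0), float(thlow)


def build_gaussian_target(
    spec: GaussianTargetSpec,
    grid: VoxelGrid,
    voxel_index: np.ndarray,
) -> TotalField:
    """Zero-phase Gaussian-intensity target field on the sampled voxels.

    The chosen component at distance d from the centroid is
    ``sqrt(a0 * exp(-d^2 / (2 sigma0^2)))``; the other two are zero.
    """
    centers = grid.index_centers(voxel_index)
    d2 = np.sum((centers - np.asarray(spec.centroid)) ** 2, axis=1)
    amplitude = np.sqrt(spec.a0 * np.exp(-d2 / (2.0 * spec.sigma0**2)))
    values = np.zeros((voxel_index.shape[0], 3), dtype=np.complex128)
    values[:, _AXIS_INDEX[spec.axis]] = amplitude
    return TotalField(values=values, grid=grid, voxel_index=voxel_index)


def estimate_peak_intensity_bound(
    matrix: FieldMatrix,
    partition: RegionPartition,
    p0_watt: float = 1.0,
    r0_ohm: float | None = None,
) -> float:
    """Cauchy-Schwarz upper bound on the achievable focal intensity.

    For any excitation with ``||b||^2 = 2 R0 P0`` the voxel intensity obeys
    ``|E(r)|^2 <= 2 R0 P0 * sum_n ||e_n(r)||^2``; the bound is the maximum of
    the right-hand side over tumor voxels (complete constructive
    interference under the input-power cap).
    """
    if r0_ohm is None:
        r0_ohm = matrix.r0_ohm
    tumor_sel = matrix.sample_selector(partition.tumor_mask)
    if not tumor_sel.any():
        raise ValueError("empty tumor region: no voxels to bound")
    power_sum = matrix.per_voxel_power_sum()[tumor_sel]
    return float(2.0 * r0_ohm * p0_watt * np.max(power_sum))


def default_candidates(a0: float, n: int = 10, lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """Log-spaced candidate upper thresholds in [lo*A0, hi*A0]."""
    return np.geomspace(lo * a0, hi * a0, n)


def run_threshold_sweep(
    matrix: FieldMatrix,
    partition: RegionPartition,
    phantom: TissuePhantom,
    a0: float,
    candidates: Sequence[float],
    p0_watt: float = 1.0,
    r0_ohm: float | None = None,
    stop: StoppingConfig | None = None,
    healthy_scope: HealthyScope = DEFAULT_SCOPE,
    keep_results: bool = False,
) -> list[ParetoCandidate]:
    """Evaluate each candidate upper threshold with one optimizer run.

    Candidates are independent (order-invariant): each derives its
    (sigma0, thlow), builds the Gaussian target along the dominant
    polarization, runs the alternating-projections loop, and records the
    V10/V50 spillover metrics of the best iterate's SAR map.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    for c in candidates:
        if not 0 < c < a0:
            raise ValueError(f"candidate thup {c} outside (0, A0={a0})")
    axis = dominant_component(matrix)
    projector = build_projector(matrix)  # shared cache; runs stay independent
    out: list[ParetoCandidate] = []
    for thup in candidates:
        sigma0, thlow = derive_mask_levels(a0, thup, partition.rt, partition.rh)
        spec = GaussianTargetSpec(a0=a0, sigma0=sigma0, centroid=partition.centroid, axis=axis)
        target = build_gaussian_target(spec, matrix.grid, matrix.voxel_index)
        mask = PowerMask(partition=partition, thlow=thlow, thup=thup)
        result = run_apa(
            matrix, target, mask, phantom,
            partition=partition, p0_watt=p0_watt, r0_ohm=r0_ohm,
            stop=stop, projector=projector,
        )
        sar = compute_sar(result.final_field, phantom, phasor_convention="peak")
        v10 = compute_vchi(sar, partition, 10.0, healthy_scope)
        v50 = compute_vchi(sar, partition, 50.0, healthy_scope)
        out.append(
            ParetoCandidate(
                thup=float(thup), thlow=thlow, sigma0_mm=sigma0,
                v10=v10, v50=v50, htq=result.best_htq,
                result=result if keep_results else None,
            )
        )
    return out


def _nondominated(points: np.ndarray) -> list[int]:
    """Indices of nondominated points under componentwise minimization."""
    ids = []
    for i, p in enumerate(points):
        dominated = False
        for j, q in enumerate(points):
            if j != i and np.all(q <= p) and np.any(q < p):
                dominated = True
                break
        if not dominated:
            ids.append(i)
    return ids


def select_knee(candidates: Sequence[ParetoCandidate]) -> ParetoFront:
    """Pick the knee of the (V10, V50) front.

    The nondominated subset is min-max normalized on both axes; the knee is
    the point with the largest perpendicular distance to the chord joining
    the two extreme nondominated points.  Degenerate fronts: a single
    nondominated point is its own knee; distance ties resolve to the smaller
    V50.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    pts = np.array([[c.v10, c.v50] for c in candidates], dtype=float)
    nd = _nondominated(pts)
    if len(nd) == 1:
        return ParetoFront(candidates, nd, nd[0])

    sub = pts[nd]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (sub - lo) / span

    order = np.lexsort((norm[:, 1], norm[:, 0]))
    a, b = norm[order[0]], norm[order[-1]]
    chord = b - a
    chord_len = np.linalg.norm(chord)
    if chord_len == 0:
        dists = np.zeros(len(nd))
    else:
        rel = norm - a
        dists = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / chord_len

    best = max(
        range(len(nd)),
        key=lambda i: (dists[i], -pts[nd[i], 1]),  # ties -> smaller v50
    )
    return ParetoFront(candidates, nd, nd[best])
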