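"""Steady-state Pennes bioheat solver on the labeled voxel grid.

Solves ``0 = div(k grad T) - rho_b Cp_b w_s (T - Ta) + Q`` over the tissue
voxels with a 7-point finite-volume stencil: harmonic-mean face
conductivities between tissue voxels, convective (Robin) faces toward the
exterior or toward named cavity tissues, insulated faces otherwise.  The
perfusion sink converts the tabulated mL/min/kg rate to 1/s through the
local tissue density.  The volumetric source is SAR * rho (W/m^3).  All
lengths enter in mm and are converted to SI here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, DegenerateInputError, NumericalError
from .phantom import TissuePhantom
from .sar_metrics import SARMap

__all__ = [
    "BLOOD_RHO",
    "BLOOD_CP",
    "ARTERIAL_T",
    "BoundaryCondition",
    "TemperatureField",
    "solve_pennes_steady",
    "thermal_estimators",
    "calibrate_input_power",
]

BLOOD_RHO = 1060.0  # kg/m^3
BLOOD_CP = 3890.0  # J/kg/degC
ARTERIAL_T = 37.0  # degC


@dataclass(frozen=True)
class BoundaryCondition:
    """Convective (Robin) surface: ``-k dT/dn = h (T - Text)``.

    ``surface`` is either ``"exterior"`` (faces between tissue and the
    exterior label 0 or the grid boundary) or a tissue name, in which case
    that tissue's voxels are treated as a cavity: excluded from conduction,
    with Robin faces on the interface.
    """

    surface: str
    h: float
    text: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ConfigurationError("heat transfer coefficient h must be >= 0")


@dataclass
class TemperatureField:
    """Per-voxel temperature (degC) over the solved tissue voxels."""

    values: np.ndarray
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise NumericalError("temperature field contains non-finite values")

    def volume(self, shape: tuple[int, int, int], fill: float = np.nan) -> np.ndarray:
        vol = np.full(shape, fill)
        i, j, k = np.asarray(self.voxel_index).T
        vol[i, j, k] = self.values
        return vol


def _perfusion_per_second(omega_ml_min_kg: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """mL/min/kg -> 1/s via the local tissue density."""
    return omega_ml_min_kg * rho * 1e-6 / 60.0


def solve_pennes_steady(
    phantom: TissuePhantom,
    sar: SARMap | None,
    bcs: Sequence[BoundaryCondition] = (),
    p0_scale: float = 1.0,
) -> TemperatureField:
    """Assemble and solve the steady-state bioheat system.

    ``sar`` may be None for the source-free problem.  Faces without a
    boundary condition are insulated (documented default).  Raises if the
    system is singular (no perfusion and no Robin face anywhere).
    """
    grid = phantom.grid
    labels = phantom.labels
    cavity_labels: set[int] = set()
    exterior_bc: BoundaryCondition | None = None
    cavity_bc: dict[int, BoundaryCondition] = {}
    for bc in bcs:
        if bc.surface == "exterior":
            exterior_bc = bc
        else:
            lab = phantom.table.label_of(bc.surface)
            cavity_labels.add(lab)
            cavity_bc[lab] = bc

    solved = (labels != 0) & ~np.isin(labels, list(cavity_labels))
    n_solved = int(np.count_nonzero(solved))
    if n_solved == 0:
        raise DegenerateInputError("no tissue voxels to solve")
    index = np.full(grid.shape, -1, dtype=np.int64)
    vox = np.argwhere(solved)
    index[solved] = np.arange(n_solved)

    k_vol = phantom.property_volume("k")
    rho_vol = phantom.property_volume("rho")
    omega_vol = phantom.property_volume("omega")

    spacing_m = np.asarray(grid.spacing) * 1e-3
    vol_m3 = float(np.prod(spacing_m))
    face_area = [
        spacing_m[1] * spacing_m[2],
        spacing_m[0] * spacing_m[2],
        spacing_m[0] * spacing_m[1],
    ]

    w_s = _perfusion_per_second(omega_vol[solved], rho_vol[solved])
    sink = BLOOD_RHO * BLOOD_CP * w_s * vol_m3  # W/degC per voxel

    q_em = np.zeros(n_solved)
    if sar is not None:
        si, sj, sk = np.asarray(sar.voxel_index).T
        rows = index[si, sj, sk]
        ok = rows >= 0
        q_em[rows[ok]] = sar.values[ok] * rho_vol[si, sj, sk][ok]  # W/m^3
    source = q_em * vol_m3 * p0_scale  # W per voxel

    diag = sink.copy()
    rhs = sink * ARTERIAL_T + source
    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    vals_l: list[np.ndarray] = []
    any_robin = False

    i, j, k = vox.T
    my_idx = index[i, j, k]
    my_k = k_vol[i, j, k]
    for axis in range(3):
        for sign in (-1, 1):
            nb = vox.copy()
            nb[:, axis] += sign
            inside = (nb[:, axis] >= 0) & (nb[:, axis] < grid.shape[axis])
            nb_lab = np.zeros(len(vox), dtype=np.int64)
            nb_lab[inside] = labels[nb[inside, 0], nb[inside, 1], nb[inside, 2]]
            nb_solved = np.zeros(len(vox), dtype=bool)
            nb_solved[inside] = solved[nb[inside, 0], nb[inside, 1], nb[inside, 2]]

            # internal conduction faces (counted from both sides; symmetric)
            m = nb_solved
            if m.any():
                kj = k_vol[nb[m, 0], nb[m, 1], nb[m, 2]]
                ki = my_k[m]
                kf = 2.0 * ki * kj / (ki + kj)
                g = kf * face_area[axis] / spacing_m[axis]  # W/degC
                diag[my_idx[m]] += g
                rows_l.append(my_idx[m])
                cols_l.append(index[nb[m, 0], nb[m, 1], nb[m, 2]])
                vals_l.append(-g)

            # boundary faces: exterior (outside grid or label 0) or cavity
            bnd = ~nb_solved
            if not bnd.any():
                continue
            is_cavity = bnd & inside & np.isin(nb_lab, list(cavity_labels) or [-1])
            is_exterior = bnd & ~is_cavity
            for sel, bc_lookup in ((is_exterior, None), (is_cavity, cavity_bc)):
                if not sel.any():
                    continue
                if bc_lookup is None:
                    bc_arr = [exterior_bc] * int(sel.sum()) if exterior_bc else None
                    if bc_arr is None:
                        continue  # insulated
                    idxs = my_idx[sel]
                    ki = my_k[sel]
                    h = exterior_bc.h
                    text = exterior_bc.text
                    if h == 0:
                        continue
                    g = face_area[axis] / (spacing_m[axis] / (2.0 * ki) + 1.0 / h)
                    diag[idxs] += g
                    rhs[idxs] += g * text
                    any_robin = True
                else:
                    labs = nb_lab[sel]
                    idxs = my_idx[sel]
                    ki = my_k[sel]
                    for lab in np.unique(labs):
                        bc = cavity_bc[int(lab)]
                        if bc.h == 0:
                            continue
                        sub = labs == lab
                        g = face_area[axis] / (
                            spacing_m[axis] / (2.0 * ki[sub]) + 1.0 / bc.h
                        )
                        diag[idxs[sub]] += g
                        rhs[idxs[sub]] += g * bc.text
                        any_robin = True

    if not any_robin and np.all(sink == 0):
        raise DegenerateInputError(
            "singular bioheat system: no perfusion and no convective surface"
        )

    rows = np.concatenate([np.arange(n_solved)] + rows_l)
    cols = np.concatenate([np.arange(n_solved)] + cols_l)
    vals = np.concatenate([diag] + vals_l)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n_solved, n_solved))
    temps = spla.spsolve(mat, rhs)

    residual = np.linalg.norm(mat @ temps - rhs)
    scale = np.linalg.norm(rhs) or 1.0
    if residual / scale > 1e-8:
        raise NumericalError(f"bioheat solve residual {residual / scale:.2e} > 1e-8")
    return TemperatureField(values=temps, voxel_index=vox)


def thermal_estimators(temps: TemperatureField, region_mask_or_sel: np.ndarray,
                       quantiles: Sequence[float] = (90.0, 50.0, 10.0)) -> tuple[float, ...]:
    """Tq temperatures for q in ``quantiles`` over a region.

    Tq is the largest temperature t such that at least q% of region voxels
    satisfy T >= t (nearest-rank on the descending sort), which guarantees
    T90 <= T50 <= T10.  The region selector is either a grid-shaped mask or
    a length-matching boolean over the solved voxels.
    """
    sel = np.asarray(region_mask_or_sel)
    if sel.ndim == 3:
        i, j, k = np.asarray(temps.voxel_index).T
        sel = sel[i, j, k]
    vals = temps.values[sel]
    if vals.size == 0:
        raise ValueError("empty region for thermal estimators")
    desc = np.sort(vals)[::-1]
    out = []
    for q in quantiles:
        rank = int(np.ceil(q / 100.0 * vals.size))
        rank = min(max(rank, 1), vals.size)
        out.append(float(desc[rank - 1]))
    return tuple(out)


def calibrate_input_power(
    phantom: TissuePhantom,
    sar_at_1w: SARMap,
    bcs: Sequence[BoundaryCondition],
    target_t: float,
    tumor_mask: np.ndarray,
    statistic_q: float = 90.0,
) -> tuple[float, TemperatureField]:
    """Scale the input power so a tumor temperature statistic hits a target.

    The steady solution is affine in the source: ``T(P) = T0 + P (T1 - T0)``
    with T0 the zero-source and T1 the 1 W solution.  The power is found by
    a bracketed root solve of the (piecewise-linear, nondecreasing) statistic
    along that family, then confirmed with one full re-solve.
    """
    from scipy.optimize import brentq

    t0 = solve_pennes_steady(phantom, None, bcs)
    t1 = solve_pennes_steady(phantom, sar_at_1w, bcs)
    delta = t1.values - t0.values

    sel = np.asarray(tumor_mask)
    if sel.ndim == 3:
        i, j, k = np.asarray(t0.voxel_index).T
        sel = sel[i, j, k]

    def stat(p: float) -> float:
        tf = TemperatureField(values=t0.values + p * delta, voxel_index=t0.voxel_index)
        return thermal_estimators(tf, sel, quantiles=(statistic_q,))[0]

    s0, s1 = stat(0.0), stat(1.0)
    if s1 - s0 <= 1e-12:
        raise DegenerateInputError("zero tumor heating at 1 W: cannot calibrate power")
    if target_t <= s0:
        raise ValueError(
            f"target {target_t} degC not above the source-free tumor statistic {s0:.3f} degC"
        )
    p_guess = (target_t - s0) / (s1 - s0)
    p_hi = p_guess
    while stat(p_hi) < target_t:
        p_hi *= 2.0
        if p_hi > 1e9:
            raise NumericalError("power calibration failed to bracket the target")
    if abs(stat(p_guess) - target_t) < 1e-12:
        p0 = p_guess
    else:
        p0 = brentq(lambda p: stat(p) - target_t, 0.0, p_hi, xtol=1e-12)

    confirmed = solve_pennes_steady(phantom, sar_at_1w, bcs, p0_scale=p0)
    return float(p0), confirmed
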