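"""Unit-excitation antenna fields, the stacked field matrix, and superposition.

The stacked matrix collects one column per antenna; each column is the
antenna's complex vector field sampled on the M tissue voxels, arranged as
three contiguous blocks (all x entries, then y, then z), so the matrix is
3M x N.  A surrogate analytic model stands in for full-wave solver exports:
each antenna radiates a spherically spreading, exponentially attenuated wave
in an effective homogeneous lossy medium, polarized along the array axis
with a small fixed transverse leakage.  Externally simulated matrices enter
through the HDF5 container with the same layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import ConfigurationError, DegenerateInputError, FormatError, UnsupportedVersionError
from .phantom import RegionPartition, TissuePhantom, VoxelGrid

__all__ = [
    "AntennaRing",
    "FieldMatrix",
    "TotalField",
    "lossy_medium_constants",
    "synthesize_surrogate_fields",
    "assemble_field_matrix",
    "superpose_field",
    "dominant_component",
    "write_field_container",
    "read_field_container",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

_MU0 = 4e-7 * np.pi  # H/m
_EPS0 = 8.8541878128e-12  # F/m

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class AntennaRing:
    """Circular phased array: N elements on a ring of given radius/height."""

    n_antennas: int
    radius_mm: float
    height_mm: float = 0.0
    frequency_hz: float = 434e6
    polarization_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    phase_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_antennas < 1:
            raise ConfigurationError("antenna ring needs N >= 1")
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency_hz}")
        ax = np.asarray(self.polarization_axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise ConfigurationError("polarization axis must be nonzero")
        object.__setattr__(self, "polarization_axis", tuple(ax / nrm))

    def positions_mm(self) -> np.ndarray:
        """(N, 3) antenna positions, uniformly spread on the ring."""
        ang = np.deg2rad(self.phase_offset_deg) + 2 * np.pi * np.arange(self.n_antennas) / self.n_antennas
        return np.stack(
            [
                self.radius_mm * np.cos(ang),
                self.radius_mm * np.sin(ang),
                np.full(self.n_antennas, self.height_mm),
            ],
            axis=1,
        )


@dataclass
class FieldMatrix:
    """Stacked 3M x N complex matrix of unit-excitation fields.

    ``voxel_index`` holds the (i, j, k) grid index of each of the M sampled
    voxels; stacked row r maps to component r // M and voxel r % M.
    """

    grid: VoxelGrid
    values: np.ndarray  # (3M, N) complex
    voxel_index: np.ndarray  # (M, 3) int
    frequency_hz: float
    antenna_positions_mm: np.ndarray  # (N, 3)
    r0_ohm: float = 50.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        self.antenna_positions_mm = np.asarray(self.antenna_positions_mm, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3 * self.voxel_index.shape[0]:
            raise FormatError(
                f"field matrix shape {self.values.shape} inconsistent with "
                f"{self.voxel_index.shape[0]} sampled voxels"
            )
        if not np.isfinite(self.values).all():
            raise FormatError("field matrix contains non-finite entries")
        if self.m_voxels < self.n_antennas:
            logger.warning(
                "field matrix has M=%d < N=%d: projection onto the column space is ill-posed",
                self.m_voxels,
                self.n_antennas,
            )

    @property
    def m_voxels(self) -> int:
        return int(self.voxel_index.shape[0])

    @property
    def n_antennas(self) -> int:
        return int(self.values.shape[1])

    def row_of(self, voxel: int, component: int) -> int:
        """Stacked row of (voxel, component); inverse of ``unrow``."""
        return component * self.m_voxels + voxel

    def unrow(self, row: int) -> tuple[int, int]:
        return row % self.m_voxels, row // self.m_voxels

    def column_field(self, n: int) -> np.ndarray:
        """(M, 3) complex vector field of antenna ``n``."""
        return self.values[:, n].reshape(3, self.m_voxels).T

    def per_voxel_power_sum(self) -> np.ndarray:
        """sum_n ||e_n(r)||^2 per sampled voxel (used by the intensity bound)."""
        blocks = self.values.reshape(3, self.m_voxels, self.n_antennas)
        return np.sum(np.abs(blocks) ** 2, axis=(0, 2))

    def sample_selector(self, mask: np.ndarray) -> np.ndarray:
        """Boolean length-M array: which sampled voxels fall in a grid mask."""
        i, j, k = self.voxel_index.T
        return np.asarray(mask)[i, j, k]


@dataclass
class TotalField:
    """Complex vector field on the M sampled voxels, (M, 3), V/m."""

    values: np.ndarray
    grid: VoxelGrid
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise FormatError(f"total field must be (M, 3), got {self.values.shape}")

    @property
    def m_voxels(self) -> int:
        return int(self.values.shape[0])

    def magnitude(self) -> np.ndarray:
        """Per-voxel 3-component Euclidean magnitude |E| (V/m)."""
        return np.sqrt(self.intensity())

    def intensity(self) -> np.ndarray:
        """Per-voxel |E|^2 (V^2/m^2), summed over complex components."""
        return np.sum(np.abs(self.values) ** 2, axis=1)

    def stacked(self) -> np.ndarray:
        """Length-3M stacked vector (x block, y block, z block)."""
        return self.values.T.reshape(-1)

    @classmethod
    def from_stacked(cls, stacked: np.ndarray, like: "FieldMatrix | TotalField") -> "TotalField":
        m = like.m_voxels
        return cls(
            values=np.asarray(stacked).reshape(3, m).T,
            grid=like.grid,
            voxel_index=like.voxel_index,
        )


def lossy_medium_constants(eps_r: float, sigma: float, frequency_hz: float) -> tuple[float, float]:
    """Attenuation alpha (Np/m) and phase beta (rad/m) of a homogeneous
    lossy medium at the given frequency (standard closed form)."""
    if frequency_hz <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency_hz}")
    omega = 2 * np.pi * frequency_hz
    eps = eps_r * _EPS0
    loss_tan = sigma / (omega * eps)
    root = np.sqrt(1.0 + loss_tan**2)
    common = omega * np.sqrt(_MU0 * eps / 2.0)
    alpha = common * np.sqrt(root - 1.0)
    beta = common * np.sqrt(root + 1.0)
    return float(alpha), float(beta)


def synthesize_surrogate_fields(
    phantom: TissuePhantom,
    ring: AntennaRing,
    reference_tissue: str = "muscle",
    amplitude: float = 1.0,
    leakage: float = 0.1,
) -> FieldMatrix:
    """Analytic stand-in for solver-exported unit-excitation fields.

    Each antenna contributes ``amplitude * sin(theta) * exp(-(alpha+j*beta)*d) / d``
    along the ring's polarization axis, where d is the source-voxel distance
    (floored at one voxel spacing), theta the angle between the propagation
    direction and the polarization axis, and alpha/beta come from an
    effective homogeneous medium built from ``reference_tissue``.  The two
    transverse axes carry ``leakage`` times the dominant component with a
    deterministic antenna-dependent phase, so the dominant-axis entries stay
    a fixed factor above the rest (1/leakage, 10x by default).
    """
    if ring.frequency_hz <= 0:
        raise ValueError("frequency must be > 0")
    if reference_tissue not in phantom.table:
        raise ConfigurationError(f"reference tissue {reference_tissue!r} not in tissue table")
    ref = phantom.table.tissue(phantom.table.label_of(reference_tissue))
    alpha, beta = lossy_medium_constants(ref.eps_r, ref.sigma, ring.frequency_hz)

    tissue = phantom.tissue_mask
    voxel_index = np.argwhere(tissue)
    centers_m = phantom.grid.index_centers(voxel_index) * 1e-3  # mm -> m
    m_vox = voxel_index.shape[0]

    positions = ring.positions_mm()
    centers_mm = phantom.grid.index_centers(voxel_index)
    tissue_rad = np.hypot(centers_mm[:, 0], centers_mm[:, 1])
    if m_vox and ring.radius_mm <= tissue_rad.max():
        raise ConfigurationError(
            f"antenna ring radius {ring.radius_mm} mm must be outside the tissue "
            f"(max tissue radius {tissue_rad.max():.1f} mm)"
        )
    positions_m = positions * 1e-3
    d_floor = min(phantom.grid.spacing) * 1e-3

    pol = np.asarray(ring.polarization_axis)
    n_ant = ring.n_antennas
    values = np.zeros((3 * m_vox, n_ant), dtype=np.complex128)
    dom_axis = int(np.argmax(np.abs(pol)))
    trans_axes = [a for a in range(3) if a != dom_axis]

    for n in range(n_ant):
        delta = centers_m - positions_m[n]
        d = np.linalg.norm(delta, axis=1)
        d = np.maximum(d, d_floor)
        dhat = delta / d[:, None]
        cos_t = dhat @ pol
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
        main = amplitude * sin_t * np.exp(-(alpha + 1j * beta) * d) / d
        col = np.zeros((m_vox, 3), dtype=np.complex128)
        col[:, dom_axis] = main
        # deterministic leakage phases keep antennas linearly independent
        phase = 2 * np.pi * (n + 1) / n_ant
        col[:, trans_axes[0]] = leakage * main * np.exp(1j * phase)
        col[:, trans_axes[1]] = leakage * main * np.exp(-1j * 2 * phase)
        values[:, n] = col.T.reshape(-1)

    return FieldMatrix(
        grid=phantom.grid,
        values=values,
        voxel_index=voxel_index,
        frequency_hz=ring.frequency_hz,
        antenna_positions_mm=positions,
    )


def assemble_field_matrix(
    per_antenna_fields: Sequence[np.ndarray],
    grid: VoxelGrid,
    sampling_mask: np.ndarray,
    frequency_hz: float,
    antenna_positions_mm: np.ndarray | None = None,
    r0_ohm: float = 50.0,
) -> FieldMatrix:
    """Stack per-antenna (nx, ny, nz, 3) complex fields into the 3M x N matrix.

    The sampling mask selects the M voxels; the row order is the x block for
    all M voxels, then y, then z, with voxels in C-order of the mask.
    """
    mask = np.asarray(sampling_mask, dtype=bool)
    if mask.shape != grid.shape:
        raise FormatError(f"sampling mask shape {mask.shape} != grid shape {grid.shape}")
    voxel_index = np.argwhere(mask)
    m_vox = voxel_index.shape[0]
    cols = []
    for n, fld in enumerate(per_antenna_fields):
        fld = np.asarray(fld, dtype=np.complex128)
        if fld.shape != grid.shape + (3,):
            raise FormatError(
                f"antenna {n}: field shape {fld.shape} != {grid.shape + (3,)}"
            )
        sampled = fld[mask]  # (M, 3), C-order matches argwhere
        cols.append(sampled.T.reshape(-1))
    values = np.stack(cols, axis=1)
    if antenna_positions_mm is None:
        antenna_positions_mm = np.full((len(cols), 3), np.nan)
    return FieldMatrix(
        grid=grid,
        values=values,
        voxel_index=voxel_index,
        frequency_hz=frequency_hz,
        antenna_positions_mm=antenna_positions_mm,
        r0_ohm=r0_ohm,
    )


def superpose_field(matrix: FieldMatrix, b: np.ndarray) -> TotalField:
    """Total field under excitation vector b: the matrix-vector product,
    reshaped to per-voxel 3-component vectors.  Linear in b."""
    b = np.asarray(b, dtype=np.complex128).reshape(-1)
    if b.shape[0] != matrix.n_antennas:
        raise ValueError(f"excitation length {b.shape[0]} != N={matrix.n_antennas}")
    return TotalField.from_stacked(matrix.values @ b, matrix)


def dominant_component(matrix: FieldMatrix) -> str:
    """Axis label with the largest mean entry magnitude; ties go x < y < z."""
    if matrix.values.size == 0:
        raise DegenerateInputError("empty field matrix")
    blocks = matrix.values.reshape(3, matrix.m_voxels, matrix.n_antennas)
    means = np.mean(np.abs(blocks), axis=(1, 2))
    if np.all(means == 0):
        raise DegenerateInputError("all-zero field matrix has no dominant component")
    return _AXES[int(np.argmax(means))]


def write_field_container(matrix: FieldMatrix, path: str | Path) -> None:
    """Persist the field matrix to the documented HDF5 layout (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("EN", data=matrix.values)
        f.create_dataset("voxel_index", data=matrix.voxel_index)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["grid_shape"] = np.asarray(matrix.grid.shape, dtype=np.int64)
        f.attrs["grid_spacing_mm"] = np.asarray(matrix.grid.spacing)
        f.attrs["grid_origin_mm"] = np.asarray(matrix.grid.origin)
        f.attrs["frequency_hz"] = matrix.frequency_hz
        f.attrs["antenna_positions_mm"] = matrix.antenna_positions_mm
        f.attrs["r0_ohm"] = matrix.r0_ohm


def read_field_container(path: str | Path) -> FieldMatrix:
    """Load a field matrix container; validates version and schema."""
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs:
            raise FormatError(f"{path}: missing format_version attribute")
        version = int(f.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"{path}: container version {version}, this build reads {FORMAT_VERSION}"
            )
        for name in ("EN", "voxel_index"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset /{name}")
        for attr in ("grid_shape", "grid_spacing_mm", "grid_origin_mm", "frequency_hz",
                     "antenna_positions_mm"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute {attr}")
        values = f["EN"][()]
        voxel_index = f["voxel_index"][()]
        if voxel_index.ndim != 2 or voxel_index.shape[1] != 3:
            raise FormatError(f"{path}: voxel_index must be (M, 3)")
        if values.ndim != 2 or values.shape[0] != 3 * voxel_index.shape[0]:
            raise FormatError(
                f"{path}: EN shape {values.shape} inconsistent with M={voxel_index.shape[0]}"
            )
        grid = VoxelGrid(
            shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            spacing=tuple(float(v) for v in f.attrs["grid_spacing_mm"]),
            origin=tuple(float(v) for v in f.attrs["grid_origin_mm"]),
        )
        return FieldMatrix(
            grid=grid,
            values=values,
            voxel_index=voxel_index,
            frequency_hz=float(f.attrs["frequency_hz"]),
            antenna_positions_mm=np.asarray(f.attrs["antenna_positions_mm"]),
            r0_ohm=float(f.attrs.get("r0_ohm", 50.0)),
        )
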