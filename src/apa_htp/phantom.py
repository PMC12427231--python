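"""Voxelized layered cylindrical phantom with tissue properties.

Geometry lives on a regular voxel grid (lengths in mm, right-handed frame,
z vertical).  A phantom pairs an integer label volume with a tissue property
table; label 0 is reserved for the exterior (air/water) and is never solved
or sampled.  Region partitioning splits the tissue voxels into tumor,
transition shell, and healthy sets around a tumor centroid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "VoxelGrid",
    "Tissue",
    "TissueTable",
    "TissuePhantom",
    "RegionPartition",
    "build_layered_cylinder_phantom",
    "partition_regions",
    "load_tissue_table_csv",
    "write_labels_nifti",
]

_TISSUE_CSV_HEADER = [
    "name",
    "eps_r",
    "sigma_S_per_m",
    "rho_kg_per_m3",
    "k_W_per_mC",
    "cp_J_per_kgC",
    "omega_ml_per_min_kg",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid; ``origin`` is the center of voxel (0, 0, 0) in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ConfigurationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise ConfigurationError(f"grid spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center coordinates in mm."""
        x, y, z = (self.axis_coords(a) for a in range(3))
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def index_centers(self, indices: np.ndarray) -> np.ndarray:
        """Centers (mm) of voxels given as an (M, 3) integer index array."""
        idx = np.asarray(indices)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class Tissue:
    """Dielectric and thermal properties of one tissue.

    ``eps_r`` unitless, ``sigma`` S/m, ``rho`` kg/m^3, ``k`` W/m/degC,
    ``cp`` J/kg/degC, ``omega`` mL/min/kg.
    """

    name: str
    eps_r: float
    sigma: float
    rho: float
    k: float
    cp: float
    omega: float

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.omega < 0:
            raise ConfigurationError(f"tissue {self.name!r}: sigma and omega must be >= 0")
        if self.rho <= 0 or self.k <= 0 or self.cp <= 0:
            raise ConfigurationError(f"tissue {self.name!r}: rho, k, cp must be > 0")


class TissueTable:
    """Ordered tissue registry; label ids are 1-based in registration order."""

    def __init__(self, tissues: Iterable[Tissue] = ()) -> None:
        self._tissues: list[Tissue] = []
        self._by_name: dict[str, int] = {}
        for t in tissues:
            self.add(t)

    def add(self, tissue: Tissue) -> int:
        if tissue.name in self._by_name:
            raise ConfigurationError(f"duplicate tissue name {tissue.name!r}")
        self._tissues.append(tissue)
        label = len(self._tissues)
        self._by_name[tissue.name] = label
        return label

    def __len__(self) -> int:
        return len(self._tissues)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [t.name for t in self._tissues]

    def label_of(self, name: str) -> int:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"tissue {name!r} not in table") from None

    def tissue(self, label: int) -> Tissue:
        if not 1 <= label <= len(self._tissues):
            raise ConfigurationError(f"label {label} not in tissue table")
        return self._tissues[label - 1]

    def property_lut(self, prop: str) -> np.ndarray:
        """Lookup array indexed by label (entry 0 is 0.0 for the exterior)."""
        lut = np.zeros(len(self._tissues) + 1)
        for i, t in enumerate(self._tissues, start=1):
            lut[i] = getattr(t, prop)
        return lut

    def map_property(self, labels: np.ndarray, prop: str) -> np.ndarray:
        """Vectorized label -> property mapping; total for valid phantoms."""
        labels = np.asarray(labels)
        if labels.size and labels.max() > len(self._tissues):
            raise ConfigurationError(
                f"label volume contains label {int(labels.max())} beyond the table"
            )
        return self.property_lut(prop)[labels]


@dataclass
class TissuePhantom:
    """Labeled voxel volume plus its tissue table."""

    grid: VoxelGrid
    labels: np.ndarray
    table: TissueTable

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise ConfigurationError(
                f"label volume shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        present = np.unique(self.labels)
        for lab in present:
            if lab != 0:
                self.table.tissue(int(lab))  # raises if missing

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != 0

    @property
    def n_tissue_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))

    def property_volume(self, prop: str) -> np.ndarray:
        return self.table.map_property(self.labels, prop)


@dataclass
class RegionPartition:
    """Disjoint tumor / transition / healthy masks over the tissue voxels."""

    tumor_mask: np.ndarray
    transition_mask: np.ndarray
    healthy_mask: np.ndarray
    centroid: tuple[float, float, float]
    rt: float
    rh: float

    def __post_init__(self) -> None:
        t, s, h = self.tumor_mask, self.transition_mask, self.healthy_mask
        if t.shape != s.shape or t.shape != h.shape:
            raise ConfigurationError("partition masks must share one shape")
        if np.any(t & s) or np.any(t & h) or np.any(s & h):
            raise ConfigurationError("partition masks must be pairwise disjoint")
        if self.rt >= self.rh:
            raise ValueError(f"rt ({self.rt}) must be < rh ({self.rh})")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.tumor_mask | self.transition_mask | self.healthy_mask


@dataclass(frozen=True)
class CylinderLayer:
    """Layer of the concentric phantom: all radii <= ``radius_mm`` not claimed
    by an inner layer take ``tissue``."""

    radius_mm: float
    tissue: str


@dataclass
class PhantomConfig:
    """Declarative description of the layered cylindrical phantom."""

    layers: Sequence[CylinderLayer]
    height_mm: float
    spacing_mm: float | tuple[float, float, float]
    table: TissueTable
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radius_mm: float | None = None
    tumor_tissue: str = "tumor"
    base_slab_thickness_mm: float = 0.0
    base_slab_tissue: str = "muscle"
    padding_mm: float = 0.0

    @property
    def spacing(self) -> tuple[float, float, float]:
        s = self.spacing_mm
        if np.isscalar(s):
            return (float(s),) * 3
        return tuple(float(v) for v in s)  # type: ignore[return-value]


def build_layered_cylinder_phantom(config: PhantomConfig) -> TissuePhantom:
    """Voxelize a concentric-layer cylinder with an optional spherical tumor.

    Membership is decided by each voxel center: its radial distance to the
    cylinder axis selects the innermost matching layer; centers inside the
    tumor sphere are relabeled as tumor.  Voxels outside every layer get
    label 0.  An optional supporting slab extends the domain below the
    cylinder.
    """
    layers = list(config.layers)
    if not layers:
        raise ConfigurationError("phantom config needs at least one layer")
    radii = [l.radius_mm for l in layers]
    if any(r <= 0 for r in radii):
        raise ConfigurationError("layer radii must be positive")
    if sorted(radii) != radii or len(set(radii)) != len(radii):
        raise ConfigurationError(f"layer radii must be strictly increasing, got {radii}")
    for l in layers:
        config.table.label_of(l.tissue)  # validate

    r_out = radii[-1]
    half_h = config.height_mm / 2.0
    sx, sy, sz = config.spacing
    pad = config.padding_mm

    slab = config.base_slab_thickness_mm
    z_lo, z_hi = -half_h - slab - pad, half_h + pad
    nx = int(np.floor(2 * (r_out + pad) / sx)) + 1
    ny = int(np.floor(2 * (r_out + pad) / sy)) + 1
    nz = int(np.floor((z_hi - z_lo) / sz)) + 1
    # symmetric about the axis in x/y so the cylinder center is a voxel center
    ox = -sx * ((nx - 1) // 2)
    oy = -sy * ((ny - 1) // 2)
    oz = z_lo
    grid = VoxelGrid((nx, ny, nz), (sx, sy, sz), (ox, oy, oz))

    centers = grid.voxel_centers()
    rad = np.hypot(centers[..., 0], centers[..., 1])
    z = centers[..., 2]
    labels = np.zeros(grid.shape, dtype=np.int32)

    in_height = (z >= -half_h) & (z <= half_h)
    prev_r = 0.0
    for layer in layers:
        lab = config.table.label_of(layer.tissue)
        ring = in_height & (rad > prev_r if prev_r else rad >= 0) & (rad <= layer.radius_mm)
        labels[ring] = lab
        prev_r = layer.radius_mm

    if slab > 0:
        slab_lab = config.table.label_of(config.base_slab_tissue)
        in_slab = (z < -half_h) & (z >= -half_h - slab) & (rad <= r_out)
        labels[in_slab] = slab_lab

    if config.tumor_center_mm is not None:
        if config.tumor_radius_mm is None or config.tumor_radius_mm <= 0:
            raise ConfigurationError("tumor sphere needs a positive radius")
        c = np.asarray(config.tumor_center_mm, dtype=float)
        rt = float(config.tumor_radius_mm)
        c_rad = float(np.hypot(c[0], c[1]))
        if c_rad + rt > r_out or abs(c[2]) + rt > half_h:
            raise ConfigurationError(
                "tumor sphere not fully inside the cylinder "
                f"(center {tuple(c)}, radius {rt}, cylinder r={r_out}, half-height {half_h})"
            )
        d2 = np.sum((centers - c) ** 2, axis=-1)
        labels[d2 <= rt**2] = config.table.label_of(config.tumor_tissue)

    return TissuePhantom(grid=grid, labels=labels, table=config.table)


def partition_regions(
    phantom: TissuePhantom,
    centroid: Sequence[float],
    rt: float,
    rh: float,
    tumor_tissue: str | None = "tumor",
) -> RegionPartition:
    """Split tissue voxels into tumor / transition / healthy regions.

    The tumor set is the union of the rt-ball around ``centroid`` and any
    voxels carrying the tumor label (so irregular imported tumors are
    covered; rt acts as a lower bound).  The transition shell reaches out to
    ``rh``; everything else is healthy.
    """
    if rt >= rh:
        raise ValueError(f"rt ({rt}) must be < rh ({rh})")
    c = np.asarray(centroid, dtype=float)
    tissue = phantom.tissue_mask
    d2 = np.sum((phantom.grid.voxel_centers() - c) ** 2, axis=-1)

    tumor = tissue & (d2 <= rt**2)
    if tumor_tissue is not None and tumor_tissue in phantom.table:
        tumor |= phantom.labels == phantom.table.label_of(tumor_tissue)
    if not tumor.any():
        raise ValueError("empty tumor mask: centroid outside tissue or rt too small")

    transition = tissue & ~tumor & (d2 <= rh**2)
    healthy = tissue & ~tumor & ~transition
    return RegionPartition(
        tumor_mask=tumor,
        transition_mask=transition,
        healthy_mask=healthy,
        centroid=tuple(float(v) for v in c),
        rt=float(rt),
        rh=float(rh),
    )


def load_tissue_table_csv(path: str | Path) -> TissueTable:
    """Read a tissue table from the documented CSV layout."""
    table = TissueTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _TISSUE_CSV_HEADER:
            raise ConfigurationError(
                f"tissue CSV header must be {_TISSUE_CSV_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            table.add(
                Tissue(
                    name=row["name"].strip(),
                    eps_r=float(row["eps_r"]),
                    sigma=float(row["sigma_S_per_m"]),
                    rho=float(row["rho_kg_per_m3"]),
                    k=float(row["k_W_per_mC"]),
                    cp=float(row["cp_J_per_kgC"]),
                    omega=float(row["omega_ml_per_min_kg"]),
                )
            )
    if len(table) == 0:
        raise ConfigurationError(f"tissue CSV {path} contains no rows")
    return table


def write_tissue_table_csv(table: TissueTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TISSUE_CSV_HEADER)
        for name in table.names:
            t = table.tissue(table.label_of(name))
            w.writerow([t.name, t.eps_r, t.sigma, t.rho, t.k, t.cp, t.omega])


def write_labels_nifti(phantom: TissuePhantom, path: str | Path) -> None:
    """Export the label volume as NIfTI (mm spacing on the diagonal affine)."""
    import nibabel as nib

    affine = np.diag(list(phantom.grid.spacing) + [1.0])
    affine[:3, 3] = phantom.grid.origin
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    nib.save(img, str(path))
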