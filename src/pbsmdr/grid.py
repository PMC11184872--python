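"""Voxel geometry shared by all dose, LET and dose-rate maps.

A :class:`VoxelGrid` fixes the discretisation on which every per-spot dose
distribution and every derived map (total dose, dose-averaged LET, maximum
dose rate) is scored.  World coordinates are in millimetres in the
isocenter/patient frame; the position of a voxel is the position of its
center, and the grid origin is the center of voxel index ``(0, 0, 0)``.
The beam axis is the grid +z axis and depth is measured from the grid's
minimum-z face (the entry plane).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Default cap on total voxel count; keeps desk-scale memory and run time.
MAX_VOXELS = 2_000_000


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel grid.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z).  Each entry must be >= 1.
    spacing
        Voxel size in mm along (x, y, z).  Each entry must be > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    max_voxels: int = field(default=MAX_VOXELS, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"grid dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be > 0, got {self.spacing}")
        if self.n_voxels > self.max_voxels:
            raise ValueError(
                f"grid has {self.n_voxels} voxels, exceeding the cap "
                f"of {self.max_voxels}"
            )

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    @property
    def entry_z(self) -> float:
        """World z of the beam entry plane (minimum-z face of the grid)."""
        return self.origin[2] - 0.5 * self.spacing[2]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of voxel-center world coordinates."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world corners of the grid volume (voxel faces)."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.dims) * np.asarray(self.spacing)
        return lo, hi

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def ravel(self, i, j, k) -> np.ndarray:
        return np.ravel_multi_index((i, j, k), self.dims)


@dataclass
class ScalarMap:
    """A dense scalar field (dose, LET_d, RBE dose, ...) on a VoxelGrid.

    ``values`` has shape ``grid.dims``; undefined voxels (e.g. LET_d where
    no dose was deposited) are NaN.
    """

    grid: VoxelGrid
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims "
                f"{self.grid.dims}"
            )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine())

    def save(self, path: str | Path) -> None:
        """Write the map as NIfTI plus a JSON sidecar recording units."""
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        meta = {"units": self.units, "name": self.name,
                "spacing_mm": list(self.grid.spacing),
                "origin_mm": list(self.grid.origin)}
        Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))


@dataclass
class StructureMask:
    """Binary mask for a named structure (OC, ONL, ONR, CTV, ...) on a grid."""

    name: str
    grid: VoxelGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.dims:
            raise ValueError(
                f"mask {self.name!r}: shape {self.voxels.shape} does not "
                f"match grid dims {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        # Structure volume = voxel count x voxel volume (binary masks,
        # no partial-volume weighting).
        return self.n_voxels * self.grid.voxel_volume_mm3

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), self.grid.affine())
        nib.save(img, str(path))


def load_mask(path: str | Path, name: str | None = None) -> StructureMask:
    """Read a binary structure mask from NIfTI."""
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(dims=data.shape, spacing=spacing, origin=origin)
    return StructureMask(name=name or Path(path).stem, grid=grid,
                         voxels=data > 0)


def same_grid(a: VoxelGrid, b: VoxelGrid) -> bool:
    return a.dims == b.dims and a.spacing == b.spacing and a.origin == b.origin
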