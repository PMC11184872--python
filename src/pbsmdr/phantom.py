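"""Synthetic phantoms: geometric primitives rasterized to structure masks.

The optic apparatus is modelled with simple primitives — the optic chiasm
(OC) as a small sphere, the left/right optic nerves (ONL, ONR) as thin
tubes running anteriorly from the chiasm, and the CTV as a sphere placed
posterior-superior to the chiasm so that the target sits near, but not on,
the optic structures.  Masks are binary: a voxel belongs to a structure iff
its center lies inside one of the structure's primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import StructureMask, VoxelGrid

_AXES = {"x": np.array([1.0, 0.0, 0.0]),
         "y": np.array([0.0, 1.0, 0.0]),
         "z": np.array([0.0, 0.0, 1.0])}


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = ((pts - np.asarray(self.center)) ** 2).sum(axis=-1)
        return d2 <= self.radius**2

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        return c - self.radius, c + self.radius


@dataclass(frozen=True)
class Tube:
    """Finite cylinder: ``center`` is the midpoint, ``axis`` one of x/y/z."""

    center: tuple[float, float, float]
    radius: float
    axis: str
    half_length: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        u = _AXES[self.axis]
        rel = pts - c
        along = rel @ u
        radial2 = (rel**2).sum(axis=-1) - along**2
        return (np.abs(along) <= self.half_length) & (radial2 <= self.radius**2)

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        u = _AXES[self.axis]
        ext = self.half_length * u + self.radius * (1.0 - u)
        return c - ext, c + ext


Primitive = Sphere | Tube

#: Default optic-apparatus geometry (mm, world frame).  The chiasm sits on
#: the beam axis; the pre-chiasmatic nerve segments run anteriorly (-y).
#: OC/ONL/ONR are disjoint by construction; the CTV sphere abuts the chiasm.
def default_structure_spec() -> dict[str, list[Primitive]]:
    return {
        "OC": [Sphere(center=(0.0, 0.0, 64.0), radius=4.0)],
        "ONL": [Tube(center=(-8.0, -10.0, 64.0), radius=2.5,
                     axis="y", half_length=10.0)],
        "ONR": [Tube(center=(8.0, -10.0, 64.0), radius=2.5,
                     axis="y", half_length=10.0)],
        "CTV": [Sphere(center=(0.0, 10.0, 75.0), radius=12.0)],
    }


DEFAULT_DIMS = (40, 40, 60)
DEFAULT_SPACING = (2.0, 2.0, 2.0)
DEFAULT_ORIGIN = (-39.0, -39.0, 1.0)


def make_phantom(
    dims: tuple[int, int, int] = DEFAULT_DIMS,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    structure_spec: dict[str, list[Primitive]] | None = None,
    origin: tuple[float, float, float] = DEFAULT_ORIGIN,
) -> tuple[VoxelGrid, dict[str, StructureMask]]:
    """Rasterize a structure spec onto a fresh voxel grid.

    Each structure is the union of its primitives, rasterized by the
    point-in-primitive test at every voxel center.  Deterministic for
    fixed inputs.

    Raises
    ------
    ValueError
        If a primitive extends outside the grid (naming the structure),
        or a structure rasterizes to zero voxels.
    """
    grid = VoxelGrid(dims=dims, spacing=spacing, origin=origin)
    if structure_spec is None:
        structure_spec = default_structure_spec()

    lo, hi = grid.bounds()
    xs, ys, zs = grid.voxel_centers()
    pts = np.stack([xs, ys, zs], axis=-1)  # (nx, ny, nz, 3)

    masks: dict[str, StructureMask] = {}
    for name, prims in structure_spec.items():
        if not prims:
            raise ValueError(f"structure {name!r} has no primitives")
        inside = np.zeros(grid.dims, dtype=bool)
        for prim in prims:
            blo, bhi = prim.bbox()
            if np.any(blo < lo) or np.any(bhi > hi):
                raise ValueError(
                    f"primitive of structure {name!r} extends outside the "
                    f"grid (bbox {blo.tolist()}..{bhi.tolist()}, grid "
                    f"{lo.tolist()}..{hi.tolist()})"
                )
            inside |= prim.contains(pts)
        if not inside.any():
            raise ValueError(f"structure {name!r} rasterized to zero voxels")
        masks[name] = StructureMask(name=name, grid=grid, voxels=inside)
    return grid, masks
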